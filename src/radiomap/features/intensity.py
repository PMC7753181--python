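"""First-order intensity statistics on raw (re-segmented, undiscretized) HU values.

Percentiles use linear interpolation between order statistics.  Variance and
the higher moments are population (biased) moments, following the common
radiomics convention.  Dispersion features of a single-voxel ROI are undefined
and reported as NaN; shape-of-distribution features (skewness, kurtosis,
coefficient of variation) are NaN whenever the variance is zero.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["intensity_features", "INTENSITY_FEATURES"]

log = logging.getLogger(__name__)

#: dispersion statistics that need more than one voxel
_DISPERSION = frozenset(
    {
        "variance",
        "skewness",
        "kurtosis",
        "interquartile_range",
        "range",
        "mean_absolute_deviation",
        "robust_mean_absolute_deviation",
        "median_absolute_deviation",
        "coefficient_of_variation",
    }
)


def _all_features(x: np.ndarray) -> dict[str, float]:
    mu = float(np.mean(x))
    var = float(np.mean((x - mu) ** 2))
    sd = np.sqrt(var)
    med = float(np.median(x))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "mean": mu,
        "variance": var,
        "skewness": float(np.mean((x - mu) ** 3)) / sd**3 if sd > 0 else np.nan,
        "kurtosis": float(np.mean((x - mu) ** 4)) / var**2 - 3.0 if sd > 0 else np.nan,
        "median": med,
        "minimum": float(np.min(x)),
        "percentile_10": p10,
        "percentile_90": p90,
        "maximum": float(np.max(x)),
        "interquartile_range": p75 - p25,
        "range": float(np.max(x) - np.min(x)),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mu))),
        "robust_mean_absolute_deviation": float(np.mean(np.abs(robust - robust.mean()))),
        "median_absolute_deviation": float(np.mean(np.abs(x - med))),
        "coefficient_of_variation": sd / mu if sd > 0 and mu != 0 else np.nan,
        "energy": float(np.sum(x.astype(np.float64) ** 2)),
        "root_mean_square": float(np.sqrt(np.mean(x.astype(np.float64) ** 2))),
    }
    return out


def intensity_features(values: np.ndarray, feature_names: tuple[str, ...]) -> dict[str, float]:
    """Compute the requested first-order statistics on raw HU values.

    Parameters
    ----------
    values : 1D array of in-ROI HU intensities (already re-segmented).
    feature_names : bare feature names (without the ``intensity_`` prefix).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI: no intensity values")
    feats = _all_features(x)
    if x.size == 1:
        log.warning("single-voxel ROI: dispersion features are undefined (NaN)")
        for name in _DISPERSION:
            feats[name] = np.nan
    unknown = [f for f in feature_names if f not in feats]
    if unknown:
        raise KeyError(f"unknown intensity features: {unknown}")
    return {f: feats[f] for f in feature_names}
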