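"""Binary feature activation maps and region-wise group comparison.

A patch is *activated* when its local feature value is strictly larger than
the median of the corresponding global feature over the training cohort
(ties count as non-activated).  Activation is summarized per patient as the
activated fraction per region (GTV, rim); patients qualify for group testing
only with at least 27 retained patches overall and at least 3 per region.
Group differences in the activation ratio are assessed with the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test — exact null distribution for small
tie-free samples, normal approximation with continuity and tie correction
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from radiomap.imaging_io import MaskVolume
from radiomap.local_radiomics import (
    LABEL_GTV,
    LABEL_MIXED,
    LABEL_RIM,
    PatchGrid,
    _patch_voxels,
)

__all__ = [
    "ActivationThreshold",
    "ActivationSummary",
    "fit_threshold",
    "binarize",
    "summarize",
    "compare_groups",
    "export_map",
]

log = logging.getLogger(__name__)

#: voxel labels in exported activation maps
MAP_BACKGROUND, MAP_NONACTIVATED, MAP_ACTIVATED, MAP_MIXED = 0, 1, 2, 3


@dataclass(frozen=True)
class ActivationThreshold:
    """Median of a global feature over the training cohort."""

    feature_name: str
    threshold: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("activation threshold must be finite")


@dataclass
class ActivationSummary:
    """Per-patient activated-patch counts and ratios by region."""

    patient_id: str
    n_activated: dict[str, int]
    n_total: dict[str, int]
    eligible: bool
    class_label: int | None = None

    def ratio(self, region: str) -> float:
        n = self.n_total.get(region, 0)
        return self.n_activated.get(region, 0) / n if n > 0 else np.nan


def fit_threshold(training_values, feature_name: str) -> ActivationThreshold:
    """Sample median (average-of-middle-two) of the global feature on training patients.

    Uses training data only; validation patients never influence the split.
    """
    vals = np.asarray(pd.Series(training_values).dropna(), dtype=np.float64)
    if vals.size == 0:
        raise ValueError(f"no finite training values for feature {feature_name!r}")
    return ActivationThreshold(feature_name=feature_name, threshold=float(np.median(vals)))


def binarize(patches: pd.DataFrame, thr: ActivationThreshold) -> pd.DataFrame:
    """Flag patches of one feature as activated (value strictly > threshold).

    Sentinel (NaN) values are excluded from counts and logged.  Returns the
    feature's rows with added ``activated`` and ``valid`` columns.
    """
    sub = patches[patches["feature"] == thr.feature_name].copy()
    if sub.empty:
        raise KeyError(f"feature {thr.feature_name!r} not present in patch table")
    sub["valid"] = np.isfinite(sub["value"])
    n_bad = int((~sub["valid"]).sum())
    if n_bad:
        log.warning("%d patches with sentinel %s values excluded from activation counts",
                    n_bad, thr.feature_name)
    sub["activated"] = sub["valid"] & (sub["value"] > thr.threshold)
    return sub


def summarize(
    flagged: pd.DataFrame,
    min_total: int = 27,
    min_region: int = 3,
    class_labels: dict[str, int] | None = None,
) -> list[ActivationSummary]:
    """Per-patient activation counts per region and eligibility flags.

    Eligibility: at least ``min_total`` retained (GTV or rim labeled, valid)
    patches overall and at least ``min_region`` in each region.  Ineligible
    patients are retained in the output but excluded from group tests.
    """
    out = []
    for pid, df in flagged.groupby("patient_id", sort=True):
        valid = df[df["valid"]]
        n_total = {r: int((valid["label"] == r).sum()) for r in (LABEL_GTV, LABEL_RIM)}
        n_act = {
            r: int(valid[(valid["label"] == r) & valid["activated"]].shape[0])
            for r in (LABEL_GTV, LABEL_RIM)
        }
        eligible = sum(n_total.values()) >= min_total and all(
            n >= min_region for n in n_total.values()
        )
        out.append(
            ActivationSummary(
                patient_id=str(pid),
                n_activated=n_act,
                n_total=n_total,
                eligible=eligible,
                class_label=None if class_labels is None else class_labels.get(str(pid)),
            )
        )
    return out


def compare_groups(
    summaries: list[ActivationSummary],
    region: str,
    group_a: int = 1,
    group_b: int = 0,
    exact_max_n: int = 12,
) -> dict:
    """Two-sided Wilcoxon rank-sum test on region activation ratios.

    Only eligible patients enter.  The exact null distribution is used when
    both groups have at most ``exact_max_n`` patients and there are no ties;
    otherwise the normal approximation with continuity and tie correction.
    """
    a = [s.ratio(region) for s in summaries if s.eligible and s.class_label == group_a]
    b = [s.ratio(region) for s in summaries if s.eligible and s.class_label == group_b]
    a = [v for v in a if np.isfinite(v)]
    b = [v for v in b if np.isfinite(v)]
    if not a or not b:
        raise ValueError(f"empty comparison group for region {region!r}")
    pooled = a + b
    has_ties = len(set(pooled)) < len(pooled)
    if len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approximation"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return {
        "region": region,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "n_group_a": len(a),
        "n_group_b": len(b),
    }


def export_map(grid: PatchGrid, flagged: pd.DataFrame, roi: MaskVolume) -> np.ndarray:
    """Voxelwise activation label volume.

    0 background, 1 non-activated, 2 activated, 3 mixed-overlap (discarded).
    All informative voxels of a patch carry that patch's label.
    """
    out = np.zeros(grid.shape, dtype=np.uint8)
    status = {
        int(r.patch_id): (MAP_ACTIVATED if r.activated else MAP_NONACTIVATED)
        for r in flagged.itertuples()
        if r.valid
    }
    for p in grid.patches:
        if p.label == LABEL_MIXED:
            code = MAP_MIXED
        elif p.label in (LABEL_GTV, LABEL_RIM) and p.patch_id in status:
            code = status[p.patch_id]
        else:
            continue
        vox = _patch_voxels(p, grid, roi.data)
        out[vox[:, 0], vox[:, 1], vox[:, 2]] = code
    return out
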