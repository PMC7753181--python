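"""Texture feature formulas per family, on count matrices.

Grey levels are 1-based (bin index + 1) in every formula, following the IBSI
convention.  Undefined quantities (zero denominators, degenerate matrices)
are emitted as NaN sentinels, never silently zeroed.

Naming: ``sznn``-style normalized non-uniformities divide by the squared
total count; e.g. zone size non-uniformity normalized is
``sum_s (sum_g Z(g,s))^2 / N_z^2``.
"""

from __future__ import annotations

import numpy as np

from radiomap.features.matrices import TextureMatrixSet

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "ngldm_features",
    "texture_features",
]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(mat: np.ndarray, n_levels: int) -> dict[str, float]:
    """Features of one symmetric co-occurrence count matrix."""
    names = [
        "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
        "difference_average", "difference_variance", "difference_entropy",
        "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
        "contrast", "dissimilarity", "inverse_difference",
        "inverse_difference_normalized", "inverse_difference_moment",
        "inverse_difference_moment_normalized", "inverse_variance",
        "correlation", "autocorrelation", "cluster_tendency", "cluster_shade",
        "cluster_prominence", "information_correlation_1", "information_correlation_2",
    ]
    total = mat.sum()
    if total == 0:
        return {k: np.nan for k in names}
    p = mat / total
    n = mat.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_i = p.sum(axis=1)
    mu = float((i * p_i).sum())
    var = float(((i - mu) ** 2 * p_i).sum())
    adiff = np.abs(ii - jj)

    # difference and sum distributions
    k_diff = np.arange(0, n, dtype=np.float64)
    p_diff = np.array([p[adiff == k].sum() for k in k_diff])
    da = float((k_diff * p_diff).sum())
    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    sa = float((k_sum * p_sum).sum())

    hxy = _entropy(p.ravel())
    hx = _entropy(p_i)
    pipj = np.outer(p_i, p_i)
    with np.errstate(divide="ignore"):
        log_pipj = np.where(pipj > 0, np.log2(np.where(pipj > 0, pipj, 1.0)), 0.0)
    hxy1 = float(-(p * log_pipj).sum())
    hxy2 = float(-(pipj * log_pipj).sum())

    off = adiff > 0
    out = {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": _entropy(p_diff),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": _entropy(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((adiff * p).sum()),
        "inverse_difference": float((p / (1.0 + adiff)).sum()),
        "inverse_difference_normalized": float((p / (1.0 + adiff / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + adiff**2)).sum()),
        "inverse_difference_moment_normalized": float((p / (1.0 + adiff**2 / n**2)).sum()),
        "inverse_variance": float((p[off] / adiff[off] ** 2).sum()),
        "correlation": (float(((ii * jj * p).sum() - mu**2) / var) if var > 0 else np.nan),
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation_1": ((hxy - hxy1) / hx if hx > 0 else np.nan),
        "information_correlation_2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
    }
    return out


def _rlm_style_features(mat: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared formulas for run-length (kind='run') and size-zone (kind='zone')."""
    if kind == "run":
        short_key, long_key = "short_run", "long_run"
        lg, hg = "low_grey_level_run", "high_grey_level_run"
        length_name, pct_name, ent_name = "run_length", "run_percentage", "run_entropy"
    else:
        short_key, long_key = "small_zone", "large_zone"
        lg, hg = "low_grey_level_zone", "high_grey_level_zone"
        length_name, pct_name, ent_name = "zone_size", "zone_percentage", "zone_size_entropy"
    keys = [
        f"{short_key}_emphasis", f"{long_key}_emphasis", f"{lg}_emphasis", f"{hg}_emphasis",
        f"{short_key}_low_grey_level_emphasis", f"{short_key}_high_grey_level_emphasis",
        f"{long_key}_low_grey_level_emphasis", f"{long_key}_high_grey_level_emphasis",
        "grey_level_nonuniformity", "grey_level_nonuniformity_norm",
        f"{length_name}_nonuniformity", f"{length_name}_nonuniformity_norm",
        pct_name, "grey_level_variance", f"{length_name}_variance", ent_name,
    ]
    total = mat.sum()
    if total == 0:
        return {k: np.nan for k in keys}
    p = mat / total
    n_g, n_l = mat.shape
    i = np.arange(1, n_g + 1, dtype=np.float64)
    j = np.arange(1, n_l + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    g = p.sum(axis=1)  # grey-level marginal
    r = p.sum(axis=0)  # length marginal
    mu_g = float((i * g).sum())
    mu_r = float((j * r).sum())
    row_counts = mat.sum(axis=1).astype(np.float64)
    col_counts = mat.sum(axis=0).astype(np.float64)
    return {
        f"{short_key}_emphasis": float((r / j**2).sum()),
        f"{long_key}_emphasis": float((r * j**2).sum()),
        f"{lg}_emphasis": float((g / i**2).sum()),
        f"{hg}_emphasis": float((g * i**2).sum()),
        f"{short_key}_low_grey_level_emphasis": float((p / (ii**2 * jj**2)).sum()),
        f"{short_key}_high_grey_level_emphasis": float((p * ii**2 / jj**2).sum()),
        f"{long_key}_low_grey_level_emphasis": float((p * jj**2 / ii**2).sum()),
        f"{long_key}_high_grey_level_emphasis": float((p * ii**2 * jj**2).sum()),
        "grey_level_nonuniformity": float((row_counts**2).sum() / total),
        "grey_level_nonuniformity_norm": float((row_counts**2).sum() / total**2),
        f"{length_name}_nonuniformity": float((col_counts**2).sum() / total),
        f"{length_name}_nonuniformity_norm": float((col_counts**2).sum() / total**2),
        pct_name: float(total / n_voxels),
        "grey_level_variance": float(((ii - mu_g) ** 2 * p).sum()),
        f"{length_name}_variance": float(((jj - mu_r) ** 2 * p).sum()),
        ent_name: _entropy(p.ravel()),
    }


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rlm_style_features(mat, n_voxels, "run")


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rlm_style_features(mat, n_voxels, "zone")


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    names = ["coarseness", "contrast", "busyness", "complexity", "strength"]
    n_vc = n.sum()
    if n_vc == 0:
        return {k: np.nan for k in names}
    p = n / n_vc
    i = np.arange(1, len(n) + 1, dtype=np.float64)
    present = p > 0
    n_gp = int(present.sum())
    ps = float((p * s).sum())
    ip = i[present]
    pp = p[present]
    sp = s[present]
    d_ij = ip[:, None] - ip[None, :]
    out: dict[str, float] = {}
    out["coarseness"] = 1.0 / ps if ps > 0 else np.nan
    if n_gp > 1:
        out["contrast"] = float(
            (pp[:, None] * pp[None, :] * d_ij**2).sum() / (n_gp * (n_gp - 1)) * (s.sum() / n_vc)
        )
    else:
        out["contrast"] = np.nan
    busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
    out["busyness"] = ps / busy_den if busy_den > 0 else np.nan
    out["complexity"] = float(
        (np.abs(d_ij) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
         / (pp[:, None] + pp[None, :])).sum() / n_vc
    )
    s_sum = float(s.sum())
    out["strength"] = (
        float(((pp[:, None] + pp[None, :]) * d_ij**2).sum() / s_sum) if s_sum > 0 else np.nan
    )
    return out


def ngldm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Dependence-count features; columns are dependence counts 1..27."""
    names = [
        "low_dependence_emphasis", "high_dependence_emphasis",
        "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
        "low_dependence_low_grey_level_emphasis", "low_dependence_high_grey_level_emphasis",
        "high_dependence_low_grey_level_emphasis", "high_dependence_high_grey_level_emphasis",
        "grey_level_nonuniformity", "grey_level_nonuniformity_norm",
        "dependence_count_nonuniformity", "dependence_count_nonuniformity_norm",
        "dependence_count_percentage", "grey_level_variance",
        "dependence_count_variance", "dependence_count_entropy", "dependence_count_energy",
    ]
    total = mat.sum()
    if total == 0:
        return {k: np.nan for k in names}
    p = mat / total
    n_g, n_k = mat.shape
    i = np.arange(1, n_g + 1, dtype=np.float64)
    k = np.arange(1, n_k + 1, dtype=np.float64)
    ii, kk = np.meshgrid(i, k, indexing="ij")
    g = p.sum(axis=1)
    d = p.sum(axis=0)
    mu_g = float((i * g).sum())
    mu_d = float((k * d).sum())
    row_counts = mat.sum(axis=1).astype(np.float64)
    col_counts = mat.sum(axis=0).astype(np.float64)
    return {
        "low_dependence_emphasis": float((d / k**2).sum()),
        "high_dependence_emphasis": float((d * k**2).sum()),
        "low_grey_level_count_emphasis": float((g / i**2).sum()),
        "high_grey_level_count_emphasis": float((g * i**2).sum()),
        "low_dependence_low_grey_level_emphasis": float((p / (ii**2 * kk**2)).sum()),
        "low_dependence_high_grey_level_emphasis": float((p * ii**2 / kk**2).sum()),
        "high_dependence_low_grey_level_emphasis": float((p * kk**2 / ii**2).sum()),
        "high_dependence_high_grey_level_emphasis": float((p * ii**2 * kk**2).sum()),
        "grey_level_nonuniformity": float((row_counts**2).sum() / total),
        "grey_level_nonuniformity_norm": float((row_counts**2).sum() / total**2),
        "dependence_count_nonuniformity": float((col_counts**2).sum() / total),
        "dependence_count_nonuniformity_norm": float((col_counts**2).sum() / total**2),
        "dependence_count_percentage": float(total / n_voxels),
        "grey_level_variance": float(((ii - mu_g) ** 2 * p).sum()),
        "dependence_count_variance": float(((kk - mu_d) ** 2 * p).sum()),
        "dependence_count_entropy": _entropy(p.ravel()),
        "dependence_count_energy": float((p**2).sum()),
    }


def _averaged(per_direction: list[dict[str, float]]) -> dict[str, float]:
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


def texture_features(mats: TextureMatrixSet, family: str, aggregation: str = "merged",
                     alpha: int = 0) -> dict[str, float]:
    """Dispatch feature computation for one family block of the manifest."""
    if family == "glcm":
        if aggregation == "merged":
            return glcm_features(mats.glcm_merged, mats.n_levels)
        per_dir = [glcm_features(m, mats.n_levels) for m in mats.glcm_by_direction if m.sum() > 0]
        if not per_dir:
            return glcm_features(np.zeros((mats.n_levels, mats.n_levels), dtype=np.int64), mats.n_levels)
        return _averaged(per_dir)
    if family == "glrlm":
        if aggregation == "merged":
            return glrlm_features(mats.glrlm_merged, mats.n_voxels)
        per_dir = [glrlm_features(m, mats.n_voxels) for m in mats.glrlm_by_direction if m.sum() > 0]
        if not per_dir:
            return glrlm_features(np.zeros((mats.n_levels, 1), dtype=np.int64), mats.n_voxels)
        return _averaged(per_dir)
    if family == "glszm":
        return glszm_features(mats.glszm, mats.n_voxels)
    if family == "ngtdm":
        return ngtdm_features(mats.ngtdm_s, mats.ngtdm_n)
    if family == "ngldm":
        if alpha not in mats.ngldm_by_alpha:
            raise KeyError(f"NGLDM matrix for alpha={alpha} was not built")
        return ngldm_features(mats.ngldm_by_alpha[alpha], mats.n_voxels)
    raise ValueError(f"unknown texture family {family!r}")
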