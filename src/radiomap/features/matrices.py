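"""Grey-level texture matrices on a discretized 3D ROI.

All builders operate on a *bins array*: a 3D integer array holding the
discretized grey level (0-based bin index) inside the ROI and ``-1`` outside.
Neighbourhoods are 3D with distance 1 (26-connectivity); directional matrices
use the 13 unique non-opposite offsets.

Matrices are kept as raw counts; normalization happens in the feature
formulas so that merged-direction aggregation is a plain sum of counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["DIRECTIONS_13", "TextureMatrixSet", "texture_matrices",
           "glcm_direction", "glrlm_direction", "glszm", "ngtdm", "ngldm"]

#: 13 unique 3D direction offsets (first non-zero component positive)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _offset_slices(shape, d):
    """Slices (src, dst) such that arr[src] and arr[dst] are the voxel pairs
    separated by offset ``d`` (dst = src + d), both within bounds."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step >= 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_direction(bins: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction offset."""
    src, dst = _offset_slices(bins.shape, d)
    a, b = bins[src], bins[dst]
    valid = (a >= 0) & (b >= 0)
    mat = np.zeros((n_levels, n_levels), dtype=np.int64)
    np.add.at(mat, (a[valid], b[valid]), 1)
    return mat + mat.T


def glrlm_direction(bins: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Run-length count matrix (levels x run length) along one direction."""
    in_roi = bins >= 0
    shape = bins.shape
    src, dst = _offset_slices(shape, d)
    # same[v] — voxel v links to v+d (same level, both in ROI)
    same = np.zeros(shape, dtype=bool)
    same[src] = (bins[src] == bins[dst]) & in_roi[src] & in_roi[dst]
    # prev_same[v] — voxel v-d links to v
    prev_same = np.zeros(shape, dtype=bool)
    prev_same[dst] = same[src]
    starts = in_roi & ~prev_same
    # forward run length from each voxel, by iterative propagation
    length = in_roi.astype(np.int64)
    while True:
        shifted = np.zeros(shape, dtype=np.int64)
        shifted[src] = length[dst]
        new = in_roi + np.where(same, shifted, 0)
        if np.array_equal(new, length):
            break
        length = new
    run_levels = bins[starts]
    run_lengths = length[starts]
    max_len = int(run_lengths.max()) if run_lengths.size else 1
    mat = np.zeros((n_levels, max_len), dtype=np.int64)
    np.add.at(mat, (run_levels, run_lengths - 1), 1)
    return mat


def _pad_widths(mats: list[np.ndarray]) -> list[np.ndarray]:
    width = max(m.shape[1] for m in mats)
    return [np.pad(m, ((0, 0), (0, width - m.shape[1]))) for m in mats]


def glszm(bins: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix (levels x zone size), zones by 26-connectivity."""
    cols: dict[int, dict[int, int]] = {}
    max_size = 1
    for g in range(n_levels):
        labeled, n_zones = ndimage.label(bins == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        row: dict[int, int] = {}
        for s in sizes:
            row[int(s)] = row.get(int(s), 0) + 1
        cols[g] = row
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, row in cols.items():
        for s, c in row.items():
            mat[g, s - 1] = c
    return mat


def ngtdm(bins: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood grey-tone difference: per-level sums ``s_i`` and counts ``n_i``.

    Only voxels with at least one in-ROI neighbour contribute.
    """
    in_roi = bins >= 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vals = np.where(in_roi, bins, 0).astype(np.float64)
    nbr_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(in_roi.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = in_roi & (nbr_cnt > 0.5)
    s = np.zeros(n_levels)
    n = np.zeros(n_levels, dtype=np.int64)
    if valid.any():
        mean_nbr = nbr_sum[valid] / nbr_cnt[valid]
        level = bins[valid]
        diff = np.abs(level - mean_nbr)
        np.add.at(s, level, diff)
        np.add.at(n, level, 1)
    return s, n


def ngldm(bins: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Grey-level dependence count matrix (levels x dependence count).

    The dependence count of a voxel is 1 (itself) plus the number of in-ROI
    neighbours whose level differs by at most ``alpha``; columns run 1..27.
    """
    in_roi = bins >= 0
    dep = np.zeros(bins.shape, dtype=np.int64)
    for d in OFFSETS_26:
        src, dst = _offset_slices(bins.shape, d)
        dep[src] += (np.abs(bins[src] - bins[dst]) <= alpha) & in_roi[src] & in_roi[dst]
    counts = dep[in_roi] + 1  # include the centre voxel
    levels = bins[in_roi]
    mat = np.zeros((n_levels, 27), dtype=np.int64)
    np.add.at(mat, (levels, counts - 1), 1)
    return mat


@dataclass
class TextureMatrixSet:
    """All texture matrices of one discretized ROI."""

    n_levels: int
    n_voxels: int
    glcm_by_direction: list[np.ndarray]
    glrlm_by_direction: list[np.ndarray]
    glszm: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_n: np.ndarray
    ngldm_by_alpha: dict[int, np.ndarray]

    @property
    def glcm_merged(self) -> np.ndarray:
        return sum(self.glcm_by_direction)

    @property
    def glrlm_merged(self) -> np.ndarray:
        return sum(_pad_widths(self.glrlm_by_direction))


ALL_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "ngldm")


def texture_matrices(
    bins: np.ndarray,
    n_levels: int | None = None,
    alphas: tuple[int, ...] = (0,),
    families: tuple[str, ...] | None = None,
) -> TextureMatrixSet:
    """Build texture matrices for a bins array (``-1`` marks non-ROI).

    ``families`` restricts construction to the named families (all by
    default); matrices of unrequested families are left empty.
    """
    bins = np.asarray(bins)
    if bins.ndim != 3:
        raise ValueError("bins array must be 3D")
    in_roi = bins >= 0
    n_vox = int(in_roi.sum())
    if n_vox == 0:
        raise ValueError("empty ROI: no discretized voxels")
    if n_levels is None:
        n_levels = int(bins.max()) + 1
    fams = ALL_FAMILIES if families is None else tuple(families)
    s, n = ngtdm(bins, n_levels) if "ngtdm" in fams else (np.zeros(n_levels), np.zeros(n_levels, dtype=np.int64))
    return TextureMatrixSet(
        n_levels=n_levels,
        n_voxels=n_vox,
        glcm_by_direction=(
            [glcm_direction(bins, n_levels, d) for d in DIRECTIONS_13] if "glcm" in fams else []
        ),
        glrlm_by_direction=(
            [glrlm_direction(bins, n_levels, d) for d in DIRECTIONS_13] if "glrlm" in fams else []
        ),
        glszm=glszm(bins, n_levels) if "glszm" in fams else np.zeros((n_levels, 1), dtype=np.int64),
        ngtdm_s=s,
        ngtdm_n=n,
        ngldm_by_alpha={a: ngldm(bins, n_levels, a) for a in alphas} if "ngldm" in fams else {},
    )
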