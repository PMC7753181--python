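"""Patch-based local radiomics on the GTV+Rim ROI.

The ROI is tiled with non-overlapping, axis-aligned 3x3x3 voxel blocks on a
lattice whose phase (offset in {0,1,2}^3) is chosen, by exhaustive search over
all 27 phases, to cover the ROI with the minimum number of blocks; ties break
toward the lexicographically smallest offset.  Blocks with fewer than 9
informative ROI voxels are discarded.  Retained blocks are labeled by their
fractional overlap with the GTV among their informative voxels: rim below the
lower cutoff, GTV above the upper cutoff, and mixed (discarded from analysis)
in between, including exact ties at either cutoff.

Per-patch feature values are computed on the informative voxels only, with
grey-level discretization anchored at the minimum intensity of the *entire*
re-segmented ROI, so local and global radiomics share one bin definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radiomap.features.manifest import FeatureManifest
from radiomap.features.panel import compute_features_on_values, resegment
from radiomap.imaging_io import MaskVolume, VolumeGrid

__all__ = [
    "Patch",
    "PatchGrid",
    "tile_patches",
    "label_patches",
    "compute_local_features",
    "global_roi_anchor",
]

LABEL_GTV = "GTV"
LABEL_RIM = "rim"
LABEL_MIXED = "mixed"
LABEL_SMALL = "discarded_small"


@dataclass
class Patch:
    """One lattice block: anchor = voxel index of its low corner (may be
    negative by up to edge-1 when the lattice phase shifts off the array)."""

    patch_id: int
    anchor: tuple[int, int, int]
    n_informative: int
    gtv_overlap: float = np.nan
    label: str = ""


@dataclass
class PatchGrid:
    """Non-overlapping cubic tiling of an ROI at the optimal lattice phase."""

    offset: tuple[int, int, int]
    edge: int
    shape: tuple[int, int, int]
    patches: list[Patch]

    @property
    def retained(self) -> list[Patch]:
        return [p for p in self.patches if p.label != LABEL_SMALL]

    def labeled(self, labels=(LABEL_GTV, LABEL_RIM)) -> list[Patch]:
        return [p for p in self.patches if p.label in labels]


def _block_index(coords: np.ndarray, offset: np.ndarray, edge: int) -> np.ndarray:
    return np.floor_divide(coords - offset, edge)


def tile_patches(roi: MaskVolume, edge: int = 3, min_informative: int = 9) -> PatchGrid:
    """Tile the ROI with non-overlapping ``edge``^3 blocks at the best lattice phase.

    All ``edge**3`` lattice phases are evaluated; the phase minimizing the
    number of blocks intersecting the ROI wins, ties broken by the
    lexicographically smallest offset.  Blocks under ``min_informative`` ROI
    voxels are flagged ``discarded_small`` (kept for bookkeeping, excluded
    from analysis).
    """
    coords = np.argwhere(roi.data)
    if coords.size == 0:
        raise ValueError("empty ROI")
    best_offset = None
    best_count = None
    for ox in range(edge):
        for oy in range(edge):
            for oz in range(edge):
                off = np.array([ox, oy, oz])
                blocks = _block_index(coords, off, edge)
                n_blocks = len(np.unique(blocks, axis=0))
                if best_count is None or n_blocks < best_count:
                    best_count = n_blocks
                    best_offset = (ox, oy, oz)
    off = np.array(best_offset)
    blocks = _block_index(coords, off, edge)
    uniq, counts = np.unique(blocks, axis=0, return_counts=True)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))
    patches = []
    for pid, idx in enumerate(order):
        b = uniq[idx]
        anchor = tuple(int(v) for v in (b * edge + off))
        n_inf = int(counts[idx])
        patches.append(
            Patch(
                patch_id=pid,
                anchor=anchor,
                n_informative=n_inf,
                label="" if n_inf >= min_informative else LABEL_SMALL,
            )
        )
    return PatchGrid(offset=tuple(best_offset), edge=edge, shape=roi.shape, patches=patches)


def _patch_voxels(patch: Patch, grid: PatchGrid, roi: np.ndarray) -> np.ndarray:
    """(n, 3) coordinates of the patch's informative (in-ROI) voxels."""
    a = np.array(patch.anchor)
    lo = np.maximum(a, 0)
    hi = np.minimum(a + grid.edge, grid.shape)
    sub = roi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return np.argwhere(sub) + lo


def label_patches(
    grid: PatchGrid,
    roi: MaskVolume,
    gtv: MaskVolume,
    low: float = 0.10,
    high: float = 0.90,
) -> PatchGrid:
    """Label retained patches rim/GTV/mixed by GTV overlap fraction.

    The denominator is the patch's informative ROI voxel count (edge patches
    contain non-ROI voxels that do not vote).  Strict inequalities: a fraction
    exactly at a cutoff is mixed and discarded.
    """
    if grid.shape != roi.shape or grid.shape != gtv.shape:
        raise ValueError("grid, ROI and GTV must share one array shape")
    for p in grid.patches:
        if p.label == LABEL_SMALL:
            continue
        vox = _patch_voxels(p, grid, roi.data)
        n_gtv = int(gtv.data[vox[:, 0], vox[:, 1], vox[:, 2]].sum())
        frac = n_gtv / p.n_informative
        p.gtv_overlap = frac
        p.label = LABEL_RIM if frac < low else (LABEL_GTV if frac > high else LABEL_MIXED)
    return grid


def compute_local_features(
    volume: VolumeGrid,
    grid: PatchGrid,
    roi: MaskVolume,
    manifest: FeatureManifest,
    global_anchor: float,
    bin_width: float = 20.0,
    hu_range: tuple[float, float] = (-1024.0, 200.0),
    patient_id: str = "",
) -> pd.DataFrame:
    """Per-patch feature values for retained GTV/rim patches.

    ``global_anchor`` must be the minimum HU of the whole re-segmented ROI so
    that all patches share one discretization.  Returns a tidy table with
    columns patient_id, patch_id, label, feature, value.
    """
    rows = []
    for p in grid.labeled():
        vox = _patch_voxels(p, grid, roi.data)
        hu = volume.data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(np.float64)
        keep = (hu >= hu_range[0]) & (hu <= hu_range[1])
        hu, vox = hu[keep], vox[keep]
        if hu.size == 0:
            continue
        feats = compute_features_on_values(
            hu, vox, grid.shape, manifest, bin_width=bin_width, anchor=global_anchor
        )
        for name, value in feats.items():
            rows.append(
                {
                    "patient_id": patient_id,
                    "patch_id": p.patch_id,
                    "label": p.label,
                    "feature": name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "patch_id", "label", "feature", "value"])


def global_roi_anchor(
    volume: VolumeGrid, roi: MaskVolume, hu_range: tuple[float, float] = (-1024.0, 200.0)
) -> float:
    """Minimum HU of the re-segmented ROI — the shared discretization anchor."""
    return float(resegment(volume, roi, *hu_range).values.min())
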