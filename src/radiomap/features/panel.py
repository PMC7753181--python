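"""End-to-end feature panel computation for one ROI of one patient.

Pipeline: HU re-segmentation (default window [-1024, 200] HU, removing bone
and dense structures that cannot be excluded manually) -> fixed-bin-size
discretization (default 20 HU, bin 0 anchored at the minimum intensity of the
ROI) -> first-order statistics on raw HU plus texture features on the
discretized grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radiomap.features.intensity import intensity_features
from radiomap.features.manifest import FeatureManifest, default_manifest
from radiomap.features.matrices import TextureMatrixSet, texture_matrices
from radiomap.features.texture import texture_features
from radiomap.imaging_io import MaskVolume, VolumeGrid

__all__ = [
    "ResegmentedROI",
    "DiscretizedROI",
    "FeatureVector",
    "resegment",
    "discretize_fbs",
    "compute_panel",
    "compute_features_on_values",
]

HU_RANGE_DEFAULT = (-1024.0, 200.0)
BIN_WIDTH_DEFAULT = 20.0


@dataclass
class ResegmentedROI:
    """In-mask voxels surviving the HU window, with their grid coordinates."""

    values: np.ndarray  # HU, 1D
    coords: np.ndarray  # (n, 3) voxel indices
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


@dataclass
class DiscretizedROI:
    """Fixed-bin-size discretization of a re-segmented ROI."""

    bins: np.ndarray  # 1D bin index per retained voxel
    coords: np.ndarray
    shape: tuple[int, int, int]
    bin_width: float
    anchor: float  # HU of the lower edge of bin 0

    @property
    def n_bins(self) -> int:
        return int(self.bins.max()) + 1

    def bins_array(self) -> np.ndarray:
        """Dense 3D bins array over the ROI bounding box, -1 outside the ROI."""
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0)
        arr = np.full(tuple(hi - lo + 1), -1, dtype=np.int64)
        rel = self.coords - lo
        arr[rel[:, 0], rel[:, 1], rel[:, 2]] = self.bins
        return arr


@dataclass
class FeatureVector:
    """Ordered feature values for one ROI of one patient."""

    names: tuple[str, ...]
    values: np.ndarray
    patient_id: str = ""
    roi_name: str = ""

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("feature names and values differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.patient_id)


def resegment(
    volume: VolumeGrid,
    mask: MaskVolume,
    hu_min: float = HU_RANGE_DEFAULT[0],
    hu_max: float = HU_RANGE_DEFAULT[1],
) -> ResegmentedROI:
    """Keep exactly the in-mask voxels with ``hu_min <= HU <= hu_max``."""
    if not volume.same_grid(mask):
        raise ValueError("volume and mask are not on the same grid")
    if not mask.data.any():
        raise ValueError("empty mask")
    inside = mask.data & (volume.data >= hu_min) & (volume.data <= hu_max)
    if not inside.any():
        raise ValueError("empty ROI after re-segmentation")
    coords = np.argwhere(inside)
    return ResegmentedROI(
        values=volume.data[inside].astype(np.float64),
        coords=coords,
        shape=volume.shape,
    )


def discretize_fbs(
    roi: ResegmentedROI,
    bin_width: float = BIN_WIDTH_DEFAULT,
    anchor: float | None = None,
) -> DiscretizedROI:
    """Fixed-bin-size discretization: ``bin(x) = floor((x - anchor)/width)``.

    By default the anchor is the ROI minimum, so the minimum maps to bin 0.
    Passing an explicit ``anchor`` (e.g. the minimum of a larger parent ROI)
    keeps bin identities comparable across sub-regions.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    if anchor is None:
        anchor = float(roi.values.min())
    bins = np.floor((roi.values - anchor) / bin_width).astype(np.int64)
    if bins.min() < 0:
        raise ValueError("anchor lies above some ROI intensities")
    return DiscretizedROI(
        bins=bins, coords=roi.coords, shape=roi.shape, bin_width=float(bin_width), anchor=anchor
    )


def _assemble(
    manifest: FeatureManifest,
    hu_values: np.ndarray,
    mats: TextureMatrixSet | None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for blk in manifest.blocks:
        if blk.family == "intensity":
            vals = intensity_features(hu_values, blk.features)
        elif mats is None:
            vals = {f: np.nan for f in blk.features}
        else:
            fam = texture_features(mats, blk.family, blk.aggregation, blk.alpha)
            vals = {f: fam[f] for f in blk.features}
        for bare, full in zip(blk.features, blk.names):
            out[full] = vals[bare]
    return out


def _needed_alphas(manifest: FeatureManifest) -> tuple[int, ...]:
    alphas = sorted({blk.alpha for blk in manifest.blocks if blk.family == "ngldm"})
    return tuple(alphas) if alphas else (0,)


def _needed_families(manifest: FeatureManifest) -> tuple[str, ...]:
    return tuple({blk.family for blk in manifest.blocks if blk.family != "intensity"})


def compute_features_on_values(
    hu_values: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int, int],
    manifest: FeatureManifest,
    bin_width: float = BIN_WIDTH_DEFAULT,
    anchor: float | None = None,
) -> dict[str, float]:
    """Compute manifest features on an explicit voxel set (used for patches).

    ``anchor`` fixes the discretization origin; pass the parent-ROI minimum so
    that bins are shared across patches rather than re-anchored per patch.
    """
    roi = ResegmentedROI(
        values=np.asarray(hu_values, dtype=np.float64),
        coords=np.asarray(coords),
        shape=shape,
    )
    needs_texture = any(blk.family != "intensity" for blk in manifest.blocks)
    mats = None
    if needs_texture and roi.n_voxels >= 2:
        d = discretize_fbs(roi, bin_width=bin_width, anchor=anchor)
        mats = texture_matrices(
            d.bins_array(), alphas=_needed_alphas(manifest), families=_needed_families(manifest)
        )
    return _assemble(manifest, roi.values, mats)


def compute_panel(
    volume: VolumeGrid,
    mask: MaskVolume,
    manifest: FeatureManifest | None = None,
    hu_range: tuple[float, float] = HU_RANGE_DEFAULT,
    bin_width: float = BIN_WIDTH_DEFAULT,
    patient_id: str = "",
    roi_name: str = "",
) -> FeatureVector:
    """Compute the full feature panel for one ROI of one patient."""
    if manifest is None:
        manifest = default_manifest()
    try:
        roi = resegment(volume, mask, *hu_range)
    except ValueError as err:
        raise ValueError(f"patient={patient_id!r} roi={roi_name!r}: {err}") from err
    mats = None
    if any(blk.family != "intensity" for blk in manifest.blocks) and roi.n_voxels >= 2:
        d = discretize_fbs(roi, bin_width=bin_width)
        mats = texture_matrices(
            d.bins_array(), alphas=_needed_alphas(manifest), families=_needed_families(manifest)
        )
    feats = _assemble(manifest, roi.values, mats)
    names = manifest.names
    return FeatureVector(
        names=names,
        values=np.array([feats[n] for n in names], dtype=np.float64),
        patient_id=patient_id,
        roi_name=roi_name,
    )
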