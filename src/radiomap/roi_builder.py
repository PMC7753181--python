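"""Construction of the five analysis ROIs from a gross tumor volume (GTV) mask.

The peritumoral regions are defined by metric morphology in physical mm
(Euclidean distance between voxel centers, so anisotropic grids are handled
correctly):

- ``gtv``           — the tumor mask as delineated
- ``lung_exterior`` — 8 mm expansion from the GTV restricted to lung tissue
- ``iso_exterior``  — 8 mm expansion from the GTV into lung and soft tissue
- ``gradient``      — band from a 4 mm contraction to an 8 mm expansion of the GTV
- ``gtv_plus_rim``  — union of GTV and iso_exterior

Structures that would disturb the analysis (bronchi, bone) are removed via a
user-supplied exclusion mask subtracted from every peritumoral ROI.  A patient
whose GTV vanishes entirely under the 4 mm contraction carries no interior
voxels to contrast against the border band; such cases are flagged
``gradient_excluded`` and skipped for gradient-ROI analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from radiomap.imaging_io import MaskVolume, VolumeGrid

__all__ = [
    "MorphologyParams",
    "ROISet",
    "expand_metric",
    "contract_metric",
    "build_roi_set",
    "lung_mask_from_hu",
]


@dataclass(frozen=True)
class MorphologyParams:
    """Metric margins (mm) for peritumoral ROI construction."""

    expansion_mm: float = 8.0
    contraction_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.expansion_mm <= 0 or self.contraction_mm <= 0:
            raise ValueError("morphology margins must be > 0")


@dataclass
class ROISet:
    """The five named analysis masks for one patient, on one grid."""

    gtv: MaskVolume
    lung_exterior: MaskVolume
    iso_exterior: MaskVolume
    gradient: MaskVolume
    gtv_plus_rim: MaskVolume
    gradient_excluded: bool

    def as_dict(self) -> dict[str, MaskVolume]:
        return {
            "gtv": self.gtv,
            "lung_exterior": self.lung_exterior,
            "iso_exterior": self.iso_exterior,
            "gradient": self.gradient,
            "gtv_plus_rim": self.gtv_plus_rim,
        }

    def voxel_counts(self) -> dict[str, int]:
        return {name: roi.n_voxels for name, roi in self.as_dict().items()}


def _distance_to_foreground(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest foreground center."""
    if not mask.any():
        raise ValueError("empty mask has no foreground to measure distance to")
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def expand_metric(mask: MaskVolume, r: float) -> MaskVolume:
    """Expand a mask by ``r`` mm (Euclidean, voxel-center metric).

    The result contains the original foreground plus every voxel whose center
    lies within ``r`` mm of some foreground voxel center.
    """
    if r < 0:
        raise ValueError("expansion radius must be >= 0")
    dist = _distance_to_foreground(mask.data, mask.spacing)
    return MaskVolume(data=dist <= r, spacing=mask.spacing, origin=mask.origin)


def contract_metric(mask: MaskVolume, r: float) -> MaskVolume:
    """Contract a mask by ``r`` mm; keeps foreground voxels whose distance to
    the nearest background voxel center exceeds ``r``.  May be empty."""
    if r < 0:
        raise ValueError("contraction radius must be >= 0")
    if not mask.data.any():
        return MaskVolume(data=np.zeros_like(mask.data, dtype=bool), spacing=mask.spacing, origin=mask.origin)
    if mask.data.all():
        return MaskVolume(data=mask.data.copy(), spacing=mask.spacing, origin=mask.origin)
    dist_bg = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return MaskVolume(data=dist_bg > r, spacing=mask.spacing, origin=mask.origin)


def build_roi_set(
    gtv: MaskVolume,
    lung: MaskVolume,
    exclusion: MaskVolume | None = None,
    params: MorphologyParams = MorphologyParams(),
) -> ROISet:
    """Build the five analysis ROIs from the GTV on its native grid."""
    if not gtv.data.any():
        raise ValueError("empty GTV")
    for other, name in ((lung, "lung"), (exclusion, "exclusion")):
        if other is not None and not gtv.same_grid(other):
            raise ValueError(f"{name} mask is not on the GTV grid")
    excl = np.zeros_like(gtv.data) if exclusion is None else exclusion.data

    expanded = expand_metric(gtv, params.expansion_mm).data
    contracted = contract_metric(gtv, params.contraction_mm).data

    iso_ext = expanded & ~gtv.data & ~excl
    lung_ext = iso_ext & lung.data
    gradient = (expanded & ~contracted) & ~excl
    gtv_plus_rim = (gtv.data | iso_ext) & ~excl

    def _mk(arr: np.ndarray) -> MaskVolume:
        return MaskVolume(data=arr, spacing=gtv.spacing, origin=gtv.origin)

    return ROISet(
        gtv=gtv,
        lung_exterior=_mk(lung_ext),
        iso_exterior=_mk(iso_ext),
        gradient=_mk(gradient),
        gtv_plus_rim=_mk(gtv_plus_rim),
        gradient_excluded=not contracted.any(),
    )


def lung_mask_from_hu(
    volume: VolumeGrid,
    threshold_hu: float = -500.0,
    n_components: int = 2,
    min_fraction: float = 0.05,
) -> MaskVolume:
    """Approximate lung mask by HU thresholding (foreground = HU < threshold).

    Keeps the largest 26-connected components (up to ``n_components``) whose
    size is at least ``min_fraction`` of the largest.  This is a coarse
    stand-in for an anatomical lung segmentation — adequate to restrict
    peritumoral expansion to low-density tissue, not for lung volumetry.
    """
    fg = volume.data < threshold_hu
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return MaskVolume(data=fg, spacing=volume.spacing, origin=volume.origin)
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    keep = [order[0] + 1]
    for idx in order[1:n_components]:
        if sizes[idx] >= min_fraction * sizes[order[0]]:
            keep.append(idx + 1)
    out = np.isin(labels, keep)
    return MaskVolume(data=out, spacing=volume.spacing, origin=volume.origin)
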