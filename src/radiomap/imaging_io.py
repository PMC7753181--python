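"""NIfTI volume/mask I/O, grid bookkeeping, and isotropic resampling.

Conventions
-----------
Arrays are ordered ``(x, y, z)``; images are reoriented to the closest
canonical (RAS) orientation on read so that axis order and voxel spacing are
well defined regardless of how the file was stored.  ``spacing`` is mm per
voxel along each axis and ``origin`` is the physical position (mm) of the
center of voxel ``(0, 0, 0)``.  Voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing``.

Resampling preserves the origin and covers the full physical extent of the
input grid: the output size along each axis is ``ceil(n * spacing / target)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "resample_mask",
]

AXIS_ORDER = "xyz"


@dataclass
class VolumeGrid:
    """A 3D scalar field (HU) with physical spacing and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("volume must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "VolumeGrid | MaskVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class MaskVolume:
    """A binary mask sharing the grid of a companion :class:`VolumeGrid`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "VolumeGrid | MaskVolume", tol: float = 1e-6) -> bool:
        return VolumeGrid.same_grid(self, other, tol)  # type: ignore[arg-type]


def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI scalar image; HU values are passed through unmodified."""
    data, spacing, origin = _load_canonical(path)
    return VolumeGrid(data=data, spacing=spacing, origin=origin)


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> MaskVolume:
    """Read a binary NIfTI mask (values must be 0/1)."""
    data, spacing, origin = _load_canonical(path)
    return MaskVolume(data=data, spacing=spacing, origin=origin)


def write_mask(mask: MaskVolume, path: str | Path, data: np.ndarray | None = None) -> None:
    """Write a mask (or an integer label field sharing its grid) as uint8 NIfTI."""
    arr = mask.data.astype(np.uint8) if data is None else np.asarray(data, dtype=np.uint8)
    img = nib.Nifti1Image(arr, _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _resample_field(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    target: float,
    order: int,
) -> np.ndarray:
    extent = np.asarray(data.shape) * np.asarray(spacing)
    out_shape = np.ceil(extent / target - 1e-9).astype(int)
    out_shape = np.maximum(out_shape, 1)
    # output voxel centers in input index coordinates
    grids = [np.arange(n) * target / sp for n, sp in zip(out_shape, spacing)]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(
        data.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )


def resample_isotropic(volume: VolumeGrid, target: float, mode: str = "linear") -> VolumeGrid:
    """Resample a volume to cubic voxels of ``target`` mm.

    ``mode='linear'`` is trilinear interpolation (used for intensities, no
    overshoot); ``mode='nearest'`` is nearest neighbour.  The output origin
    equals the input origin and the output covers the input extent.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be > 0, got {target}")
    order = {"linear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown resampling mode {mode!r}")
    out = _resample_field(volume.data, volume.spacing, target, order)
    return VolumeGrid(data=out, spacing=(target,) * 3, origin=volume.origin)


def resample_mask(mask: MaskVolume, target: float, mode: str = "linear_threshold") -> MaskVolume:
    """Resample a binary mask to cubic voxels of ``target`` mm.

    Default is linear interpolation of the 0/1 field followed by a >= 0.5
    threshold; ``mode='nearest'`` selects nearest-neighbour instead.  Output
    values are strictly binary either way.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be > 0, got {target}")
    if mode == "nearest":
        out = _resample_field(mask.data.astype(np.float64), mask.spacing, target, 0) > 0.5
    elif mode == "linear_threshold":
        out = _resample_field(mask.data.astype(np.float64), mask.spacing, target, 1) >= 0.5
    else:
        raise ValueError(f"unknown mask resampling mode {mode!r}")
    return MaskVolume(data=out, spacing=(target,) * 3, origin=mask.origin)
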