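"""Synthetic lung-CT phantom cohorts with controllable texture placement.

Each case emulates the coarse statistics of a lung-window CT: a noisy
low-density lung background, a soft-tissue plateau along one face of the
grid, and a quasi-spherical tumor of near-water density.  Class-dependent
texture is synthesized as a correlated Gaussian random field (white noise
convolved with an isotropic Gaussian kernel, then renormalized to a target
standard deviation): the kernel width controls the spatial correlation
length and hence the zone-size structure that size-zone texture features
respond to.  The contrast parameters place the class difference selectively:

- ``kappa_rim``  — extra correlation length (mm) class 1 receives in the
  peritumoral shell;
- ``kappa_core`` — the same, inside the tumor.

With both at zero the two classes are distributionally identical (a null
construction).  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from radiomap.imaging_io import MaskVolume, VolumeGrid, write_mask, write_volume

__all__ = ["PhantomParams", "PhantomCase", "generate_case", "generate_cohort", "write_cohort"]

HU_CLIP = (-1024.0, 3071.0)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, tissue plateaus (HU) and texture contrast of the phantom."""

    shape: tuple[int, int, int] = (56, 56, 48)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    tumor_radius_mm: float = 20.0
    tumor_radius_jitter_mm: float = 3.0
    center_jitter_mm: float = 3.0
    lung_mean_hu: float = -850.0
    lung_sd_hu: float = 60.0
    soft_tissue_hu: float = 40.0
    soft_tissue_sd_hu: float = 10.0
    soft_tissue_fraction: float = 0.18  # slab thickness as fraction of x extent
    tumor_mean_hu: float = 0.0
    tumor_sd_hu: float = 40.0
    rim_width_mm: float = 10.0
    base_corr_mm: float = 1.0
    kappa_rim: float = 0.0
    kappa_core: float = 0.0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("phantom grid too small")
        if self.kappa_rim < 0 or self.kappa_core < 0:
            raise ValueError("texture contrast parameters must be >= 0")


@dataclass
class PhantomCase:
    """One synthetic patient: CT volume, GTV and lung masks, class label."""

    patient_id: str
    volume: VolumeGrid
    gtv: MaskVolume
    lung: MaskVolume
    class_label: int
    params: PhantomParams


def _correlated_field(shape, spacing, sigma_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with correlation length sigma_mm."""
    white = rng.standard_normal(shape)
    if sigma_mm <= 0:
        return white
    sigma_vox = [sigma_mm / s for s in spacing]
    f = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_case(params: PhantomParams, label: int, seed: int, patient_id: str | None = None) -> PhantomCase:
    """Generate one phantom case; bit-identical for fixed params/label/seed."""
    if label not in (0, 1):
        raise ValueError("class label must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = params.shape
    spacing = np.asarray(params.spacing)
    extent = np.asarray(shape) * spacing

    radius = params.tumor_radius_mm + rng.uniform(-1, 1) * params.tumor_radius_jitter_mm
    center = extent / 2 + rng.uniform(-1, 1, size=3) * params.center_jitter_mm
    clearance = np.minimum(center, extent - center) - radius
    if clearance.min() < 10.0:
        raise ValueError("tumor does not fit inside the grid with 10 mm clearance")

    idx = np.indices(shape, dtype=np.float64)
    pos = idx * spacing[:, None, None, None]
    dist = np.sqrt(((pos - center[:, None, None, None]) ** 2).sum(axis=0))

    gtv = dist <= radius
    slab_x = extent[0] * (1.0 - params.soft_tissue_fraction)
    slab = pos[0] >= slab_x
    lung = ~gtv & ~slab
    rim = (dist > radius) & (dist <= radius + params.rim_width_mm)

    # background lung: short-range correlated noise
    data = params.lung_mean_hu + params.lung_sd_hu * _correlated_field(
        shape, spacing, params.base_corr_mm, rng
    )
    # class-dependent rim texture (lung part of the shell only)
    rim_sigma = params.base_corr_mm + (params.kappa_rim if label == 1 else 0.0)
    rim_field = _correlated_field(shape, spacing, rim_sigma, rng)
    rim_lung = rim & lung
    data[rim_lung] = params.lung_mean_hu + params.lung_sd_hu * rim_field[rim_lung]
    # soft-tissue plateau
    slab_noise = rng.standard_normal(shape)
    data[slab] = params.soft_tissue_hu + params.soft_tissue_sd_hu * slab_noise[slab]
    # tumor core texture
    core_sigma = params.base_corr_mm + (params.kappa_core if label == 1 else 0.0)
    core_field = _correlated_field(shape, spacing, core_sigma, rng)
    data[gtv] = params.tumor_mean_hu + params.tumor_sd_hu * core_field[gtv]

    data = np.clip(data, *HU_CLIP)
    sp = tuple(float(s) for s in params.spacing)
    return PhantomCase(
        patient_id=patient_id or f"case_{seed}",
        volume=VolumeGrid(data=data, spacing=sp),
        gtv=MaskVolume(data=gtv, spacing=sp),
        lung=MaskVolume(data=lung, spacing=sp),
        class_label=label,
        params=params,
    )


def generate_cohort(
    n_per_class: int,
    params: PhantomParams,
    seed: int,
    cohort_tag: str = "training",
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Balanced cohort with independent per-case seeds derived from the master seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    cases = []
    rows = []
    i = 0
    for label in (0, 1):
        for j in range(n_per_class):
            pid = f"{cohort_tag}_{label}_{j:03d}"
            cases.append(generate_case(params, label, int(case_seeds[i]), patient_id=pid))
            rows.append({"patient_id": pid, "label": label, "cohort": cohort_tag})
            i += 1
    return cases, pd.DataFrame(rows)


def write_cohort(cases: list[PhantomCase], labels: pd.DataFrame, out_dir: str | Path) -> pd.DataFrame:
    """Write NIfTI volumes/masks plus a labels table; returns a path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        ct = out / f"{case.patient_id}_ct.nii.gz"
        gtv = out / f"{case.patient_id}_gtv.nii.gz"
        lung = out / f"{case.patient_id}_lung.nii.gz"
        write_volume(case.volume, ct)
        write_mask(case.gtv, gtv)
        write_mask(case.lung, lung)
        rows.append(
            {
                "patient_id": case.patient_id,
                "ct": str(ct),
                "gtv": str(gtv),
                "lung": str(lung),
                "label": case.class_label,
            }
        )
    manifest = pd.DataFrame(rows).merge(labels[["patient_id", "cohort"]], on="patient_id")
    manifest.to_csv(out / "labels.csv", index=False)
    return manifest
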