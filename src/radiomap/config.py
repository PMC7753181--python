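"""Structured study configuration with provenance hashing.

All defaults are the workflow's standard analysis constants: 3.75 mm
resampling, [-1024, 200] HU re-segmentation, 20 HU bins, 8 mm expansion,
4 mm contraction, 3-voxel patch edge, 9-voxel informative minimum,
10%/90% overlap cutoffs, 27/3 patch eligibility, ICC > 0.9 stability,
95% PCA variance, alpha = 0.05, 5-fold CV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["StudyConfig"]


@dataclass(frozen=True)
class StudyConfig:
    resample_spacing: float = 3.75        # mm, cubic voxels
    hu_range: tuple[float, float] = (-1024.0, 200.0)
    bin_width: float = 20.0               # HU
    expansion_mm: float = 8.0
    contraction_mm: float = 4.0
    patch_edge: int = 3                   # voxels
    min_informative: int = 9              # voxels per patch
    overlap_low: float = 0.10
    overlap_high: float = 0.90
    min_total_patches: int = 27
    min_region_patches: int = 3
    icc_cutoff: float = 0.9
    pca_variance: float = 0.95
    alpha: float = 0.05
    cv_folds: int = 5
    mask_resampling: str = "linear_threshold"  # or "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resample_spacing <= 0 or self.bin_width <= 0:
            raise ValueError("spacings and bin width must be positive")
        if not 0 <= self.overlap_low < self.overlap_high <= 1:
            raise ValueError("overlap cutoffs must satisfy 0 <= low < high <= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hu_range"] = list(d["hu_range"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "StudyConfig":
        if "hu_range" in kwargs:
            kwargs["hu_range"] = tuple(kwargs["hu_range"])
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls().with_overrides(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
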