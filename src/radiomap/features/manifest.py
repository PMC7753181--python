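"""Declarative feature-panel manifest.

The default panel (shipped as ``radiomap/data/default154.yaml``) enumerates
exactly 154 features: 17 first-order intensity statistics plus 137 texture
features across GLCM, GLRLM, GLSZM, NGTDM and NGLDM (including merged-3D and
direction-averaged aggregation variants).  The panel is swappable: any YAML
file with the same schema can be loaded in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["FeatureBlock", "FeatureManifest", "default_manifest", "load_manifest"]

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "ngldm")

#: features the per-ROI signature models rely on; the default panel must carry them
REQUIRED_FEATURES = (
    "glrlm_run_entropy",
    "glcm_inverse_variance",
    "glszm_zone_percentage",
    "glcm_contrast",
    "glcm_inverse_difference_normalized",  # a.k.a. homogeneity normalized
    "ngldm_low_dependence_emphasis",
    "intensity_median",
    "glcm_correlation",
    "glszm_zone_size_nonuniformity_norm",
    "intensity_percentile_90",
)


@dataclass(frozen=True)
class FeatureBlock:
    """One family block of the panel: a family, its parameters, its features."""

    family: str
    prefix: str
    features: tuple[str, ...]
    aggregation: str = "merged"  # glcm/glrlm only
    alpha: int = 0  # ngldm only

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f"{self.prefix}_{f}" for f in self.features)


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered collection of feature blocks defining the panel."""

    name: str
    blocks: tuple[FeatureBlock, ...]

    def __post_init__(self) -> None:
        names = self.names
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in manifest: {dupes}")
        for blk in self.blocks:
            if blk.family != "intensity" and blk.family not in TEXTURE_FAMILIES:
                raise ValueError(f"unknown feature family {blk.family!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for blk in self.blocks for n in blk.names)

    @property
    def intensity_names(self) -> tuple[str, ...]:
        return tuple(n for blk in self.blocks if blk.family == "intensity" for n in blk.names)

    @property
    def texture_names(self) -> tuple[str, ...]:
        return tuple(n for blk in self.blocks if blk.family != "intensity" for n in blk.names)

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: list[str] | tuple[str, ...]) -> "FeatureManifest":
        """Restrict the manifest to the given feature names (order preserved per block)."""
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise KeyError(f"features not in manifest: {sorted(missing)}")
        blocks = []
        for blk in self.blocks:
            keep = tuple(f for f, full in zip(blk.features, blk.names) if full in wanted)
            if keep:
                blocks.append(
                    FeatureBlock(
                        family=blk.family,
                        prefix=blk.prefix,
                        features=keep,
                        aggregation=blk.aggregation,
                        alpha=blk.alpha,
                    )
                )
        return FeatureManifest(name=f"{self.name}_subset", blocks=tuple(blocks))


def _parse(doc: dict, name_fallback: str) -> FeatureManifest:
    blocks = []
    for raw in doc["blocks"]:
        blocks.append(
            FeatureBlock(
                family=raw["family"],
                prefix=raw["prefix"],
                features=tuple(raw["features"]),
                aggregation=raw.get("aggregation", "merged"),
                alpha=int(raw.get("alpha", 0)),
            )
        )
    return FeatureManifest(name=doc.get("name", name_fallback), blocks=tuple(blocks))


def load_manifest(path: str | Path) -> FeatureManifest:
    """Load a feature manifest from a YAML file."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh), Path(path).stem)


def default_manifest() -> FeatureManifest:
    """The shipped 154-feature default panel (17 intensity + 137 texture)."""
    text = resources.files("radiomap").joinpath("data/default154.yaml").read_text()
    manifest = _parse(yaml.safe_load(text), "default154")
    names = set(manifest.names)
    missing = [f for f in REQUIRED_FEATURES if f not in names]
    if missing:  # shipped file is broken — fail loudly
        raise RuntimeError(f"default manifest lacks required model features: {missing}")
    return manifest
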