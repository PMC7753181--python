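"""End-to-end study orchestration: ROIs -> features -> models -> activation maps.

`run_study` reproduces the full workflow on any cohort of (CT, GTV, lung,
optional exclusion) cases with binary class labels and training/validation
tags: it builds the five analysis ROIs per patient, extracts the global
feature panel per ROI, fits a logistic signature per ROI on the training
cohort (PCA surrogates -> univariate screen -> backward AIC), evaluates on
training and validation with DeLong CIs and 5-fold CV, and runs the
patch-based activation-map analysis on the GTV+Rim region for the final
model's features.  Per-patient failures are isolated, logged and reported in
an exclusions table; everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from radiomap import activation_maps as amap
from radiomap import local_radiomics as lr
from radiomap import signature_modeling as sig
from radiomap.config import StudyConfig
from radiomap.features import FeatureManifest, compute_panel, default_manifest
from radiomap.imaging_io import MaskVolume, VolumeGrid, resample_isotropic, resample_mask
from radiomap.roi_builder import MorphologyParams, build_roi_set

__all__ = ["StudyCase", "prepare_case", "extract_case_features", "feature_table",
           "model_roi", "activation_analysis", "run_study"]

log = logging.getLogger(__name__)

ROI_NAMES = ("gtv", "lung_exterior", "iso_exterior", "gradient", "gtv_plus_rim")


@dataclass
class StudyCase:
    """One patient's inputs on a shared native grid."""

    patient_id: str
    volume: VolumeGrid
    gtv: MaskVolume
    lung: MaskVolume
    exclusion: MaskVolume | None = None
    label: int | None = None
    cohort: str = "training"


@dataclass
class PreparedCase:
    """Resampled volume and ROI masks ready for feature extraction."""

    patient_id: str
    volume_iso: VolumeGrid
    rois_iso: dict[str, MaskVolume]
    gradient_excluded: bool
    label: int | None
    cohort: str


def prepare_case(case: StudyCase, config: StudyConfig) -> PreparedCase:
    """Build ROIs on the native grid (metric margins), then resample everything.

    ROI construction happens before resampling so that the 8 mm / 4 mm
    margins are exact in physical mm; masks follow to the isotropic grid via
    linear interpolation + 0.5 threshold (configurable to nearest neighbour).
    """
    rois = build_roi_set(
        case.gtv,
        case.lung,
        case.exclusion,
        MorphologyParams(config.expansion_mm, config.contraction_mm),
    )
    vol_iso = resample_isotropic(case.volume, config.resample_spacing, mode="linear")
    rois_iso = {
        name: resample_mask(mask, config.resample_spacing, mode=config.mask_resampling)
        for name, mask in rois.as_dict().items()
    }
    return PreparedCase(
        patient_id=case.patient_id,
        volume_iso=vol_iso,
        rois_iso=rois_iso,
        gradient_excluded=rois.gradient_excluded,
        label=case.label,
        cohort=case.cohort,
    )


def extract_case_features(
    prep: PreparedCase,
    manifest: FeatureManifest,
    config: StudyConfig,
    rois: tuple[str, ...] = ROI_NAMES,
) -> dict[str, pd.Series]:
    """Global panel per ROI; gradient skipped when the contraction emptied the GTV."""
    out: dict[str, pd.Series] = {}
    for roi_name in rois:
        if roi_name == "gradient" and prep.gradient_excluded:
            log.info("patient %s: gradient ROI excluded (contraction empties GTV)", prep.patient_id)
            continue
        fv = compute_panel(
            prep.volume_iso,
            prep.rois_iso[roi_name],
            manifest,
            hu_range=config.hu_range,
            bin_width=config.bin_width,
            patient_id=prep.patient_id,
            roi_name=roi_name,
        )
        out[roi_name] = fv.to_series()
    return out


def feature_table(
    prepared: list[PreparedCase],
    manifest: FeatureManifest,
    config: StudyConfig,
    rois: tuple[str, ...] = ROI_NAMES,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Wide per-ROI feature tables plus an exclusions table of failed cases."""
    rows: dict[str, list[pd.Series]] = {r: [] for r in rois}
    meta: dict[str, list[dict]] = {r: [] for r in rois}
    exclusions = []
    for prep in prepared:
        try:
            feats = extract_case_features(prep, manifest, config, rois)
        except ValueError as err:
            log.warning("patient %s excluded: %s", prep.patient_id, err)
            exclusions.append({"patient_id": prep.patient_id, "reason": str(err)})
            continue
        for roi_name, series in feats.items():
            rows[roi_name].append(series)
            meta[roi_name].append(
                {"patient_id": prep.patient_id, "label": prep.label, "cohort": prep.cohort}
            )
    tables = {}
    for roi_name in rois:
        if not rows[roi_name]:
            continue
        df = pd.DataFrame(rows[roi_name]).reset_index(drop=True)
        info = pd.DataFrame(meta[roi_name])
        tables[roi_name] = pd.concat([info, df], axis=1)
    return tables, pd.DataFrame(exclusions, columns=["patient_id", "reason"])


def _finite_features(df: pd.DataFrame, names: list[str]) -> list[str]:
    """Features finite in every patient (sentinel-valued features are dropped)."""
    return [f for f in names if np.isfinite(df[f].to_numpy(dtype=np.float64)).all()]


def model_roi(
    table: pd.DataFrame,
    feature_names: list[str],
    config: StudyConfig,
    stable_features: list[str] | None = None,
    run_cv: bool = True,
) -> dict:
    """Fit and evaluate the signature chain for one ROI table.

    ``table`` must carry patient_id/label/cohort plus feature columns; the
    training cohort drives every selection step.
    """
    train = table[table["cohort"] == "training"].reset_index(drop=True)
    valid = table[table["cohort"] == "validation"].reset_index(drop=True)
    pool = list(feature_names)
    if stable_features is not None:
        pool = [f for f in pool if f in set(stable_features)]
    pool = _finite_features(train, pool)
    if not pool:
        raise ValueError("no usable features after robustness/missingness filtering")
    surrogates = sig.pca_surrogates(train, pool, variance_kept=config.pca_variance)
    screen = sig.univariate_screen(train, surrogates, alpha=config.alpha)
    kept = screen[screen["keep"]]["feature"].tolist()
    if kept:
        model = sig.backward_aic(train, kept)
    else:  # nothing passes the screen: the signature is the intercept-only model
        model = sig.ModelSpec(intercept=0.0, coefficients={})
    cv = None
    if run_cv:
        try:
            cv = sig.cross_validate(
                train, surrogates, k=config.cv_folds, seed=config.seed, alpha=config.alpha
            )
        except ValueError as err:  # e.g. cohort too small for class-balanced folds
            log.warning("cross-validation skipped: %s", err)
            cv = {"error": str(err)}
    result = {
        "n_pool": len(pool),
        "surrogates": surrogates,
        "screen": screen.to_dict(orient="records"),
        "model": model.to_dict(),
        "train_eval": sig.evaluate(model, train),
        "cv": cv,
    }
    # an intercept-only model is still evaluable: constant score, AUC 0.5
    if len(valid) and valid["label"].nunique() == 2:
        result["validation_eval"] = sig.evaluate(model, valid)
    else:
        result["validation_eval"] = None
    return result


def activation_analysis(
    prepared: list[PreparedCase],
    feature_name: str,
    global_table: pd.DataFrame,
    manifest: FeatureManifest,
    config: StudyConfig,
    roi_name: str = "gtv_plus_rim",
    compare_cohort: str = "validation",
) -> dict:
    """Patch-based activation-map analysis of one feature on the GTV+Rim ROI.

    The binarization threshold is the training-cohort median of the global
    feature; activation ratios are compared between classes in
    ``compare_cohort`` with the Wilcoxon rank-sum test.
    """
    train_vals = global_table.loc[global_table["cohort"] == "training", feature_name]
    thr = amap.fit_threshold(train_vals, feature_name)
    sub_manifest = manifest.subset([feature_name])
    tables = []
    labels_by_pid: dict[str, int] = {}
    patch_stats = []
    for prep in prepared:
        roi = prep.rois_iso[roi_name]
        vol = prep.volume_iso
        reseg = MaskVolume(
            data=roi.data & (vol.data >= config.hu_range[0]) & (vol.data <= config.hu_range[1]),
            spacing=roi.spacing,
            origin=roi.origin,
        )
        if not reseg.data.any():
            log.warning("patient %s: empty GTV+Rim after re-segmentation", prep.patient_id)
            continue
        grid = lr.tile_patches(reseg, edge=config.patch_edge, min_informative=config.min_informative)
        grid = lr.label_patches(
            grid, reseg, prep.rois_iso["gtv"], low=config.overlap_low, high=config.overlap_high
        )
        anchor = lr.global_roi_anchor(vol, reseg, hu_range=config.hu_range)
        table = lr.compute_local_features(
            vol, grid, reseg, sub_manifest, anchor,
            bin_width=config.bin_width, hu_range=config.hu_range, patient_id=prep.patient_id,
        )
        if table.empty:
            continue
        tables.append(table)
        labels_by_pid[prep.patient_id] = prep.label
        patch_stats.append(
            {
                "patient_id": prep.patient_id,
                "cohort": prep.cohort,
                "n_patches": len(grid.retained),
                "n_labeled": len(grid.labeled()),
            }
        )
    if not tables:
        raise ValueError("no patients with usable patches")
    patches = pd.concat(tables, ignore_index=True)
    flagged = amap.binarize(patches, thr)
    summaries = amap.summarize(
        flagged,
        min_total=config.min_total_patches,
        min_region=config.min_region_patches,
        class_labels=labels_by_pid,
    )
    cohort_of = {s["patient_id"]: s["cohort"] for s in patch_stats}
    compare = [s for s in summaries if cohort_of.get(s.patient_id) == compare_cohort]
    tests = {}
    for region in ("rim", "GTV"):
        try:
            tests[region] = amap.compare_groups(compare, region)
        except ValueError as err:
            tests[region] = {"error": str(err)}
    return {
        "feature": feature_name,
        "threshold": thr.threshold,
        "summaries": [
            {
                "patient_id": s.patient_id,
                "cohort": cohort_of.get(s.patient_id),
                "label": s.class_label,
                "eligible": s.eligible,
                "rim_ratio": s.ratio("rim"),
                "gtv_ratio": s.ratio("GTV"),
                "n_total": dict(s.n_total),
            }
            for s in summaries
        ],
        "tests": tests,
    }


def run_study(
    cases: list[StudyCase],
    config: StudyConfig | None = None,
    manifest: FeatureManifest | None = None,
    rois: tuple[str, ...] = ROI_NAMES,
    observer_tables: list[pd.DataFrame] | None = None,
) -> dict:
    """Full workflow on a cohort of cases; returns a JSON-serializable report."""
    config = config or StudyConfig()
    manifest = manifest or default_manifest()
    prepared = []
    exclusions = []
    for case in cases:
        try:
            prepared.append(prepare_case(case, config))
        except ValueError as err:
            log.warning("patient %s excluded at ROI stage: %s", case.patient_id, err)
            exclusions.append({"patient_id": case.patient_id, "reason": str(err)})
    tables, feat_excl = feature_table(prepared, manifest, config, rois)
    exclusions.extend(feat_excl.to_dict(orient="records"))

    stable = None
    icc_summary = None
    if observer_tables is not None:
        icc_results = sig.icc_filter(observer_tables, cutoff=config.icc_cutoff)
        stable = [r.feature_name for r in icc_results if r.stable]
        icc_summary = {
            "n_features": len(icc_results),
            "n_stable": len(stable),
            "stable_fraction": len(stable) / len(icc_results) if icc_results else np.nan,
        }

    texture_names = [n for n in manifest.names if not n.startswith("intensity_")]
    models = {}
    for roi_name, table in tables.items():
        try:
            models[roi_name] = model_roi(table, list(manifest.names), config, stable)
        except ValueError as err:
            models[roi_name] = {"error": str(err)}

    activation = None
    if "gtv_plus_rim" in tables and isinstance(models.get("gtv_plus_rim"), dict):
        spec = models["gtv_plus_rim"].get("model", {})
        model_feats = list(spec.get("coefficients", {}))
        texture_feats = [f for f in model_feats if f in set(texture_names)]
        feature = texture_feats[0] if texture_feats else (model_feats[0] if model_feats else None)
        from_model = feature is not None
        if feature is None and "glszm_zone_size_nonuniformity_norm" in manifest.names:
            # intercept-only signature: map the canonical size-zone texture feature
            feature = "glszm_zone_size_nonuniformity_norm"
        if feature is not None:
            activation = activation_analysis(
                prepared, feature, tables["gtv_plus_rim"], manifest, config
            )
            activation["feature_from_model"] = from_model

    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "n_patients": len(cases),
        "exclusions": exclusions,
        "gradient_excluded": [p.patient_id for p in prepared if p.gradient_excluded],
        "icc": icc_summary,
        "models": models,
        "activation": activation,
    }
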