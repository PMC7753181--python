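# Methods

This note documents the models, conventions, defaults and numerical choices
behind `radiomap`, and what the synthetic studies do and do not demonstrate.

## Grids, I/O and resampling

Arrays are ordered `(x, y, z)`; NIfTI images are reoriented to the closest
canonical (RAS) orientation on read. A voxel `(i, j, k)` sits at
`origin + (i, j, k) · spacing` (mm). Resampling to isotropic voxels (default
**3.75 mm**) uses trilinear interpolation for intensities (monotone — no
overshoot) and, for masks, trilinear interpolation of the 0/1 field followed
by a ≥ 0.5 threshold (nearest-neighbour available via
`StudyConfig.mask_resampling`). The output grid keeps the input origin and
has `ceil(extent / target)` voxels per axis, so the physical extent is
always covered; this rule is deterministic and avoids half-voxel drift.

ROIs are constructed **before** resampling, on the native grid, because the
morphological margins are metric: expansion/contraction use the exact
Euclidean distance transform with per-axis spacing, so an 8 mm margin is
8 mm even on 0.98 × 1.37 × 5 mm CT grids. A voxel belongs to an `r`-expansion
iff its center lies within `r` of some foreground voxel center; contraction
is the morphological dual. The `gradient` ROI keeps the GTV voxels between
the 4 mm-eroded surface and the border plus the 8 mm exterior shell; if the
4 mm erosion removes the entire GTV there is no interior left to contrast
against, and the patient is flagged `gradient_excluded` (skipped only for
gradient analyses).

The lung mask is an input; `lung_mask_from_hu` (HU < −500, largest connected
components) is a deliberately coarse fallback for restriction purposes, not
a lung segmentation.

## Feature panel

Defaults: HU re-segmentation window **[−1024, 200]** (removes bone/dense
structures), fixed bin size **20 HU** with bin 0 anchored at the minimum
intensity of the ROI (≈ 60 bins over the full window). Intensity features
are computed on raw HU; texture features on the discretized grid with
1-based grey levels. Percentiles use linear interpolation between order
statistics; variance and higher moments are population moments; kurtosis is
excess kurtosis.

The default panel (`radiomap/data/default154.yaml`) has 154 features:

| block | features | parameters |
|---|---|---|
| intensity | 17 | raw HU |
| GLCM | 25 + 25 | distance 1, 13 directions; merged and direction-averaged |
| GLRLM | 16 + 16 | 13 directions; merged and direction-averaged |
| GLSZM | 16 | 26-connected zones |
| NGTDM | 5 | 26-neighbourhood |
| NGLDM | 17 + 17 | 26-neighbourhood, α = 0 and α = 1 |

"Merged" sums the 13 directional count matrices before computing features
(the default referenced by the named model features); "averaged" computes
features per direction and averages them. The NGLDM dependence count
includes the center voxel (columns 1…27); α is the grey-level tolerance for
a neighbour to count as dependent. The panel is declarative and swappable;
the ten features used by the per-ROI signature models
(`intensity_median`, `intensity_percentile_90`, `glcm_contrast`,
`glcm_correlation`, `glcm_inverse_variance`,
`glcm_inverse_difference_normalized`, `glrlm_run_entropy`,
`glszm_zone_percentage`, `glszm_zone_size_nonuniformity_norm`,
`ngldm_low_dependence_emphasis`) are mandatory in any replacement.

Undefined quantities (zero denominators, single grey level, single-voxel
ROI dispersion) are emitted as NaN sentinels, never silently zeroed;
downstream modeling drops any feature that is NaN for at least one training
patient. Zone size non-uniformity normalized is
`Σ_s (Σ_g Z(g,s))² / N_z²` (column sums over zone sizes), its grey-level
sibling uses row sums — the two are easy to confuse on small fixtures.

## Local radiomics and activation maps

The GTV+Rim ROI is first re-segmented (informative voxels = in-ROI voxels
inside the HU window), then tiled with non-overlapping 3×3×3 blocks. All 27
lattice phases are evaluated; the phase intersecting the ROI with the fewest
blocks wins (tie → lexicographically smallest offset). Blocks with < 9
informative voxels are discarded. GTV-overlap fractions use the informative
voxels as denominator (edge blocks contain non-ROI voxels that do not
vote); labels are strict: overlap < 0.10 → rim, > 0.90 → GTV, otherwise
mixed and discarded — equality at a cutoff is mixed.

Patch features are computed on each patch's informative voxels with the
discretization anchored at the **whole-ROI** minimum, so local and global
features share one bin definition. A patch is *activated* iff its value is
strictly greater than the training-cohort median of the global feature
(ties → non-activated). The per-patient activation ratio is the activated
fraction `n_act / n_total` per region (bounded and defined when all patches
are activated; the odds form is monotone in it, so rank-based tests agree).
Eligibility — ≥ 27 labeled patches in total and ≥ 3 per region — is
assessed after overlap labeling and sentinel exclusion; the threshold is fit
on all training patients' global features regardless of patch eligibility.
Group comparison uses the two-sided Wilcoxon rank-sum test: exact null
distribution when both groups have ≤ 12 patients and there are no ties,
otherwise the normal approximation with continuity and tie correction; the
method used is recorded. No multiple-testing correction is applied across
the two regions.

A global threshold only transfers to 27-voxel patches for features that are
(approximately) scale-invariant — normalized texture measures and intensity
locations. Extensive features such as the unnormalized non-uniformities
grow with ROI size, so every patch falls on one side of the global median
and the map is uninformative; prefer the normalized variants for mapping
(the default is `glszm_zone_size_nonuniformity_norm`).

## Signature modeling

- **ICC filter**: ICC(2,1) — two-way random effects, absolute agreement,
  single rater — from the classical ANOVA mean squares; stable iff
  ICC > 0.9. Constant tables have undefined ICC and count as unstable.
- **PCA surrogates**: features are z-scored with training statistics (the
  panel mixes HU, counts and unitless ratios, so unscaled PCA would be
  dominated by HU-scale features); the smallest k components reaching 95 %
  cumulative variance are kept and each is replaced by the feature with the
  largest |Pearson r| to its scores (tie → earlier panel order; duplicates
  collapse).
- **Univariate screen**: one logistic fit per surrogate; Wald p for the
  slope, keep iff p < 0.05 (no multiplicity correction). Under
  (quasi-)separation the Wald statistic degenerates (detected via an
  exploding standard error) and the p-value falls back to the
  likelihood-ratio test. The screen standardizes the covariate internally
  for numerical stability — p and AUC are invariant to that.
- **Backward AIC**: from the full multivariate logistic model, repeatedly
  remove the feature whose removal most decreases AIC; stop when no removal
  helps. Fits use raw feature values so coefficients stay on the feature
  scale. Note that AIC retains a pure-noise covariate with asymptotic
  probability P(χ²₁ > 2) ≈ 0.157 — elimination of a noise feature in ~84 %
  of runs is the expected behaviour, not a defect.
- **Evaluation**: AUC via the Mann–Whitney statistic on the linear
  predictor; 95 % CI by DeLong's analytic method, clipped to [0, 1]. A
  validation CI covering 0.5 is reported as failed validation. An
  intercept-only model evaluates to AUC 0.5 with a degenerate CI.
- **Cross-validation**: 5 random folds without repetition; the full
  selection chain (screen + backward AIC over the fixed surrogate pool) is
  re-run per fold. A partition leaving a fold single-class is rejected and
  re-drawn with an incremented seed (logged).

## Phantom generator

Each case is a 56×56×48 grid at 2.5 mm spacing: lung background
−850 ± 60 HU, a soft-tissue slab (+40 HU) along one face, and a
quasi-spherical tumor (0 ± 40 HU) of radius 20 ± 3 mm with ± 3 mm center
jitter — sizes chosen to resemble stage-III lung lesions and to yield
realistic patch counts (≳ 27 labeled patches per patient at 3.75 mm).
Texture is a correlated Gaussian random field: white noise convolved with
an isotropic Gaussian kernel and renormalized to the target SD. The kernel
width is `base_corr_mm` (1 mm) plus `kappa_rim` (in the 10 mm shell around
the tumor, lung part only) or `kappa_core` (inside the tumor) for class-1
cases; κ therefore controls the class difference in spatial correlation
length, which size-zone statistics respond to. κ = 3 mm is the configured
effect size for recovery studies: a correlation length comparable to the
analysis voxel (3.75 mm), i.e. a coarse-vs-fine texture contrast a
radiologist would plausibly notice; shorter correlation lengths are largely
destroyed by resampling. With κ = 0 the two classes are distributionally
identical by construction.

What the phantom does **not** emulate: real lung anatomy and vasculature,
breathing blur, scanner/kernel effects, HU calibration drift, irregular
tumor shapes, or correlated inter-feature structure beyond what one random
field induces. Passing recovery tests therefore shows the *pipeline*
localizes injected effects correctly and is calibrated under its null —
not that clinical effect sizes are reproduced.

## Simulation study sizes

Simulations are sized to run comfortably on one CPU: null calibration uses
20 replicates (tests) / 12 replicates (acceptance script) of
15-per-class training and validation cohorts; effect-placement studies use
10/8 replicates of the same size; modeling-chain recovery uses 5/4 seeds
with 20-per-class training cohorts. Pass criteria are the stated
proportions (≥ 90 %, ≤ 15 %, ≥ 80 %) applied to these replicate counts. All
randomness is seeded; replicate seeds are derived from one master seed.

## Known limitations

- One connected GTV is assumed per case; multiple components are tolerated
  but not split into separate lesions.
- The exact identity of 137-texture-feature panels varies across radiomics
  software; the default manifest is a documented IBSI-aligned composition,
  not a clone of any one tool.
- DICOM/RTSTRUCT ingestion, PET co-registration and scanner harmonization
  are out of scope; inputs are NIfTI volumes and masks.
- The activation threshold (training-cohort median) is a deliberately
  simple convention; no attempt is made to optimize it.
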