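# Methods

This note records the models, numerical conventions and design choices
behind `radgen`, and what the synthetic-data tests do and do not establish
about real CT cohorts.

## Synthetic cohort model

The generator emulates the *statistical structure* the analysis assumes,
not renal CT physics.

**Tumors.** Each tumor is an axis-aligned ellipsoid with per-patient radii
drawn uniformly in 0.22–0.30 of the grid edge. A concentric core ellipsoid,
scaled so its volume fraction equals the class necrotic fraction, is filled
around `core_hu_mean` (default 25 HU — low-attenuation necrosis); the rim is
filled around `rim_hu_mean` (default 140 HU — nephrographic-phase
enhancement). Texture is spatially correlated Gaussian noise (white noise
smoothed at `texture_correlation_length`, default 1.5 voxels, rescaled to
unit variance) with class-dependent rim amplitude
(`rim_texture_contrast_by_class`, default 1.0 vs 1.7). Metastatic-class
tumors draw the larger necrotic fraction (0.35 vs 0.08), so the four
signature features (INNER_Min_Hist, INNER_MaxProbability_GLCM,
OUTER_Energy_Hist, Under80HURatio) separate the classes by construction.
Defaults mirror the emulated study scale: 58 patients, 12/58 metastatic.
The discovery cohort's real feature distributions are unpublished, so these
defaults are calibration-free and should be read as plausible, not fitted.

**Outcomes.** Metastasis-free survival is exponential with subject hazard
`h0 · exp(Σ β_k z_k)` over the cohort-standardized signature features, with
the published Cox coefficients (−0.1020, 0.0343, 0.4302, 0.6369) as the
default true weights, baseline hazard 0.02/month and independent
exponential censoring at 0.015/month (≈60% event rate over typical
follow-up). Times are months.

**Expression.** A signal gene assigned to feature *f* is
`exp(s·effect·z(f) + σ·ε)` with sign `s = ±1`; the exponential link keeps
abundances positive (RPKM-like) without affecting rank statistics. The
fraction of negative-sign genes per feature is configurable (the emulation
setting plants 91% negative for INNER_Min_Hist). Remaining genes are i.i.d.
log-normal noise.

**What passing tests do not show.** Real tumors are not ellipsoids, real
texture is not stationary Gaussian, censoring is not independent
exponential, and real radiomics features are heavily collinear across the
121 columns. Recovery results here certify the *machinery* (estimators,
resampling, test calibration), not clinical performance.

## ROI partitioning

The inner ROI is the morphological erosion of the mask by a ball of
physical radius `(1 − inner_fraction) · R_eq`, where `R_eq` is the
equivalent-sphere radius of the tumor; the outer ROI is the set difference.
The radius is discretized per axis through the voxel spacing (ellipsoidal
structuring element), so anisotropic slices erode correctly in millimetres.
A sub-voxel radius falls back to the minimal 6-connected element, so any
positive radius peels at least one surface layer and a single-voxel mask
yields an empty core. `inner_fraction` defaults to 0.5; the construction is
shape-adaptive and parameter-light, chosen because the original split
procedure is unpublished.

## Feature library

All conventions are frozen in `radgen.features.registry` and pinned by
brute-force oracle tests.

* **Histogram (19)**, 128 equal-width bins over the ROI's own [min, max].
  Entropy in bits; uniformity `Σ p_i²`; *energy* is `Σ n_i²` over bin
  counts (total energy multiplies by voxel volume) — kept distinct from
  uniformity deliberately; the alternative readings (`Σ p²`, `Σ x²`) are
  indistinguishable from the source material, and the choice is pinned by
  tests. Skewness (`m3/m2^1.5`) and Pearson kurtosis (`m4/m2²`) of a
  constant ROI are defined as 0 to keep tables complete.
* **GLCM (16)**, 128 bins, the 13 unique symmetric 3D unit offsets,
  restricted to in-mask pairs; per-offset matrices normalized to sum 1,
  features computed per offset and averaged over offsets with at least one
  pair. Gray levels are 1-based bin indices. Degenerate conventions:
  correlation of a zero-variance matrix is 1; IMC1 is 0 when
  `max(HX, HY) = 0`; IMC2's radicand is clamped at 0.
* **Size-zone (2)**, 32 bins, zones are 26-connected equal-level
  components: zone percentage `N_zones / N_voxels` and normalized size-zone
  non-uniformity `Σ_s c_s² / N_zones²`.
* **Morphology (8)** on the whole ROI. Surface area comes from a
  marching-cubes iso-surface of the mask after a light Gaussian smoothing
  (0.5 voxel): raw voxel surfaces inflate area ≈ 8%, pushing digital-ball
  sphericity to ≈ 0.93; smoothing restores it to 0.96–0.98 at the tumor
  sizes simulated here while slightly rounding genuinely sharp corners.
  Sphericity is `(36π V²)^{1/3} / A`, compactness `36π V²/A³`; elongation
  and flatness are `√(λ₂/λ₁)` and `√(λ₃/λ₁)` of the voxel-cloud covariance
  eigenvalues. Maximum 3D diameter is the largest pairwise distance among
  convex-hull vertices of the voxel centres.
* **Semantic (2)**: fractions of in-mask voxels strictly below 100 and
  80 HU ("under" is read literally as `<`).

An empty inner ROI (erosion exhausted the mask) makes inner-family features
fall back to the whole ROI with a log warning, keeping the table complete.

## Class balancing and stability selection

ADASYN (He et al.) weights each minority point by the majority fraction
among its k = 5 nearest neighbors in the full data and interpolates
synthetic points toward random minority neighbors; originals are preserved
as a prefix of the output. Balancing is applied once, globally, before the
bootstrap (`adasyn_mode="global"`), reproducing the emulated protocol; a
`per_bootstrap` mode balances inside each training split instead, because
global oversampling lets synthetic neighbors leak across train/holdout
boundaries. A consequence worth knowing: under a label permutation, global
ADASYN interpolates the (now random) minority points into a compact
synthetic cluster that a selector can "detect" — null-calibration checks
must therefore permute the labels of the balanced cohort, and the test
suite does.

Each of the `n_bootstrap` (default 10,000) replicates draws a stratified
80/20 split without replacement, z-scores the training columns, and fits an
L1-logistic path whose penalties run from the data-driven λ_max down two
decades (the glmnet convention for n < p), with the value chosen by
five-fold cross-validated log-loss. The signature is every feature with
nonzero coefficient in ≥ 95% of replicates. With perfectly collinear
duplicates the L1 optimum is non-unique and the solver may split weight
across copies; at least one copy survives per replicate, but per-copy
frequencies are not interpretable in that regime.

Classifier evaluation (logistic, linear SVM, random forest with 50 trees —
other hyperparameters at library defaults) reports bootstrap-mean AUC,
sensitivity, specificity and accuracy on train and holdout splits;
replicates whose holdout lacks a class are resampled and logged.
Unpenalized multivariate logistic fits (ridge 1e−8 for numerical safety)
supply per-feature weights and odds ratios, `OR = exp(weight)` exactly;
perfect separation is reported with capped weights and a warning.

## Risk score and stratification

The RRS is the linear predictor of a lifelines Cox fit (Efron ties) over
the signature; optional case weights enter the partial likelihood (uniform
weight scaling leaves estimates unchanged — note that literally duplicating
rows does *not*, because duplicates create ties). The cutoff grid is the
unique score values inside the 15th–85th percentile band (preventing
degenerate groups; the band is configurable), maximizing the standard
two-group log-rank statistic with ties broken toward the median. The
reported group HR comes from a single-covariate Cox fit on the binary group
label. Because maximally selected statistics are anti-conservative, the
unadjusted log-rank p is reported as such and
`cutoff_permutation_p` offers a permutation-calibrated alternative
(shuffling outcomes against scores and re-maximizing). Validation mode
keeps the signature names but refits coefficients and cutoff on the new
cohort. The internal log-rank statistic is a vectorized implementation
verified against lifelines to machine precision.

## Radiogenomics

Per (gene, feature) pair the Spearman rho uses average ranks; two-sided
p-values use the t-approximation for n ≥ 10 and, below that, exact
enumeration of all n! rank permutations. The screen keeps p < α (default
0.05, uncorrected, matching the emulated protocol; a Benjamini–Hochberg
option exists). Top-n ranking (default 100) is by |rho| — the alternative
orderings (by p, or by rho within sign) coincide in the no-tie continuous
case. Set overlap is Jaccard `|∩|/|∪|`.

The per-sample enrichment score of a set of m genes among N is the
rank-sum z,

    ES = (mean in-set rank − (N+1)/2) / sqrt((N+1)(N−m)/(12 m)),

a deliberate simplification of the Kuiper-like GSVA statistic: it is
rank-based (invariant to any monotone within-sample transform), has an
analytic N(0, 1) null, and the downstream use is purely ordinal
(low/intermediate/high subgroups). Subgroups come from Ward clustering of
samples on their ES profiles, cut at k = 3 and ordered by mean combined ES
(unweighted mean over the four sets — the original combination rule is
unpublished); the high and low subgroups are compared by log-rank.

## Reproducibility and problem sizes

One global seed hash-derives a per-stage seed (SHA-256 of
`"{seed}:{stage}"`, reduced below 2³¹), so stages are independently
re-runnable and two identical configurations produce identical outputs.
All simulation-based checks state their scale explicitly: selection
recovery runs 500 bootstraps on the balanced 46 + 12 cohort and its
permutation null 200 bootstraps × 3 seeds; Cox recovery uses 400 simulated
patients; the planted HR = 8 check uses 200; the trait-gene null
calibration 200 seeds of 200 genes × 11 samples (the scale of the emulated
expression cohort). These sizes were chosen so each check has comfortable
statistical resolution for its assertion; pushing them higher sharpens
Monte-Carlo error but does not change any conclusion.

## Known limitations

* The feature rosters beyond the four signature features follow the common
  radiomics canon; a different 19/16/2 membership would change non-signature
  columns but not the pipeline's behavior on the signature.
* ADASYN's "global" mode reproduces the emulated order of operations
  including its leakage; use `per_bootstrap` for honest generalization
  estimates.
* Wavelet/filtered features, 2D slice-wise extraction, DICOM ingestion,
  pathway/network annotation, immune deconvolution and drug-sensitivity
  mining are out of scope.
* The generator's defaults are plausibility choices, not fits to any
  cohort; absolute metric values on synthetic data (e.g. classifier AUCs)
  characterize the simulation, not clinical discrimination.
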