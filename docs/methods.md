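# Methods

This note documents the models, algorithms and design choices behind
`radstab`, in the spirit of a statistical software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## The study template

The package operationalizes a common robustness design: the *same*
nodules are reconstructed under ten acquisition settings S1–S10 that each
vary a single factor against the reference S2 (1 mm slices, 1024×1024
matrix, B_SHARP_C kernel, console export):

| factor | settings | variation |
|---|---|---|
| transmission | S1 vs S2 | PACS export vs console |
| slice thickness | S2, S3, S4 | 1 / 3 / 5 mm |
| kernel | S2, S5–S9 | sharp ↔ soft family |
| matrix | S2 vs S10 | 1024 vs 512 |

Per-feature agreement across each group, and jointly across all ten
settings, is scored with ICC(A,1); features are stratified at 0.8 / 0.4
(boundaries inclusive: ICC = 0.8 is stable, ICC = 0.4 unstable); and
malignancy models restricted to each stratum are compared for performance
*and* for consistency of performance across the setting-variant test sets.

## ICC(A,1)

We fix the McGraw–Wong single-rating absolute-agreement two-way model
form

ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

estimated from the two-way ANOVA mean squares with subjects as rows and
settings as columns. Properties relied on elsewhere: invariance to a
common affine transform of the whole matrix; strict decrease under
rater-specific offsets (absolute agreement penalizes systematic setting
shifts, unlike consistency-type ICCs); estimates bounded above by 1 and
below by −1/(k−1), retained as computed (never clipped). A matrix with
zero total variance has no defined agreement: it is flagged degenerate
and assigned "unstable", because a feature constant across patients
carries no discriminative signal and must not enter the stable-stratum
model silently. Subjects with any missing cell are dropped
(complete-case), matching designs that require every nodule visible under
all settings.

## Feature extraction

A reduced IBSI-style panel of 644 features: 14 shape descriptors
(computed once, on the original-geometry mask), and 18 first-order + 24
GLCM statistics computed on the original image and 14 derived images
(8 wavelet sub-bands, LoG at σ = 1, 2, 3 mm, square, square-root,
exponential). Run-length, size-zone, neighbourhood-tone and dependence
families are deliberately omitted: the GLCM family suffices to exercise
every downstream stage, and the extractor is config-extensible.

Numerical conventions, all of which matter for reproducibility:

- **Preprocessing order**: min–max rescale to [0, 2048] (a constant
  volume maps to the lower bound), then resample to 1 mm isotropic —
  B-spline for the image (clamped back into range to remove overshoot),
  nearest-neighbour for the mask. An ROI that empties under resampling
  raises a degenerate-ROI error rather than returning NaNs.
- **Discretization**: fixed bin width 25 with edges anchored at integer
  multiples of the width from 0; occupied bins are shifted so the lowest
  becomes level 1 (a full-range [0, 2048] image yields at most 82
  levels). Gaps between occupied bins are preserved.
- **GLCM**: symmetric co-occurrence accumulated over the 13 unique 3D
  offsets at Chebyshev distance 1; statistics averaged over directions;
  a single-gray-level ROI yields contrast 0 and a NaN sentinel for
  correlation (never a silent zero).
- **Shape**: mesh volume and surface area from a marching-cubes surface
  at level 0.5 on the padded mask, lightly Gaussian-smoothed (σ = 0.6
  voxels) before surface extraction to suppress the staircase artifact
  that otherwise inflates surface area on digitized round objects (a
  digitized 10 mm sphere then scores sphericity ≈ 0.97 rather than
  ≈ 0.91). Maximum3DDiameter is the largest pairwise distance between
  *boundary-voxel centres* (convex-hull accelerated), not mesh vertices —
  simpler and deterministic; values are slightly smaller than
  mesh-vertex-based implementations. The 2D maximum diameters take the
  in-plane maximum per slice stack. Axis lengths use population (ddof 0)
  covariance eigenvalues of the voxel-centre coordinates. Single-voxel
  masks produce zero diameters and NaN sentinels for sphericity,
  elongation and flatness.
- **Wavelet**: single-level *stationary* (undecimated) 3D transform,
  `coif1` by default, so sub-bands stay congruent with the mask; odd
  axes are edge-padded to even length and cropped back. High-pass
  sub-bands of a constant volume are exactly zero.
- **LoG**: scale-normalized (σ²·∇²G) with σ specified in millimetres and
  converted per-axis to voxels; the tiny nonzero DC gain of the discrete
  kernel is subtracted so constants map exactly to zero.
- **Algebraic filters**: the standard range-preserving forms — square
  (c·x)² with c = 1/√max|x|, square-root √(c·x) with c = max|x| (odd
  extension for negatives), exponential exp(c·x) with c = ln(max|x|)/max|x|.

## Classifiers

Each stratum model is a three-step pipeline fitted strictly on the
training part of each CV fold:

1. **Z-score normalization** with training means/sds; zero-variance
   features are dropped (and logged). Validation and test tables are
   transformed with training parameters only.
2. **MRMR selection** (default top 20): greedy forward selection with the
   difference criterion. Relevance is the label F-statistic mapped to
   correlation units, √(F/(F+n−2)) — the absolute point-biserial
   correlation — so it is commensurate with the redundancy term, the mean
   absolute Pearson correlation with already-selected features. This
   scaling was chosen over raw-F normalization because it keeps both
   terms in [0, 1] with comparable dynamics (an exact duplicate of a
   selected feature scores relevance − 1 < 0 and loses to any modestly
   informative independent feature). Ties break on column order;
   selection is deterministic and invariant to feature scaling and row
   order.
3. **Firth-penalized logistic regression**: maximizes
   ℓ(β) + ½·log det(XᵀWX) (Jeffreys prior) by IRLS on the bias-adjusted
   responses yᵢ + hᵢ(½ − πᵢ), hᵢ the hat-matrix diagonals, with
   step-halving on the penalized objective. Convergence: penalized-score
   norm < 1e-6, at most 100 iterations (one IRLS iteration = one
   "epoch"); a non-converged model is returned flagged rather than
   raised. Exactly collinear or rank-excess columns are dropped by a
   QR-diagonal test before fitting. The penalty guarantees finite
   coefficients under complete separation; with penalty weight 0
   (diagnostic mode) the fit reproduces the ordinary MLE on non-separable
   data. Closed-form anchors used in tests: intercept-only with balanced
   labels gives β₀ = 0; with 4/4 positives, π̂ = 4.5/5 so β₀ = ln 9.

Prediction thresholds probabilities at 0.5, with p = 0.5 counting as
positive — fixed so McNemar comparisons are reproducible.

## Evaluation

Fivefold stratified CV (stratification by label, seeded); per fold each
stratum model is evaluated on the fold's train/validation parts and on
all ten setting-variant test tables; reported cells are means of per-fold
metrics (mean-of-folds is nonlinear for G-mean and AUC, so per-fold values
are also emitted). The G-mean and balanced-accuracy identities —
G = √(sens·spec), acc = (sens+spec)/2 for balanced cohorts — hold exactly
per fold but only approximately for fold-means; the acceptance checks use
table cells where the identity survives rounding to 3 decimals.

AUC is the midrank Mann–Whitney statistic. The DeLong test uses
placement-value structural components; the variance of the AUC difference
needs at least two cases per class, and zero variance yields p = 1 with a
flag. McNemar on paired correctness (sensitivity on positives,
specificity on negatives) is exact binomial for discordant count
b + c < 25, else χ² with continuity correction; b + c = 0 gives p = 1,
flagged. Significance is two-sided 0.05 without multiplicity correction.
Pairwise comparisons are computed per fold on the validation set and the
reference test set.

## Synthetic generators: what they emulate, what they do not

**Phantom cohort.** Nodules are irregular ellipsoids (random axis
anisotropy with unit geometric mean; radius modulated by a smooth random
field) embedded in Gaussian background noise, at a reference geometry of
1 mm slices and a 0.5 mm in-plane grid standing for a 1024 matrix over a
nodule-sized field of view (grid 45×80×80, so a 30 mm nodule fits and the
axial extent divides by 3 and 5). Defaults: background −800 HU with 50 HU
noise, nodule −50 HU — plausible lung-window contrast; equivalent-sphere
diameters from a normal(9.31, 4.90²) mm truncated to [5, 30] mm, the size
distribution reported for routine clinical nodule cohorts; malignant
nodules receive additional spatially correlated intra-nodule texture
(effect size 1.0 in units of the background noise sd) — a caricature of
the heterogeneity radiologists associate with malignancy, not a
biological model.

**Setting transforms** are deterministic operators applied in
reconstruction order: kernel, slice thickness, matrix, transmission.
Thicker slices are non-overlapping k-slab means (trailing partial slab
averaged over the remainder; masks take each slab's centre slice by
nearest-neighbour). The 512 matrix halves the in-plane grid by linear
interpolation (nearest for the mask). The six proprietary kernels cannot
be reproduced physically; they are modelled as a one-parameter
blur/sharpen family — B_SHARP_C identity (it is the reference), blur σ
growing 0.3 → 1.5 mm through B_SHARP_A, B_SOFT_C, B_SOFT_F, B_VSOFT_A,
and unsharp masking for B_VSHARP_D — preserving the ordinal smooth↔sharp
structure that drives feature instability, with no claim of fidelity to
any vendor's modulation transfer. PACS export is a 12-bit quantization
round-trip (near-identity, matching its empirically inert role). All
operators preserve constant volumes.

**Feature panels.** Feature f of subject i under setting s is
y = t + m·g·c + d + e: subject effect t ~ N(0, σ_b²), malignancy
indicator m with class effect c (optionally modulated per setting by g),
fixed setting offsets d, residual e. The residual variance is solved per
feature so the population ICC(A,1) equals the requested target: fixed
offsets enter the A,1 denominator through Σ(d_s − d̄)²/(k−1) (the
probability limit of the (k/n)(MSC−MSE) term), and when the class effect
is homogeneous across settings its Bernoulli variance p(1−p)c² counts as
between-subject signal. Offsets too large for the target raise a
parameter error. Calibration is exact in the population; the estimate at
n = 1000 has sampling sd ≈ 0.02 at low targets, so recovery checks use
the Monte-Carlo mean over replicate panels.

**The stability benchmark** (`stability_benchmark_panel`) constructs the
ground truth for the generalizability claim: a robust block (ICC 0.95,
setting-invariant class effect), a fragile block (ICC 0.2, class effect
scaled per setting — 1.0 at the reference, down to 0.0 under the
strongest slice-thickness change and up to 1.4 elsewhere), and an
uninformative block (ICC 0.6, no effect). Only the robust block carries
*setting-robust* signal; the fragile block's signal exists at the
reference but decays or drifts across settings, which is what makes a
fragile-feature model's AUC swing across test sets rather than sit at
chance everywhere (a fully signal-free fragile block would reduce the
contrast to sampling noise).

What passing tests on these generators show: the estimators, the
selection/fitting machinery and the orchestration behave correctly under
a controlled data-generating process that has the right *structure*
(two-way subject×setting design, stratified signal robustness). What they
do not show: anything about real scanner physics, real nodule biology, or
the numerical values of stability fractions and AUCs on clinical data.

## Cohort plumbing inside the pipeline

`run_pipeline` uses a single simulated cohort for both roles that a
clinical study would fill with separate datasets: all subjects under all
settings feed the ICC stratification, the reference-setting table of the
non-held-out subjects forms the training-validation cohort, and the
held-out subjects under all ten settings form Test Sets 1–10. Two modes
share all downstream stages: `panel` (direct feature simulation, fast,
exact ICC control) and `imaging` (phantoms → setting transforms →
extraction). One master seed is fanned out deterministically per stage;
the run manifest records SHA-256 checksums of every artifact, and
identical config + seed reproduce identical checksums.

## Problem sizes

Defaults used by the test suite and acceptance script: panels of
100–1000 subjects; the benchmark cohort 400 subjects (300
training-validation, 100 test) × 60 features × 10 settings × 3 seeds;
imaging smoke runs 12–16 phantoms at reduced extraction configs; Firth
recovery 50 replicates at n = 2000. These sizes make every stage's
behaviour measurable with comfortable statistical margins while keeping a
full run in minutes on one CPU.

## Known limitations

- No physically accurate CT projection/reconstruction, scanner noise
  spectra, or DICOM handling.
- Shape features use voxel/boundary conventions that differ slightly from
  mesh-vertex-based extractors; no numerical parity with any third-party
  tool is claimed (feature *names* follow the common
  `<image>_<class>_<feature>` convention for familiarity).
- ICC confidence intervals, alternative agreement indices (CCC,
  Bland–Altman), calibration analysis and nested hyperparameter tuning
  are out of scope.
- MRMR runs inside each CV fold (leakage-safe). Running it once per
  stratum on the full development cohort is possible by calling
  `mrmr_select` directly, but is not the default and is not claimed to
  match any particular published protocol.
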