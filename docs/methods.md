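# Methods

This note documents the models, algorithms and numerical choices behind
`radpipe`, in the order data flows through the pipeline, together with
what the synthetic generators do and do not emulate.

## Imaging model and preprocessing

Inputs are pairs of co-registered 3D volumes (T1w, T2w) with a binary
primary-tumor mask on the same grid, voxel spacing taken from the NIfTI
header. Axes 0/1 are in-plane (x, y), axis 2 is the slice direction.

Preprocessing applies, in a fixed canonical order:

1. **Denoising.** Separable Gaussian convolution with σ = 0.5 voxels,
   truncated to a 3×3×3 support and renormalized to unit sum, so a
   constant volume is exactly preserved. Boundaries are reflected.
   Because the kernel is strongly truncated (centre weight ≈ 0.49), the
   exact stencil matters; tests pin it against direct enumeration.
2. **Bias-field correction hook.** Intensity non-uniformity correction
   (e.g. N4) is deliberately *not* reimplemented: the pipeline accepts
   an optional callable and otherwise skips the step with a logged
   notice. The rest of the chain is insensitive to this choice in the
   synthetic setting (phantoms have no bias field).
3. **Z-score standardization** over the whole volume (not ROI-only):
   the intent of the step is to bring different acquisitions to similar
   signal ranges, which is a whole-image property. A constant volume is
   a contract violation (zero variance) and raises.
4. **Resampling to 2 mm isotropic.** Output shape =
   `round(extent / 2 mm)` per axis with the centre of voxel 0 held
   fixed; image interpolated with a prefiltered cubic B-spline, mask
   with nearest-neighbour so it stays binary. A volume already at 2 mm
   passes through voxel-identical. An ROI that vanishes under
   resampling raises. Physical ROI volume is conserved to within 10 %
   for ROIs ≥ 1 cm³ (tested).

## Radiomic features (1072 per patient)

Per modality: 14 shape + 18 first-order + 24 GLCM + 16 GLRLM on the
original image, plus (18 + 40) × 8 wavelet sub-bands = 536; T1w and T2w
concatenate to 1072. Shape features depend only on the mask and are
reported once per modality to keep the per-modality block at 536.

- **Discretization**: fixed bin count (default 32) over the ROI's
  [min, max], half-open bins with the top bin closed; a constant ROI
  occupies bin 1. Re-binning is done independently per image and per
  wavelet sub-band. Fixed-bin-count binning makes all texture features
  invariant to adding a constant to the image.
- **First-order** (18): the conventional set (Energy, TotalEnergy,
  Entropy, percentiles, Range, MAD, rMAD, RMS, Skewness, Kurtosis,
  Variance, Uniformity …). Entropy/Uniformity use the fixed-bin
  histogram; moments are population moments; Kurtosis is not
  excess-corrected. A constant ROI short-circuits the moment formulas
  to 0 to avoid catastrophic cancellation.
- **GLCM** (24): co-occurrences at distance 1 along the 13 unique 3D
  directions, symmetrized and normalized per direction; features are
  computed per direction and averaged (directions with no valid pair
  are dropped). Degenerate conventions: Correlation of a zero-variance
  matrix is 1; MCC of a single occupied gray level is 1.
- **GLRLM** (16): maximal same-gray-level runs per direction; every ROI
  voxel belongs to exactly one run per direction (conservation is
  tested against a brute-force enumerator), features averaged over
  directions. The four signature features follow the standard
  formulas, e.g. LongRunEmphasis = (1/N_r) Σ r² R(g, r), RunPercentage
  = N_r/N_p.
- **Shape** (14): marching-cubes surface mesh of the mask at iso-level
  0.5 after a mild Gaussian anti-aliasing (σ = 0.6 voxels) — without
  it the stair-stepped binary mesh overestimates a sphere's surface by
  ~10 % and Sphericity saturates near 0.91; with it a radius-10-voxel
  digital sphere reads its volume within 2 % and Sphericity ≈ 0.98.
  (Tiny ROIs that smooth below the iso-level fall back to the binary
  mesh.) Axis lengths are 4√λ of the voxel-coordinate covariance
  eigenvalues; 2D diameters are per-slice maxima over voxel centres.
- **Wavelet** (8 sub-bands): single-level stationary (undecimated)
  separable transform, coif1 by default, symmetric edge padding of odd
  axes, so each sub-band lives on the original grid and the mask
  applies unchanged. Labels L/H follow axis order (LLL … HHH), and the
  decomposition reconstructs the input to machine precision (tested).

## Stability screening

Inter-reader segmentation variability is mimicked by whole-voxel
in-plane translations of the mask: ±round(0.10 × bounding-box length)
voxels along x and y (minimum 1 voxel), giving 5 measurement conditions
including the original. Diagonal and through-plane shifts are excluded
(through-plane resolution is coarse; the perturbation axes are
config-exposed). Agreement across conditions is ICC(2,1) — two-way
random effects, absolute agreement, single measurement,
(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) — and a feature is
stable iff ICC > 0.75 (strict). A degenerate panel with no
between-subject variance is assigned ICC 0 with a warning. The number
of replicas (5) is a design choice, not an external constraint.

## Cox fitting

All Cox models are fitted by Newton iteration on the partial likelihood
with Efron's tie correction (Breslow available), step-halving line
search, convergence at gradient max-norm < 1e-7, and a hard failure
(never silent) on non-convergence, singular information, or fewer
events than covariates + 1. The solver is vectorized over risk sets
because the selection protocol performs tens of thousands of small
fits; it reproduces lifelines' coefficients and standard errors to
~1e-6 on random instances (tested), and lifelines remains the
independent oracle, never the implementation.

## Feature selection

Within the training cohort: for each of 20 repeat seeds, 100 iterations
(reducible via config) of

1. random disjoint 70/30 partition by patient count (redrawn, ≤50
   tries, until both sides hold ≥2 events);
2. univariate Cox Wald screen at p < 0.05 on the 70 % side, 20 lowest
   p kept (non-convergent features skipped and logged);
3. greedy forward multivariate Cox selection: starting empty
   (validation C-index defined as 0.5), add the candidate that most
   increases the held-out 30 % C-index; stop at the first
   non-improvement (strict, tolerance 1e-6). Collinear candidates that
   break the fit are skipped at that step.

Selection counts accumulate over all iterations; the final signature is
the 5 highest-count features, ties broken by higher full-cohort
univariate C-index and then name, so the result is deterministic given
the seed list. "Bootstrap" here means repeated random partitions
without replacement — the protocol splits rather than resamples — and
the evaluation side of the wrapper is the held-out 30 % (otherwise the
split would serve no purpose); both choices are config-exposed.

A note on null behaviour: within a *fixed* cohort of pure-noise
features the iterations share the data, so whichever feature is
spuriously prognostic in that cohort is legitimately re-selected in
most iterations — selection counts are *not* uniform within one null
cohort. Absence of systematic bias (positional, tie-break) is instead
verified across independent null cohorts, counting each feature once
per cohort.

## Signature, stratification, evaluation

The signature is s = Σ β_f (x_f − μ_f)/σ_f with μ, σ from the training
cohort only; external cohorts are normalized with the training
statistics (tested by contract). The risk threshold τ is the training
median score; s > τ is high-risk, s = τ low-risk. Evaluation computes:

- **Harrell's C-index** over comparable pairs (earlier time has the
  event; score ties count ½), exactly equal to exhaustive pair
  enumeration (tested), with a 100-resample bootstrap distribution
  (median and IQR; resamples without comparable pairs are redrawn);
- **hazard ratio** of high vs low risk from a univariate Cox fit on the
  group indicator, Wald 95 % CI on the log scale;
- **Kaplan-Meier** curves with the plain Greenwood 95 % band (clipped
  to [0, 1]) and the two-group **log-rank** test;
- **distribution comparisons** between models' bootstrap C-indexes:
  Mann-Whitney U for two, Kruskal-Wallis omnibus plus Tukey-Kramer on
  rank means (studentized-range reference, infinite df, tie-corrected
  rank variance) for more;
- **signature vs stage**: score distributions across TNM stages
  (singleton stages excluded with a warning) and a joint Cox model with
  the signature and a binary advanced-stage covariate, reporting both
  hazard ratios.

The shipped published-model asset contains feature names, training
means/SDs, and coefficients, but no threshold (not reported at the
source) and no baseline hazard — it supports scoring and *relative*
risk ordering out of the box; absolute stratification needs a
user-supplied τ or a calibration cohort.

## Synthetic data

**Feature-level cohorts** draw features from an equicorrelated
multivariate normal (pairwise correlation ρ, default 0.2); survival is
exponential with hazard (1/b)·exp(Σ β_true x_true), b = 60 months, and
censoring is an independent Uniform(0, 75 months) administrative time.
These defaults give ~57 % censoring and a median follow-up in the
mid-30s of months, the regime of a retrospective head-and-neck cohort.
The constant baseline hazard is chosen for closed-form checks
(Kaplan-Meier against exp(−t/b) is tested); the censoring mechanism is
a parameter, since real cohorts rarely document theirs.

**Phantom cohorts** build ellipsoidal tumors (default radii 12×10×9 mm,
lognormally jittered across patients, fractional SD 0.15) on an
anisotropic grid (default 0.625×0.625×3 mm — typical 1.5 T
acquisition geometry) over a smooth background ramp. The tumor interior
is a constant modality mean plus amplitude × a unit-variance
Gaussian-filtered white-noise field whose filter width (the texture
correlation length, default 4 mm) is modulated by a latent per-patient
risk: ℓ_eff = ℓ·exp(0.35·latent), latent ~ N(0, 1) truncated at ±2.5.
Longer correlation length produces longer gray-level runs, so the
latent risk is recoverable from run-length and co-occurrence features
(monotonicity is tested). Survival follows the same exponential PH
model on the latent risk. T1w and T2w share geometry and texture field
and differ in contrast (tumor hypo- vs hyper-intense). Randomness is
organized as per-patient substreams spawned from the cohort seed, so
extending a cohort never reshuffles existing patients.

What the phantoms do *not* emulate: anatomy, MRI physics (bias fields,
k-space artefacts, Rician noise), inter-scanner variation, multi-reader
segmentation beyond rigid translation, and non-proportional hazards.
Passing end-to-end tests therefore demonstrates that the pipeline's
machinery is correct and recovers a known texture-survival link under
its own model assumptions — not that the published effect sizes
transfer to clinical data.

## Problem sizes and runtime choices

Tests and the end-to-end suite run at deliberately reduced sizes, as
their own design choice: phantom grids of 48×48×16 voxels at 1×1×3 mm
(≈ 24³ after 2 mm resampling), cohorts of 120 patients split in half,
and selection at 20 bootstraps × 5 repeats. At these sizes one full
pipeline run (simulate → preprocess → extract, including the 5-condition
stability re-extraction on the training half → screen → select → train
→ evaluate) takes ~2 minutes. The full-protocol defaults (100 × 20
selection; Table-1-like 0.625 mm grids) are what `RunConfig` ships
with.

## Known limitations

- No LoG or other filter banks; no 2D slice-wise extraction; only the
  four feature classes listed (the per-modality arithmetic fixes the
  inventory at 536).
- No time-dependent covariates, competing risks, or proportionality
  diagnostics; no LASSO/mRMR selection alternatives.
- Shape's 2D diameters use voxel centres (half-voxel downward bias on
  very small ROIs).
- The wrapper-forward search is greedy; it is bounded by, but need not
  attain, the best-subset validation C-index (both are logged in the
  corresponding test).
- The published signature asset cannot be used for absolute risk
  stratification without an external threshold (see above).
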