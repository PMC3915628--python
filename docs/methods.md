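# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `morphosvm`, in the order data flows through the pipeline.

## Density maps and mass preservation

A density map assigns each template-space voxel the amount of tissue (grey
matter, white matter, or ventricular CSF) a subject carries at that
anatomical location. The defining contract is conservation of tissue mass
under spatial operations.

**Warp.** `mass_preserving_warp` consumes a displacement field (voxel units,
subject → template) and pushes each source voxel's mass to its displaced
location, split among the 8 surrounding grid cells by trilinear weights.
This conserves total mass to machine precision by construction; compression
concentrates mass (density rises), expansion dilutes it. Displacements that
would carry mass outside the field of view are clamped to the boundary so no
mass is lost; callers should pad volumes if boundary pile-up matters. The
package deliberately does not estimate registrations — deformation fields
are inputs (synthetic fields in the tests), because registration estimation
is a separate, solved problem with dedicated tools.

**TBV normalization.** `normalize_tbv` rescales all compartments by one
factor so the total brain volume (sum of tissue + CSF amounts) equals a
reference constant of 1.0, making maps fractions of brain volume. Any
positive constant is equivalent (the classifier is scale-invariant); 1.0 is
the simplest. The operation is idempotent and preserves every
between-compartment ratio. Normalization is applied *before* smoothing; the
order is exposed through the generator/pipeline configuration because either
order is defensible and they differ only at the boundary.

**Smoothing.** `smooth` applies a Gaussian with σ = FWHM/(2√(2 ln 2)) per
axis, converted from mm to voxels (8 mm on 2 mm voxels gives σ = 1.699
voxels). At volume edges the truncated kernel is renormalized per *source*
voxel — implemented as G(m/W) with W = G(1) — so each voxel redistributes
exactly its own mass and the total is conserved, matching the map semantics
(plain zero-padding would leak mass; reflection would distort gradients).

**Ventricle isolation** is intersection with a template-space ventricle
mask. The original automated isolation algorithm is unpublished; a mask
intersection preserves the downstream contract (a VENT compartment on the
shared grid) and is exact for synthetic data, where the mask is known.

## Synthetic cohorts

The generator emulates a population-based first-episode affective-psychosis
study: patient groups BD (first-episode psychotic mania) and MDD (psychotic
major depression) plus a healthy-control pool.

* **Demographics.** Age ~ Normal(group mean, group SD) truncated to the
  study's 18–50 inclusion window; gender, handedness, and scanner are
  Bernoulli draws. Group marginals are the published ones (BD 27.09 ± 8.87 y,
  39.1% male, 100% right-handed; MDD 29.05 ± 8.34 y, 21.1% male, 84.2%
  right-handed). The control *pool* is never tabulated directly — only the
  two matched subsamples are — so its marginals are set between them
  (28.7 ± 7.3 y, 30% male, 94.5% right-handed). The scanner indicator is
  S1 with probability 0.55, matching the roughly 55/45 acquisition split.
* **Maps.** Each compartment is a constant baseline inside an ellipsoidal
  brain mask (GM 4, WM 3, VENT 1 density units) plus i.i.d. Gaussian voxel
  noise (SD 1.0 by default), clipped at zero. Group differences are planted
  as additive mean shifts of `effect_size × noise_sd` inside a sphere,
  applied to the case group (the first non-control group of the spec),
  *before* smoothing — so the planted voxel-level standardized difference is
  exactly Cohen's d. TBV normalization and 8 mm smoothing then run through
  the same code path as real data.
* **Determinism.** One `numpy` generator seeded from the spec drives every
  draw; identical specs give bit-identical cohorts.
* **What it does not emulate.** No scanner-specific intensity artifacts, no
  anatomical structure beyond the ellipsoid, no medication or substance-use
  covariates, and spatially white (pre-smoothing) noise rather than the
  long-range correlations of real morphometry. Passing tests therefore
  demonstrate the *procedural* correctness of the pipeline (no leakage,
  signal recoverable, metrics exact), not that real diagnostic groups are
  separable.
* **Normalization echo.** Because TBV normalization divides by total mass, a
  focal planted increase also produces a small diffuse *decrease* everywhere
  else in the case group. Classifiers legitimately exploit this echo —
  discriminative signatures need not coincide with the planted region. This
  mirrors real RAVENS analyses, where TBV correction redistributes focal
  effects.

**Matched-control selection** follows the study's hierarchy: gender match
first, then age within ±2 years, then handedness. Matching is individual and
greedy, cases taking turns (round-robin) so that control counts spread
evenly; ties break by smallest absolute age difference, then lowest pool
index (deterministic and auditable). As many eligible controls as available
are taken, up to an explicit `max_controls` — the source design's stopping
rule ("as many as possible") is not otherwise quantified, so the cap is a
parameter rather than a guess.

## Adaptive regional feature extraction

* **Discriminative power** of a voxel (or of a regional sum) is |Pearson r|
  between density and the 0/1 group label. Correlation is the only measure
  the method names, and it is invariant to any common affine rescaling of
  the densities. Zero-variance voxels score 0.
* **Watershed** runs on −|r| with one marker per 26-connected local maximum
  of |r|; voxels with |r| below a floor (default 0.1, configurable) are
  background. The floor is a practical noise gate — no published value
  exists — and each catchment region contains exactly one discriminative
  peak.
* **Region growing** starts at a region's peak and greedily adds the
  26-neighbor (within the watershed region) that maximizes the summed
  feature's |r|, stopping when the best candidate would *decrease* it
  (non-decreasing rule, with a 1e-9 guard so exact plateaus keep growing but
  genuine drops stop). The result is connected and never less discriminative
  than its seed.
* **Spatial consistency** is ICC(1,1), the one-way random-effects intraclass
  correlation, computed over the element's member-voxel per-subject values.
  It serves as a ranking tie-break (agreement of adjacent candidate
  features), not a hard filter.
* **Candidate cap.** The strongest `max_candidates` (default 32) seeds per
  fold are grown and pooled across GM, WM, and VENT compartments into one
  candidate set. The cap bounds fold cost and mirrors the published feature
  counts' order of magnitude at synthetic scale.

## Feature selection and classification

"SVM criteria" selection is implemented as recursive backward elimination on
linear-SVM weight magnitude (half of the surviving features dropped per
round), which yields a full ranking; the retained subset size is then chosen
over a doubling ladder (1, 2, 4, …, all) by stratified internal
cross-validation (≤ 5 folds) of the RBF classifier on the training data
alone, ties to the smaller size. The procedure is deterministic given data
and configuration.

The classifier is a Gaussian-RBF SVM, C = 1 and gamma = 1/(n_features ×
feature variance) by default (no published values exist; both are exposed),
with features standardized using training-fold statistics only.

**Class weights are always balanced by inverse class frequency.** This is
load-bearing: a leave-one-out harness trains on folds imbalanced by exactly
one subject, and an unweighted SVM on weak features drifts toward the
majority class — which is systematically the *opposite* of the held-out
subject, biasing null accuracy far below chance (an artifact of the
validation design, not a property of the data). With balanced weights the
held-out subject, being independent of its training fold, is scored
symmetrically; 20-cohort null calibration then centers accuracy and AUC at
chance.

## Cross-validation and evaluation

* **Nesting.** Per fold, the entire extraction–selection–training procedure
  re-runs on the training subjects; the held-out map is only summed over the
  selected elements' voxels and scored. A fold with no above-floor voxels
  (rare) falls back to a zero score and majority vote.
* **Scores.** Pooled held-out decision values are standardized to Z scores
  (zero mean, unit variance across the evaluated set). Predictions use the
  classifier's own sign; ROC, AUC, and threshold analysis use the Z scores
  (rank-preserving, so AUC is unchanged by the standardization).
* **AUC** is computed as the probability that a random positive outscores a
  random negative (ties ½) — the rank-statistic definition — and is verified
  in tests to coincide with trapezoidal integration of the ROC staircase.
* **Best threshold** maximizes overall accuracy over midpoints between
  consecutive distinct scores (plus sentinels), ties resolved toward higher
  specificity (i.e. the higher cut).
* **Percentages** are rounded half away from zero to 1 decimal (2 where the
  source prints 2). Two published cells (an NPV of 66.6 and a specificity of
  52.1) are truncations of 66.67 and 52.17; the package rounds (66.7, 52.2)
  and documents the discrepancy rather than mimicking truncation. The
  confusion reconstruction accepts a per-call tolerance: 0.05 percentage
  points covers pure rounding; truncated cells need 0.1.

## Calibration experiments and problem sizes

The acceptance experiments run cohorts of 20 + 20 subjects on 16³ grids
(2 mm voxels), noise SD 1.0, 8 mm smoothing: 20 seeds with no effect and 10
seeds with a d = 2.5 sphere of radius 3 voxels in GM. These sizes give each
LOOCV fold a realistic subject-to-feature regime while keeping a full
calibration run to a few minutes on one CPU. Measured with this package:
null mean accuracy 0.489–0.528 across seed bases (binomial band 0.465–0.535
for 800 predictions), null mean AUC 0.49–0.55, planted-effect accuracy
≥ 0.75 in 10/10 seeds. Note the binomial band treats the 800 held-out
predictions as independent; folds within a cohort share training data, so
the effective variance of the 20-cohort mean is somewhat larger (per-cohort
accuracy SD ≈ 0.10).

## Known limitations

* Synthetic anatomy is an ellipsoid; no cortical geometry, no
  template-registration error model, no scanner effects.
* The warp clamps out-of-bounds mass to the boundary rather than erroring.
* Ventricle isolation assumes a given mask; the original automated algorithm
  is not reproduced.
* The precise "SVM criteria" of the original selection step are unspecified
  in print; weight-magnitude RFE is one reasonable reading.
* Real-data diagnostic performance (the published AUCs near chance) cannot
  be reproduced without the original scans and is out of scope; the package
  reproduces the printed table arithmetic exactly and the procedural
  properties (leakage-freedom, signal recovery) by simulation.
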