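# Methods

This note documents the models, conventions and numerical choices behind
`sfcoupling`, and what the synthetic cohorts can and cannot tell you about
real data.

## 1. Connectome construction

**Structural symmetrization.** Probabilistic tractography emits a directed
count matrix `S`: `S_ij` streamlines seeded in ROI i reached ROI j. We
symmetrize and normalize as

    W_ij = (S_ij + S_ji) / (samples_per_voxel · (N_i + N_j))

with `N_i` the ROI's voxel count and `samples_per_voxel` the number of
samples initiated per seed voxel (default 5000). Dividing by the total
number of initiated samples in both ROIs converts counts into a connection
probability that is comparable across ROIs of different sizes; when both
`S_ij ≤ samples_per_voxel · N_i` and the reverse hold, `W_ij ≤ 1`. The
arithmetic admits a second reading — multiplying by `(N_i + N_j)` — which
is available as `sc_normalization="multiply_by_volumes"`; the default is
the probability reading because it is the standard normalization for
probabilistic tractography. Coupling, the headline statistic, is a rank
correlation and is identical under any monotone reparameterization of `W`,
so this choice affects absolute weights but not coupling itself.

**Functional connectivity.** Pearson correlation of ROI time series,
Fisher z-transformed (`atanh`), diagonal set to 0 and never used. A
constant column or a perfectly correlated pair (|r| = 1, infinite z) is an
error naming the offending ROI, not a silent clip: both indicate broken
input, and the synthetic generator cannot produce them.

**Consistency thresholding.** For every candidate edge (nonzero in at
least one subject) we compute the cross-subject coefficient of variation
CV = sd/mean of its weight, with zeros included and sd the sample standard
deviation (ddof = 1). Including zeros is deliberate: an edge present in
only a few subjects has enormous CV and is exactly the kind of
tractography false positive the criterion exists to remove. The
`ceil(f · E)` highest-CV edges (default f = 0.30) are zeroed in every
subject; ties are broken by ascending edge index so runs are
deterministic. The alternative reading of a "30th percentile" cut —
keeping only the lowest-CV 30% — is implemented as `mode="keep_bottom"`.
Diagonals are never candidates.

## 2. Features

**Structure–function coupling** of ROI i in subject s is the Spearman
correlation (average ranks for ties) between that subject's thresholded
nonzero structural weights `{W_ij : W_ij > 0}` and the Fisher-z functional
values `{Z_ij}` on the same edges. ROIs with fewer than `min_edges = 3`
surviving edges give NaN — a Spearman over 2 points is ±1 by construction
and carries no information. Before prediction, ROIs that are NaN for any
subject are dropped listwise from *all* feature tables so every model sees
identical columns; the dropped set is logged and written alongside the
feature tables. Negative functional weights participate as-is.

**ALFF.** Raw ALFF of a ROI is the mean one-sided amplitude spectrum
`2·|FFT(x − mean)|/T` over frequencies in 0.01–0.1 Hz inclusive, then
z-scored across ROIs within subject. Z-scoring at ROI level is an
approximation to z-scoring voxel maps before averaging (the two do not
commute), adopted because this package operates on parcellated data only.
The amplitude scale is arbitrary; only the within-subject pattern
survives the z-score.

**Degree centralities.** sDC(i) sums a ROI's nonzero structural weights;
fDC(i) sums the functional values on that same structurally present edge
set (parallel to the coupling definition). Summing the full functional row
instead is available as `fdc_edges="all"`; the two differ whenever an edge
carries FC but no SC.

**GMV** is a validated passthrough of per-ROI gray matter volumes from
tabular input; map-level processing is out of scope.

## 3. Prediction

Per feature table, K-fold (default 10) cross-validation with shuffled fold
assignment determined only by `(seed, n_subjects, n_folds)`. Within each
training fold, in order:

1. *Covariate residualization* (default mode `residualize_features`):
   each feature column is regressed on [1, covariates] with training-fold
   OLS and the training-fold coefficients are applied to the held-out
   fold. `residualize_both` also residualizes the score (predictions are
   shifted back to the score scale with training-fold coefficients);
   `none` disables adjustment. Default covariates: age, sex, mean
   framewise displacement.
2. *Filter*: Spearman correlation of each column with the training
   scores; two-sided p from the t approximation
   `t = ρ·sqrt((n−2)/(1−ρ²))` on n−2 df; keep columns with p < 0.05
   (uncorrected). Constant columns are excluded with a warning.
3. *Standardize* selected columns by training-fold mean/SD. Without this,
   L2 weights are incomparable across ROIs and summed-weight rankings
   would be meaningless.
4. *Fit* an L2-regularized L2-loss (squared-epsilon-insensitive) linear
   SVR — liblinear's primal formulation (`dual=False`, deterministic),
   C = 1, epsilon = 0, tol = 1e-4 — and predict the held-out subjects.

A fold that selects zero features predicts its training-score mean, so
every subject is out-of-fold exactly once; a run where all folds are empty
is flagged `degenerate`. Metrics are computed on pooled out-of-fold
predictions: Spearman ρ (headline), Pearson r, MAE, MSE.

Per ROI we report the selection count across folds, the sum of signed SVR
weights over folds where selected (exactly 0 where never selected), and
the mean ± SD of the filter correlation across folds. ROIs selected in
every fold form the *most predictive* set. Weights are summed signed, not
absolute; an ROI whose sign flips across folds self-cancels, which is the
honest reading of "summed weights".

**Permutation test.** Each of B permutations (default 5000) reshuffles the
score vector across subjects — covariates stay with their subjects — and
reruns the complete pipeline including the in-fold filter, so the null
distribution honors every data-dependent step. One-sided p with the
add-one convention, `p = (1 + #{ρ_null ≥ ρ_obs}) / (1 + B)`, which can
never be 0; one-sided because the alternative of interest is positive
predictability.

## 4. Mediation

Simple (single-mediator) mediation by three OLS regressions, covariates
optional in every equation:

    M = a·X + …,   Y = c′·X + b·M + …,   Y = c·X + …

so `c = c′ + a·b` holds exactly on any fitted sample. The indirect effect
is a·b; the partially standardized indirect effect divides by the sample
SD of Y (ddof = 1), making it invariant to rescaling the outcome.
Uncertainty comes from a percentile bootstrap over subjects (default
5000 resamples, 95% interval); bias-corrected intervals are deliberately
not used — percentile is the conventional default for this model family.
"Full mediation" is reported as a descriptive label (indirect CI excludes
0 and the direct path's p ≥ 0.05), not an inferential claim. X and M with
|r| > 0.999 are rejected as collinear: the b and c′ paths are then not
identifiable. The mediator may be a single ROI's coupling or the mean over
an ROI set; both are exposed in the CLI.

A specificity utility computes Spearman ρ and p between feature columns
and nominally irrelevant variables (e.g., IQ, hearing threshold).

## 5. The synthetic cohort generator

The generator's job is to produce cohorts in which the analysis's
assumptions hold by construction and ground truth is known. Defaults
describe a 106-subject cohort; the full construction with all constants is
in the `sfcoupling.synthetic` module docstring. Design reasoning:

- **Only monotone structure matters.** Coupling is a rank correlation, so
  the generator plants a monotone SC→FC relation (rank-mapped target
  correlations) rather than any particular functional form.
- **Latent coupling λ ∈ (0,1)** per subject and ROI controls the noise on
  the monotone relation via
  `sd = 0.02 + 2.0·((1−λ_i)(1−λ_j))²`. The multiplicative, squared form
  keeps an edge clean whenever *either* endpoint is strongly coupled;
  because functional edges are shared between two ROIs, an additive form
  would let neighbors' decoupling drown the ROI's own signal and make the
  per-ROI rank correlation an unusable readout of λ.
- **Signal circuit.** ROIs listed in `signal_rois` share a subject-level
  coupling factor (pairwise correlation 0.6), as expected for regions of
  one functional circuit; the behavioral score is
  `score_mean + effect_size·score_sd·z(mean λ over circuit) + noise_sd·ε`.
  Defaults `score_mean = 22`, `score_sd = 3` mimic an averaged
  music-perception battery score spanning roughly 14.5–29.5;
  `noise_sd = 1.8` makes the total score SD equal 3 at the reference
  effect size 0.8. `effect_size = 0` yields a fully null cohort.
- **Band-limited time series.** ROI series are Gaussian noise restricted
  to 0.01–0.2 Hz (the same spectral mask for every latent column, so the
  mixing through the Cholesky factor of the target correlation matrix
  preserves cross-ROI correlations exactly in expectation). Band-limiting
  matters quantitatively: a series band-limited to `[f1, f2]` of duration
  D has only ≈ 2·(f2−f1)·D effective degrees of freedom for correlation
  estimation. At the default 300 timepoints × 2 s this is ≈ 230 — enough
  for the planted signal to be recoverable — whereas a 0.01–0.1 Hz band
  would halve it.
- **Spurious structural edges** (8% of the backbone count, present in 20%
  of subjects with weaker counts) are planted so consistency thresholding
  has something real to remove; their cross-subject CV exceeds the
  backbone median by construction.
- **Target correlation repair.** The edge-wise target matrix is generally
  not positive semidefinite; it is projected by eigenvalue clipping (floor
  1e-3) and diagonal renormalization. This distorts planted edge values
  slightly (and is one of the two attenuation sources between latent λ and
  measured coupling, the other being finite-series sampling noise).
- **Fast mode** (`mode="fc"`) stores the Fisher-z FC matrix and a per-ROI
  log-normal spectral-model ALFF instead of raw time series.
- **A known side channel**: planted edge correlations are clipped to
  [−0.9, 0.95], and heavily noised edges (decoupled ROIs) are clipped
  asymmetrically around the positive edge baseline, so a ROI's *summed*
  functional weight is mildly increasing in its coupling level. fDC can
  therefore inherit a weak indirect association with the score on signal
  cohorts. The coupling feature remains clearly stronger (the comparison
  checks rely on the margin, not on fDC being exactly null), but fDC
  should not be treated as a pure negative control.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real MRI: hemodynamics and autocorrelated
physiological noise, scanner/site effects, spatial autocorrelation of
parcels, motion-coupled artifacts (motion is an independent covariate
unless `motion_confound` is set), distance-dependent tractography biases,
and any voxel-level phenomenon. Tests on synthetic cohorts validate the
*statistical machinery* — leakage-free cross-validation, calibrated
permutation nulls, correct thresholding and feature arithmetic, parameter
recovery when the generative assumptions hold — not claims about brains.

## 6. Numerical conventions and degenerate inputs

- Spearman everywhere uses average ranks for ties; coupling values sit on
  a finite rank lattice (a Spearman over m edges has O(m³) achievable
  values), so exact cross-subject ties are normal at realistic edge
  counts.
- Filter p-values use the t approximation, consistent between the
  in-fold filter and its tests; |ρ| = 1 maps to p = 0.
- Fold assignment: scikit-learn `KFold(shuffle=True, random_state=seed)`.
- The SVR maximum iteration count is 10000; convergence warnings at the
  default tolerance are suppressed as noise.
- All pipeline outputs are plain text (TSV/JSON) written with fixed
  formats; two runs from the same config and seed are byte-identical
  (stage wall-times go to the log file only).
- Problem sizes used by the shipped checks — 106 subjects × 30 ROIs for
  study-scale recovery (25 seeds), 60 × 12 for null calibration (200
  cohorts × 99 permutations), 999–4999 bootstrap/permutation draws — were
  chosen as the smallest sizes at which the Monte-Carlo error of each
  check is comfortably below its decision margin.

## 7. Known limitations

- ALFF z-scoring at parcel level is not identical to voxel-level z-scoring
  followed by parcel averaging.
- The permutation test permutes scores only; covariates stay attached to
  subjects. Under strong covariate-score dependence a Freedman–Lane-style
  scheme would be more exact; it is not implemented.
- Mediation is a single-mediator model with no serial/parallel mediators,
  no moderated mediation, and no sensitivity analysis for unmeasured
  confounding; "full mediation" is a reporting label only.
- No hyperparameter search: C is fixed (configurable), matching the
  "default parameters" convention of the modeled analysis.
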