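# Methods

This note documents the models, defaults and numerical choices behind
`falffmvpa`, and what its synthetic benchmarks do and do not establish
about real resting-state data.

## The fALFF statistic

Each voxel's series is linearly detrended, confound-regressed (OLS on an
intercept plus six motion regressors, a linear trend and white-matter/CSF
signals) and Fourier transformed; the amplitude spectrum is the square root
of the power spectrum. fALFF is the sum of amplitudes over bins whose
centre frequency lies in the closed interval 0.01–0.08 Hz divided by the
sum over 0–0.25 Hz. Conventions:

- The DC bin is excluded from both sums: at 0 Hz the coefficient carries
  the mean, not fluctuation.
- Bands are unions of whole bins; no interpolation at band edges. A full
  band reaching beyond the Nyquist frequency (0.25 Hz at TR = 2 s) is an
  error that names the achievable maximum.
- A numerically constant series (full-band amplitude below a
  100·ε·N·scale floor) returns fALFF 0 rather than a 0/0 ratio.
- The z-map standardises fALFF to mean 0, SD 1 across in-mask voxels only.

A literal band-pass filter of 0.01–0.10 Hz before computing fALFF would
empty the 0.08–0.25 Hz part of the denominator and make the ratio nearly 1
everywhere; the ratio formula is therefore the operative definition and
the default pipeline computes fALFF on the unfiltered (confound-regressed)
series. A `prefilter` option applies the narrow band-pass anyway for
sensitivity analyses, since some published pipelines describe that
ordering.

## Synthetic cohorts

Nothing in the analysis sees more than the amplitude spectrum, so the
generator plants the minimal structure fALFF can detect. A voxel series is

```
white noise (sd 1)
+ amp · band-limited (0.01–0.08 Hz) Gaussian component, unit RMS
+ linear drift (slope sd 0.05)
+ loadings (sd 0.05) on shared confound signals
```

with `amp = osc_amp · exp(N(0, 0.2)) · cluster factor` per voxel and
subject. Patient-group effect voxels get `amp` multiplied by
`1 + effect_size`.

Three design choices deserve comment:

- **Regional covariance.** Voxels of one planted cluster share a
  per-subject lognormal amplitude factor (`cluster_jitter_sd = 0.3`).
  Functional clusters in real data rise and fall together across subjects;
  without this, a group effect spread over 50 voxels and calibrated to a
  given overall detectability would be invisible at single-voxel level, so
  no voxelwise screen could ever find it. With it, per-voxel and
  multivariate detectability scale together, as they do in practice.
  Within-subject z-standardisation removes a *global* amplitude factor, so
  the shared factor is regional, not global.
- **Deterministic geometry.** Cluster seed points come from farthest-point
  sampling over the mask and grow breadth-first to ~10 voxels each, so the
  planted "anatomy" is a fixed property of the grid and only subjects and
  noise vary with the seed.
- **Effect size.** The default `effect_size = 0.35` was calibrated once so
  that a large-sample linear-discriminant oracle given the true voxel set
  classifies at ≈ 0.80 accuracy — a moderate, realistic effect for a
  140-subject fMRI study — and then frozen.

The treated patients' attack-frequency reduction is a linear function of
their baseline z-fALFF at 5 predictive voxels (spread across clusters)
plus Gaussian noise; `outcome_snr` sets the noise SD as a fraction of the
linear predictor's SD within the cohort. The raw linear outcome is then
affinely mapped to a clinical scale (mean 1.45, SD 2.5 attacks/month,
consistent with a paired t ≈ 3.3 at n = 33); an affine map leaves every
correlation-based result unchanged. When a large planted reduction would
push the post-treatment frequency below zero, the baseline frequency is
raised instead so the planted reduction stays exact.

Covariate distributions (age, sex proportions, SAS/SDS/MSQ, baseline
frequency, mean framewise-displacement-like head motion) default to the
published cohort summaries for the patient group; control-group
questionnaire values are generic healthy-range choices, and none of these
defaults is a claim about the real cohort's subject-level distributions.

What passing the synthetic benchmarks shows: the pipeline is correctly
wired, calibrated under the null, and recovers planted spectral and
outcome structure at realistic sizes. What it does not show: robustness to
spatial autocorrelation of noise, non-Gaussian artefacts, registration
error, physiological confounds, or any property of real migraine data.

## Screening and cross-validation

The voxelwise screen fits `z-fALFF = β₀ + β₁·group + covariates` per voxel
and tests β₁ (t with df = n − 2 − #covariates; equal to the pooled
two-sample t when no covariates are given; sex coded 0/1, which does not
affect the group t). Benjamini–Hochberg selection is implemented as |t|
cutoffs precomputed per (m, df, q), mathematically identical to the
step-up rule on two-sided p-values but cheap enough to re-run inside every
fold and permutation.

Two screening modes are provided deliberately. `whole_sample` reproduces
the original workflow (screen once on everyone, then cross-validate);
`per_fold` — the default — recomputes the screen inside each training fold
so the held-out subject never influences feature selection. The benchmark
suite reports both side by side: whole-sample accuracy is systematically
optimistic, per-fold accuracy is the honest estimate.

Under a null cohort the FDR screen legitimately selects nothing, which
would leave the classifier without features; the screen then falls back to
raw p < 0.05 and, failing that, to all voxels, so cross-validation is
total. A `k` in the feature-count grid that exceeds a fold's surviving
feature count is capped to that count for the fold (with a warning) rather
than skipped, because in per-fold mode the surviving count varies across
folds and skipping would leave subjects without predictions.

SVM and SVR are libsvm-backed (`sklearn.svm.SVC`/`SVR`) with linear kernel
and C = 1 — the toolbox defaults the original workflow implies — with
per-fold standardisation (training mean/SD applied to the held-out
subject) because margin methods are scale-sensitive. Ties on the accuracy
curve go to the smallest k (parsimony). The weight map at the best k is
the mean of fold weight vectors (de-standardised) re-expanded to voxel
space, with zeros where a voxel went unselected; a voxel is
"discriminative" if its mean weight is nonzero, and Study 2's chain
integrity asserts the SVR sees only those columns.

## Permutation inference

The permutation statistic re-runs the cross-validated procedure under
permuted labels and uses the add-one estimator
p = (1 + #{null ≥ observed}) / (1 + n_perm) ∈ (0, 1]. In per-fold mode
everything, including the screen, is re-run per permutation. In
whole-sample mode the screen computed on the real labels stays fixed while
labels are permuted: re-screening on permuted labels would hand every
permutation its own overfit feature set and push null accuracies toward
1.0, destroying the test's power; holding the screen fixed matches how the
original workflow's permutation distribution behaves (null centred near
chance). Both facts are verified in the test suite.

## Post-hoc statistics

Paired t, summary-statistics two-sample t (pooled by default; Welch
optional — with near-equal SDs and equal n they agree to two decimals) and
the uncorrected 2×2 Pearson chi-square delegate to scipy. Partial
correlation is computed by residualising both variables on
[intercept, covariates] and correlating residuals, with
p from t = r·√(df/(1−r²)) at df = n − 2 − #covariates; scipy's plain
Pearson p would use the wrong df, which is why this one is hand-rolled
(and cross-checked against pingouin). FDR across regions reuses the same
BH routine as the screen.

## Benchmark problem sizes

The calibration and recovery suites run at reduced scale chosen to keep a
laptop run comfortable while preserving the statistics of interest: null
calibration uses 50 cohorts of 20 + 20 subjects × 1,000 voxels with
100-permutation tests; classification recovery uses 10 cohorts of 30 + 30
subjects × 2,000 voxels with 50 planted voxels; outcome recovery uses 20
cohorts of 33 treated patients × 1,000 voxels at SNR 1 (shuffled-outcome
controls on 10 of them). Feature-count grids in these runs are small
explicit lists (e.g. 10/25/50/100), exercising the same search code as the
full-resolution grid. The acceptance script uses the same conditions at
smaller replicate counts.

## Known limitations

- The generator's noise is temporally white outside the planted band and
  spatially independent outside planted clusters; real BOLD noise is
  autocorrelated in both senses.
- Only baseline scans are generated; the post-treatment fALFF-change
  analyses operate on user-supplied or test-constructed region values.
- Anatomical labelling of clusters is out of scope; clusters are reported
  by grid (optionally affine-mapped) coordinates.
- LOOCV accuracy under the null is slightly pessimistic (below 0.5), a
  known property of leave-one-out with class-balanced folds, visible in
  the calibration suite's distribution.
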