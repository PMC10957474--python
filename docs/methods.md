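# Methods

## Model and assumptions

The core model is a Bayesian multivariate regression on additive
log-ratio (alr) coordinates of relative abundances — the logistic-normal
model on the simplex.  Its assumptions, in decreasing order of
importance:

- **Compositionality.** Only ratios between features carry information;
  all inference is in log-ratio coordinates, and every reported summary
  (clr coefficients, contrasts, rankings, balances) is invariant to the
  alr reference used during fitting.
- **Linear trajectories.** Expected log-ratio abundance is linear in the
  visit index (0-3).  Visit is treated as the dose axis (one infusion per
  visit); calendar-time variation is carried separately by the
  mean-centered days-since-first-infusion covariate.
- **Proportion-only observation.** The alr vector is computed
  deterministically from zero-replaced proportions; no multinomial count
  layer is fitted, so sequencing-depth noise is absorbed into the
  residual covariance `Sigma` rather than modelled separately.  This is
  the natural regime when only relative abundances (not totals) are
  available, and it makes the posterior exactly conjugate: no MCMC, no
  convergence diagnostics, bit-reproducible draws under a fixed seed.
- **Homogeneous residual covariance.** One `Sigma` for all samples and
  visits.

Repeated measurements are handled by a weighted-sum-coded patient
identifier in the fixed-effects design.  This makes the model exactly
reproducible (no random-effects integration) at the cost of a
rank-deficient design — patient indicators span outcome and center —
which the matrix-normal prior on the coefficients regularizes.  The
numerical rank is logged as a warning, not an error.

## Design matrix and contrasts

The 16-term focal block crosses visit, PFS12 and the three clinical
moderators (combination therapy, colitis, PPI).  Peripheral categorical
covariates use weighted-sum contrasts (columns have observation-weighted
mean zero) and continuous ones are mean-centered, so marginal means of
focal settings depend only on the focal coefficients.  Seven named
contrasts cover the study questions (overall PFS12; colitis;
colitis-within-responders; therapy-within-colitis; PFS12 within
monotherapy, within combination therapy, and within PPI users).  Averaged
moderators are weighted by their observed **joint** frequencies
(marginalized over the fixed ones, identical weights in both arms);
equal-weight averaging would be a one-line change but proportional
weights are the consistent companion of weighted-sum coding.

Significance is an equal-tailed credible-interval criterion: a feature is
flagged at Bayesian confidence level p when the central p-interval of the
contrast posterior excludes zero.  Quantiles use linear interpolation of
order statistics; the 100% level is the full range of the draws, so it is
met only when every draw has the same sign.  Flag counts are therefore
monotonically non-increasing in the level, which the tests assert.

Trajectory-shape labels are a rule set applied in fixed precedence
(stable-difference, baseline-only, emergent, crossing, case-flat,
control-flat, none), built from the per-visit significance pattern and
the per-arm slope intervals.  The taxonomy is a deliberate
simplification: it captures the canonical shapes of paired longitudinal
trajectories but collapses finer sub-patterns that are only
distinguishable graphically.

## Priors and numerics

Defaults: `Theta = 0`, `Gamma = I_Q`, `nu = D + 2`,
`Xi = (nu - D) I_{D-1}`, giving prior mean `Sigma = I` on the alr scale —
a weakly-informative choice that shrinks coefficients toward zero with
unit prior variance.  All hyperparameters are configurable and recorded
in the output manifest.  Numerical choices:

- zero replacement: multiplicative, `epsilon = 1e-6` per zero part
  (configurable).  The replacement is mandatory plumbing — the alr needs
  strictly positive parts — and the default generator produces no zeros,
  so the pipeline's zero policy can be studied in isolation via the
  generator's `zero_rate` / `seq_depth` options.
- alr reference: the most abundant feature (features are sorted by mean
  abundance before transforming), the most stable denominator.
- posterior sampling: `Sigma` by inverse-Wishart (scipy's Bartlett-based
  sampler), `Lambda | Sigma` by the Cholesky matrix-normal construction;
  one root seed, `S = 2000` draws by default.
- symmetrizations (`(A + A') / 2`) guard the conjugate updates against
  floating-point asymmetry.
- ties in rankings break lexicographically by feature ID; ties at the
  median in balance stratification go to the Low stratum; AUC uses
  midranks.

## Classical statistics

The two-sample proportion test reproduces the R `prop.test` convention —
Yates-corrected Pearson chi-square (correction clamped at the observed
deviation) and a Wald interval widened by the continuity term
`(1/n1 + 1/n2) / 2` — because that is the convention under which the
cohort comparisons this package re-derives were originally reported.
Fisher's exact test and the large-sample Wilcoxon delegate to scipy; the
Wilcoxon switches to exact enumeration for combined n <= 12 without ties.
Survival fitting delegates to lifelines (Efron tie handling, suitable for
month-resolution times); proportional hazards are checked by the trend of
scaled Schoenfeld residuals against Kaplan-Meier-transformed time.  A
small Breslow score test is included for the classical score-test /
log-rank equivalence check.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
so every stage is testable without sequencing data:

- 175 patients; per-visit inclusion probabilities 136/175, 146/175,
  72/175, 54/175 (independent across visits, matching the study's
  per-visit sample counts; note the design's second visit has *more*
  samples than baseline, which rules out monotone dropout); patients with
  no retained sample are dropped.  Expected cohort size ~408 samples.
- covariate frequencies from the cohort table: 33% combination therapy,
  19% colitis, 27% PPI, 14% antibiotics, 23% previous targeted therapy,
  47% PFS12, 43% female, five centers at their observed sizes; age ~
  N(62, 13) clipped to 19-94, BMI ~ N(27.6, 4.5).
- abundances from the model itself: planted focal coefficients on the
  clr scale (column-centered into the identifiable subspace), mapped to
  the generation alr system; `eta ~ N(Lambda X, Sigma*)`;
  `pi = softmax(eta)`.  Planted categories: 5 + 4 stable features
  (`b2 = +/-delta`), 4 baseline-only (`b2 = +/-delta`, `b3` closing the
  gap by visit 3), 4 emergent (`b3 = +/-delta/3`), 4 crossing
  (`b2 = -/+delta`, `b3 = +/-2delta/3`); `delta = 0.8` clr units.
- noise: residual SD 0.5 per alr coordinate with exchangeable correlation
  0.05, patient-level coefficient SD 0.3, other peripheral SD 0.1.  The
  residual scale reflects *within*-patient short-term variability —
  between-patient spread, which dominates gut-microbiome variance, enters
  through the patient coefficients and is absorbed by the patient factor
  in the fit.
- survival: exponential event times, baseline median 34.1 months, hazard
  multiplied by `exp(0.5)` for patients below the median planted balance
  at baseline, uniform administrative censoring at 24-88 months.
- default feature count D = 60, a desk-scale stand-in for the
  several-hundred-feature tables of real cohorts; `SimConfig.small()`
  shrinks the planted sets for tiny test fixtures.

What the generator does **not** emulate: phylogenetic correlation
structure, realistic abundance skew (real SGB tables are far
sparser and heavier-tailed), batch and center effects on composition,
informative dropout, or strain-level variation.  Passing recovery tests
therefore demonstrates correctness of the inferential machinery under
the model's own assumptions — not robustness to real-data violations of
them.

## Problem sizes used in the test and acceptance runs

Study-scale checks run the default generator (~408 samples x 60 features,
2000 posterior draws); unit tests use a 60-patient, 20-feature cohort.
The Metropolis cross-check of the conjugate posterior uses D = 3, Q = 2,
N = 8 with a 200k-step random-walk chain, compared to 20k exact draws via
batch-means Monte Carlo errors.

## Known limitations

- Linear visit trends cannot represent rebound or saturation within the
  sampled window.
- The BCL criterion is not a frequentist error rate and carries no
  multiplicity adjustment; under a null simulation the per-visit flag
  rate at 90% BCL is ~10% by construction.
- The proportion-only likelihood ignores depth-dependent precision
  differences between samples.
- The fixed-effects patient factor estimates patient offsets with no
  pooling beyond the prior; with one sample per patient its columns are
  fully confounded with the residual.
- External-cohort balance evaluation reports training AUC (all samples
  fit and scored), which is optimistic by construction; the repeated
  cross-validated AUC is the honest internal estimate.
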