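# Methods

This note documents the models, conventions, and numerical choices
behind `frailpanel`, and what the synthetic-data tests do and do not
establish about real cohort data.

## Accelerometer reduction (`accel`)

Input is a uniaxial count stream in 1-minute epochs (columns
`participant_id, date, minute, counts`), the standard configuration for
hip-worn devices in older-adult cohorts.

**Non-wear.** A non-wear run is a maximal stretch of zero-count minutes
in which up to `allowance_max = 2` *consecutive* minutes with counts in
(0, 100) are tolerated (and counted as non-wear); a run can neither
start nor end on a tolerated interruption minute, so wear minutes are
never swallowed at run edges; any minute at ≥100 counts breaks the run.
Runs of total length ≥ `window_min = 60` are non-wear.  This is the
Troiano-family convention ("≥60 min of zeros with a 1–2-min allowance of
counts below 100").  A strict zeros-only reading is available via
`allowance_max = 0`.  Days are processed independently — waking-hours
wear protocols give no meaning to runs spanning midnight — and minutes
are 0-based with half-open intervals.

**Intensity classification and validity.** Worn minutes partition
exactly into SB (<100 counts/min), light, and MVPA (≥1952 counts/min);
the cut-points are the ones most widely used for this population and are
configurable.  A day is invalid if any worn minute exceeds 20,000 counts
(strict inequality; device artefact screening treats the whole day as
contaminated) or if wear falls below 8 h.  The 8-h rule is applied to
*wear* minutes (a "recorded minutes" reading would be trivially
satisfied by a 24-h file); the threshold is configurable.  A participant
needs ≥4 valid days; behaviour summaries average over valid days only.

## Frailty Trait Scale scoring (`fts`)

Twelve items (BMI, waist, weight loss, albumin, PASE activity score,
verbal fluency, Romberg balance, ankle-brachial index, grip, knee
extension, chair-stand, gait time) are scored 0 (best) to 4 (worst);
the chair-stand test runs 0–5 because inability to rise even once earns
the extra worst point (implemented as a special rule for a raw value of
exactly 0, with quintiles computed over the positive values).

* **Quantile definition:** linear-interpolation empirical quantiles
  (numpy's default, equivalently `statistics.quantiles(...,
  method="inclusive")`) at the 20/40/60/80th percentiles.  Boundary
  values fall in the lower bin (right-closed intervals).  Populations
  with fewer than 5 distinct values cannot define quintiles and raise an
  error naming the item.
* **Direction:** for higher-is-better items (grip, albumin, …) the bin
  index is reversed so 0 is always the best quintile.
* **Rule-scored items:** weight loss and Romberg balance use fixed
  configured thresholds instead of population quintiles.  The published
  per-item clinical cut-offs of the original instrument are not part of
  this package; the correctness surface is the scoring machinery, and
  all thresholds are runtime configuration with documented synthetic
  defaults.  Scoring is population-wide; a sex-stratification hook can
  be added by computing cutpoints per stratum and scoring each stratum
  with its own spec set.
* **Total:** `100 · Σ scores / Σ max-scores`, both sums over the items
  the individual actually completed (the denominator is individual-
  specific), giving 0–100.  Fewer than 9 scored items (75% of 12) makes
  the battery invalid; missing items yield missing scores, never zeros.

BMI is weight (kg) / height (m)²; non-positive heights are rejected.

## Cross-lagged panel model (`clpm`)

The two wave-2 variables are regressed on both wave-1 variables plus
covariates; the wave-1 pair and all covariates form a freely covarying
exogenous block with saturated means (saturated means are required for
FIML and impose no constraints).  Wave-2 residuals covary freely.
Categorical covariates are reference-coded (k levels → k−1 indicators);
a rank-deficient exogenous block raises an error listing the aliased
columns.

**Time-varying covariates.** Each wave's outcome is adjusted for that
wave's covariate values: a covariate named `c` resolves to column `c`
if time-invariant (sex) and to `c_t2` otherwise.  The alternative
reading — both waves' values entering each equation — is obtainable by
listing both columns explicitly.  Accelerometer wear time is excluded
from the default adjustment set and added with
`include_wear_time=True`.

**Estimation.**  ML uses complete cases; FIML lets each case contribute
the marginal normal density of its observed subvector (cases are
grouped by missingness pattern and summarised by sufficient statistics,
so likelihood evaluations are independent of n).  When both equations
contain the same regressors the model is saturated and the MLE is
closed-form: for complete data, sample moments; with missing data, an
EM algorithm on the unrestricted mean vector and covariance matrix
(E-step fills expected sufficient statistics of the missing blocks;
convergence when the log-likelihood changes by <1e-10 relative, cap
2000 iterations), after which the structural parameters are read off by
the regression decomposition.  Constrained models (per-equation
covariate sets) are fitted by L-BFGS-B on an unconstrained
parameterisation — free paths directly, residual covariance as log-SDs
plus `atanh` correlation, exogenous covariance by Cholesky factor with
log diagonal — started at the saturated-solution projection, gradient
tolerance 1e-6, 500 iterations, with 3 jittered restarts on
non-convergence.  Rows missing either wave-1 endogenous variable are
excluded (they carry no structural information here), and rows missing
a categorical indicator are excluded listwise even under FIML, because
a normal likelihood is not appropriate for indicator variables; both
counts are reported.

**Inference.**  Standard errors come from the observed information —
the numerically differentiated (central, step 1e-4·(1+|θ|)) Hessian of
the pattern log-likelihood at the optimum.  Standardized paths multiply
each coefficient by sd(predictor)/sd(outcome) from the model-implied
covariance; their standard errors use the delta method with a numeric
Jacobian through the full parameter vector, so the uncertainty of the
variances is propagated rather than ignored.  Confidence intervals are
Wald, p-values two-sided normal.  Degenerate fits (residual covariance
numerically singular, e.g. noise-free data) are flagged and reported
with zero SEs rather than spurious ones.

**Fit indices.**  χ²_model = 2(llₛₐₜ − ll_model) with llₛₐₜ the
saturated FIML log-likelihood; the baseline is the independence model
(free means/variances, zero covariances — under missing data its MLE
factorises per variable).  RMSEA = √(max(χ²−df, 0)/(df·n)) with n the
number of cases used (the n-convention, configurable in principle;
df = 0 gives RMSEA 0 and CFI = TLI = 1 by convention);
CFI = 1 − max(χ²_M−df_M,0)/max(χ²_B−df_B, χ²_M−df_M, 0);
TLI = ((χ²_B/df_B) − (χ²_M/df_M)) / ((χ²_B/df_B) − 1); SRMR is the RMS
of the correlation-metric residuals between the saturated and implied
covariance matrices over the lower triangle including the diagonal.
The baseline model contains the same variables as the fitted model,
covariates included.

**Verdicts.**  H0: neither cross path significant at α; H1: only
frailty → behaviour; H2: only behaviour → frailty; H3: both.

## Synthetic cohort generator (`synth`)

The generator's role is to produce data whose true structure is known
exactly, so the estimators can be tested for recovery, calibration and
missing-data behaviour.

* **Panel.**  All four panel variables are generated with unit variance,
  so the configured coefficients *are* the population standardized
  betas.  Defaults follow the effect sizes a two-wave ageing cohort of
  this kind reports: stability paths 0.6 (frailty) and 0.5 (behaviour),
  cross paths −0.126 (behaviour → frailty) and 0.167 (frailty →
  behaviour), wave-1 correlation ±0.2 and residual correlation ±0.1
  (sign matched to the behaviour; these two were not reported by the
  motivating cohort and are configuration, not estimates).  Wave-2
  residual variances implied by a configuration are computed
  analytically and must be positive — otherwise the offending parameter
  is named — and the implied 4×4 covariance is checked for positive
  definiteness and exposed (`implied_covariance`) for tests.
* **Covariates** are drawn with cohort-style marginals (age 76.7 ± 3.9
  with a deterministic +3.8 y at follow-up, 52.7% female, BMI
  30.8 ± 4.6, MMSE 24.0 ± 3.7, wear time 781 ± 83 min/day; education,
  income and marital status at cohort frequencies).  Covariate *effects*
  on the panel variables are zero by default and configurable per wave
  with a cross-wave stability correlation.
* **Attrition.**  MCAR is a Bernoulli deletion of the wave-2 cells.  MAR
  uses a logistic model on standardized age (+0.5), education (−0.5) and
  wave-1 sedentary behaviour (+0.5; sign flipped when the behaviour is
  MVPA), with the intercept calibrated by bisection to hit the requested
  missing rate — dropouts are therefore older, less educated and more
  sedentary than completers, the attrition profile such cohorts report.
  The default missing rate, 0.595, is the cohort-style two-wave loss.
* **Natural scale.**  Optionally, frailty maps affinely to FTS points
  (35.35 ± 13.94 → 43.79 ± 13.86) and behaviour to min/day (SB
  530.18 ± 84.86, MVPA 20.12 ± 23.30), with MVPA left-truncated at 0.
  Truncation attenuates the MVPA coefficients, which is why recovery
  tests run on the standardized scale.
* **Epoch streams** place zeros outside a wear window and in non-wear
  blocks, MVPA bouts and optional light bouts and spike minutes at fixed
  counts, and a log-normal sub-100 background clipped to [1, 99] on worn
  minutes, so worn sedentary time is never confused with device-off
  zeros.  Profile validation rejects overlapping segments, non-wear
  blocks shorter than the detection window or closer together than the
  interruption allowance, and off-wrist margins shorter than the window
  — configurations whose ground truth would be ambiguous under the
  detection rules.
* **FTS batteries** draw raw values either from plausible continuous
  marginals or, when per-item cutpoints are supplied, with uniform
  quintile membership (the true bin is returned for oracle tests).

**What passing tests do not show.**  Real accelerometer data contain
worn zero-count stretches (quiet sitting), device artefacts other than
single-minute spikes, and non-wear that is neither pure zeros nor
neatly separated — the generator's clean separation makes ground truth
well-defined but means field data will always contain ambiguous minutes.
The panel generator is multivariate normal with linear effects; it does
not emulate floor/ceiling effects in FTS scores (beyond optional
truncation), non-linear age effects, or informative (MNAR) dropout, so
the FIML results certify correctness under MAR, not robustness beyond
it.

## Pipeline (`report`)

The driver simulates (or ingests) a cohort, optionally re-derives
behaviour through real epoch simulation + reduction and frailty through
battery construction + scoring, splits follow-up losses into
death/refusal/not-located in cohort-style proportions, applies the
exclusion cascade (losses → invalid accelerometry → invalid FTS →
participants missing >20% of covariate cells), tabulates descriptives
(paired t between waves on complete pairs; Welch t by default — pooled
optional — and Pearson χ² without continuity correction for attrition
comparisons, with a "trend" flag for 0.05 < p < 0.08), and fits both
CLPMs.  ML fits use the cascaded analytic sample; FIML fits keep
dropouts' wave-1 information while still applying the data-quality
exclusions.  Stage arithmetic in `CohortFlow` is enforced at
construction, not merely tested.  All stages derive their seeds from the
single config seed; identical configs give byte-identical result JSON.

## Problem sizes used by the test suite

Recovery and calibration suites use 200 replicates at n = 5000 (bias
and CI coverage), 1000 replicates at n = 500 (type-I error), 100 seeds
at n = 5000 (verdict power), n = 10⁴ with 30% MCAR (FIML validity), and
200 seeds at n = 2000 with 59.5% MAR dropout (FIML vs complete-case
bias); non-wear detection is cross-checked against an independent
brute-force scan on 500 random 1440-minute streams.  These sizes give
Monte-Carlo standard errors comfortably below the tolerances they are
tested against.

## Known limitations

Two waves only (no random-intercept CLPM, no latent measurement
models); normal-theory SEs (no sandwich or bootstrap); categorical
covariates handled listwise under FIML; uniaxial counts only (no
vector-magnitude or raw-acceleration processing, no sitting-vs-standing
discrimination); the FTS clinical thresholds and instrument-specific
quintile boundaries are configuration, not shipped constants.
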