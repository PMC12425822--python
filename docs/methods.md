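# Methods

## Study design

Each analysis is a prospective windowed design on calendar time:

* **observation period** (default 1999-01-01 … 2008-12-31): the only
  window from which predictors may be drawn;
* **washout period** (2 years before baseline): a buffer during which no
  predictors are recorded, limiting reverse-causation leakage from
  prodromal diagnoses;
* **baseline** (default 2011-01-01): eligibility and age are assessed
  here; survival time starts here;
* **prediction period** (default through 2018-12-31): first qualifying
  diagnosis inside this window defines a case; everyone else is censored
  at end of follow-up or the prediction horizon.

Eligibility keeps persons aged 32–70 (whole years) at baseline, satisfying
any sex restriction, with follow-up reaching baseline, no case diagnosis
on or before baseline, and (by default, configurable) no first case
diagnosis after the prediction period. Exclusion reasons are applied in a
fixed order so the tally partitions the removed persons. Durations are day
counts divided by 365.25. A 6-year observation preset
(`short_observation_design`) supports registers with shorter coverage;
window endpoints are plain configuration, so an observation window ending
in 2009 (one less year of washout) is equally expressible.

## Predictors

Raw ICD codes are uppercased and stripped of non-alphanumerics, looked up
per code system in the phecode map, and — on a miss — truncated one
trailing character at a time until a match or exhaustion. Truncation may
cross the 3-character ICD-10 category boundary; such matches are flagged
in the mapping report rather than rejected. Matched phecodes are rolled up
to their three-digit parent (string before the decimal point), and a
person's feature is the binary indicator "at least one diagnosis with this
parent inside the observation window". The predictor vocabulary is the set
of parents reaching 1% prevalence in at least one cohort of the study set
(`min_prevalence`, configurable). For each target disease, a parent is
removed from the predictor set when the parent or any of its mapped
children falls (numerically) inside any interval of the disease phecode's
exclusion range — this generalizes the worked example in which conditions
complicating pregnancy (649) is banned as a type 2 diabetes predictor
because its child 649.1 lies in the exclusion range of phecode 250.2.

## The PheRS model

The score is a regularized logistic regression of case status on the
binary parent-phecode indicators plus age (years at baseline) and sex.
Protocol, in training order:

1. 50% of the cohort is reserved as the evaluation test set; the modelling
   half splits 85% / 15% into training and hold-out sets, all splits
   stratified by event status and reproducible under a seed.
2. Missing predictor values are imputed to the training mean; all
   predictors are standardized to zero mean / unit variance on the
   training data (constant columns get SD 1, standardizing to exactly 0).
3. Hyperparameters are chosen by 5-fold stratified cross-validated grid
   search maximizing average precision: L1:L2 mixing ratio over
   0.05–0.95 in steps of 0.05 (19 values) crossed with inverse
   regularization strength C over {1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3,
   1e-2, 5e-2, 1e-1, 5e-1, 1} (11 values; 209 candidates). Grid ties break
   toward larger mixing ratio, then larger C (the sparser, simpler model).
4. The final model refits on the full training set with balanced class
   weights and the saga solver (tolerance 1e-4, at most 2000 epochs).
   A ridge preset (mixing ratio fixed at 0) drops the grid's L1 dimension;
   it backs the leave-one-out importance analysis, where each phecode
   column is removed in turn and the model refit under the identical
   protocol.

The deployed score is the **linear predictor** (log-odds), not the
predicted probability. The two are monotone-equivalent, so percentile
contrasts, c-indices and per-SD hazard ratios are unaffected; the linear
predictor makes the transfer algebra transparent. Age and sex receive the
same penalty as every other predictor.

**Transfer.** The fitted model stores its training means and SDs. Scoring
any cohort standardizes the target features with those *source*
statistics; a predictor column absent from the target is treated as
all-missing, imputed to the source mean, standardized to exactly 0, and
contributes exactly nothing — algebraically identical to multiplying its
coefficient by zero. An optional common-code restriction treats predictors
outside a supplied shared vocabulary as absent. Models serialize to JSON
(predictors, coefficients, means, SDs, hyperparameters, provenance) with a
bit-exact round trip.

For cross-model comparison of phecode importance, each model's phecode
coefficients are display-standardized to mean 0 / SD 1 and ranked in
descending coefficient order (rank 1 = largest); ties keep stable input
order and are flagged.

## Evaluation

Before any association test, the score is residualized: ordinary least
squares of the score on age and sex (plus the first ten genetic PCs when a
genetic score is being compared), residuals rescaled to mean 0 / SD 1. A
binomial-GLM variant of the residualization exists behind a flag for
sensitivity checks; the Gaussian linear model is the default and the
documented behavior.

* **HR per SD** — Cox proportional-hazards fit (lifelines, Efron tie
  handling, Newton precision 1e-10) with the residualized score as sole
  covariate; Wald SE, 95% CI, two-sided p.
* **Percentile contrast** — top decile (score above the empirical 90th
  percentile) vs the mid-risk band (40–60th percentile), Cox fit on the
  two groups; boundary values fall in the lower band, deterministically.
* **c-index** — Harrell's c over usable pairs (event i with t_i < t_j, or
  t_i = t_j with j censored; prediction ties count ½), with a
  Noether-type SE from the per-subject influence of the concordant/usable
  pair ratio. Under binary outcomes with one administrative follow-up time
  the statistic equals the ROC AUC and the SE reduces to the DeLong form
  (both asserted in tests). Nested-model gains are tested with a
  one-tailed z test of the c-index difference; effect differences on a
  common scale use z = (a−b)/√(se_a²+se_b²) with Bonferroni correction
  (m = 13 by default), treating the two estimates as independent even on a
  shared test set — conservative or anti-conservative depending on the
  correlation sign, and documented as such.
* **AUPRC** (step interpolation, prevalence as the null reference),
  **Nagelkerke pseudo-R²** (Cox–Snell over its attainable maximum, floored
  at 0), and **Pearson / partial correlations** with Fisher-z intervals
  complete the reporting surface.

## Meta-analysis

Per-cohort estimates pool under a random-effects model with
inverse-variance weights 1/(se² + τ²). τ² is estimated by REML (bounded
scalar optimization of the restricted likelihood; default) or by the
closed-form DerSimonian–Laird estimator, which doubles as the test oracle.
Log-HRs pool on the log scale; c-indices pool on the raw scale by default
(a logit-scale option exists). With τ² = 0 the estimator reduces to the
fixed-effect inverse-variance mean; with k = 1 it returns the single
estimate.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not any real register:

* persons with uniform integer ages 32–70 at baseline, Bernoulli(0.5)
  sex, standard-normal PGS and ten standard-normal PCs, all independent of
  the diagnosis channel (so the generative PheRS–PGS correlation is 0);
* parent-phecode carriage from a logistic factor model: logit prevalence =
  phecode base level (logit-uniform over 2–25%) + cohort-specific shift
  (SD 0.5, emulating coding-practice differences) + loadings (SD 0.8, 3
  latent comorbidity factors) + small age and sex terms;
* carried phecodes emitted as 1–5 dated ICD-10-style records in the
  observation window through per-cohort dialect tables (parent-level
  spellings including a variant that requires truncation, child-level
  spellings that exercise the three-digit rollup, or cohort-unique codes);
  distractor records are placed only in the washout and prediction windows
  so any feature leakage is detectable;
* proportional-hazards onset: liability = γ·carriage + age + sex + PGS
  terms, centered; exponential onset times with hazard
  baseline·exp(liability) (constant baseline hazard — the simplest
  PH-consistent choice); administrative censoring at the prediction
  horizon, 10% random early censoring, a 3% prevalent-case rate to
  exercise eligibility, and case records up to one year past the horizon
  to exercise the late-diagnosis filter.

Named scenarios fix the study conditions: **small** (3 cohorts × 5,000
persons, 60 phecodes, 2 diseases with 5 causal phecodes each at log-HR
0.5), **recovery** (1 × 20,000, 50 phecodes, 5 causal at log-HR 0.8),
**transfer** (2 × 5,000, 10 causal at 0.5), **orthogonality** (1 × 50,000,
5 causal at 0.8 plus a genetic effect of 0.35 per SD) and **null** (all
effects zero). `make_cohort_pair` suppresses a seeded 30% of the phecode
universe — half in the source, half in the target — so the shared
vocabulary is exactly 70% and each cohort records codes the other lacks,
the mechanism that separates internally and externally trained scores.
A separate helper (`simulate_scored_survival`) draws a standard-normal
score with an exactly known per-SD hazard ratio for coverage and
calibration studies.

What passing tests on these data do **not** show: the generator has no
ICD ontology breadth, no visit-level utilization structure, no
non-proportional hazards, no secular coding trends, and its cohort
differences are limited to prevalence shifts, dialects and vocabulary
gaps — real cross-register transfer also faces effect heterogeneity the
generator deliberately omits.

## Numerical and problem-size choices

* Simulation-scale fits use a reduced hyperparameter grid
  (`small_grid()`: mixing ratios {0.05, 0.5, 0.95} × C {1e-3, 1e-2, 1e-1},
  3-fold CV) — the full 209-candidate protocol remains the default for
  real-scale analyses and is exercised directly by the grid tests and the
  command-line `train`.
* The acceptance script runs 3 recovery seeds and 50 calibration
  replicates per block; the test suite runs the 10-seed / 100-replicate
  versions of the same experiments.
* Percentile-boundary ties go to the lower band; coefficient-rank ties
  keep input order and are flagged; collinear residualization covariates
  are absorbed with a warning; degenerate scores (fully explained by
  covariates) raise rather than return noise.
* Dates are closed intervals; ages are whole years at baseline; survival
  durations are days/365.25.

## Known limitations

* The c-index influence SE is asymptotic; for very few events the CI can
  undercover.
* compare_effects assumes independent estimates (see above).
* The logistic residualization variant min-max squashes the score and is
  provided for sensitivity analysis only.
* Exclusion-range arithmetic compares phecodes as decimal numbers, which
  matches the v1.2 map's numbering but would mis-order hypothetical
  phecodes with more than two decimal digits per level.
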