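# Methods

`gprisk` models the risk that an individual general practice will fall into
GP workforce "undersupply": simultaneously carrying a demography-weighted
workload per GP FTE in the highest national third and a case-mix-adjusted
patient-reported access score in the lowest national third. This note
records the model, its assumptions, the synthetic-data design, the
numerical choices, and what the test suite does and does not demonstrate.

## The modelling pipeline

**Outcome.** Workload per GP FTE is the practice's registered list,
reweighted per gender × 5-year age-band stratum by relative consultation
workload and scaled by an IMD-quintile deprivation factor, divided by GP
FTE. Access is the practice-level random intercept of a mixed-effects
logistic regression of a dichotomised survey item on five respondent
case-mix covariates (age band, gender, ethnicity, long-term condition,
deprivation quintile), expressed as a log odds ratio against the average
practice. Undersupply is the joint tercile condition; tercile cutpoints are
computed once over the full post-exclusion national panel with the linear
quantile convention, ties assigned to the lower tercile, and stored for
classifying regional subsets.

**Exclusions**, in a fixed order: registered lists ≤ 1000 patients; GP FTE
below 0.5 (a staffing record that low is treated as a data error); then the
top and bottom 2.5% of the workload-per-FTE distribution
(`floor(0.025 × n)` practices per tail, ties broken by practice id). The
audit log counts each step. A sensitivity refit with a 1% trim is the same
pipeline with `trim_fraction=0.01` — no code path changes.

**Development model.** A maximum-likelihood logistic regression of
follow-up undersupply on baseline covariates: the three survey scores,
nurse/GP FTE ratio, workload per FTE (per 1000), total GP FTE, the
"other"-category share of GP FTE (mostly locums), rurality (urban
reference), IMD quintile indicators (quintile 1 reference), the projected
adjusted weighted list (per 1000), the expected proportion of GP FTE still
in patient care in five years, and that proportion's interaction with the
nurse/GP ratio. Every covariate is retained regardless of significance;
intervals are Wald. The interaction is retained a priori — the exploratory
screen of retention × {locum share, access, nurse ratio} is available as a
diagnostic that reports p-values only, with no automated selection.
Discrimination is the mean of 10 unstratified random-fold held-out AUROCs
(pooling held-out predictions is available as an option; stratified folds
likewise); fold fits use L-BFGS so separable folds still score. Calibration
compares mean predicted probability with observed undersupply fraction
across rank-based deciles, which keeps tied predictions in equal-count
groups. A simpler two-covariate comparison model (access score + workload
per FTE) is the same fitting operation with a reduced covariate list.

**Retention.** The demographic method FTE-weights a lookup of five-year
stay-in-patient-care probabilities by GP age band and gender. The survey
method substitutes each responder's stated career intention via a
configurable mapping — quit within 2 years → 0; quit within 5 (not 2)
years → 0.5 on a uniform-timing argument; reduce hours → retain 60% of the
post; no change → the demographic value — and falls back to the
demographic lookup per non-responding individual, preserving FTE weights.
Coverage (share of practice FTE with a response) is reported. How best to
collapse two intention horizons into one proportion is genuinely open; the
mapping is configuration, not a claim.

**Prediction and stress tests.** Stored coefficients (with transform
metadata sufficient to rebuild the linear predictor unambiguously) are
applied to current data, with each practice's strata scaled by its area's
projected growth ratios at constant within-area share. Relative risk
classes are within-scenario quartiles (top 25% high, bottom 25% low);
absolute classes reuse the baseline scenario's 25th/75th probability
cutoffs, stored as artifacts. Scenarios perturb the fitted model:
`delta_beta_leave` adds to the linear predictor per unit of the proportion
of GP FTE expected to *leave*, and `list_inflation` multiplies the
projected adjusted weighted list. The standard set is A (+2), B (+4),
C (×1.2), D (×1.4), E = A∘C, F = B∘D. The leaving-scale parameterisation
is deliberate: it is the only one under which the standard equivalences
hold — a delta of 2 multiplies a practice's odds by exp(2 × 0.10) ≈ 1.22
when 10% of its FTE is expected to leave, and a delta of 4 by ≈ 1.49. An
increment applied literally to the proportion-*remaining* coefficient
would contradict both numbers, so the package does not do that.

## The synthetic-data generator

No public accession exists for practice-level survey extracts, workforce
censuses or registered-population tables, so the generator emulates their
structure with known ground truth. All randomness descends from one root
seed through named substreams (CRC32 spawn keys off a `SeedSequence`), so
output is byte-identical under a fixed seed and one table's draws never
perturb another's.

Per practice: list size lognormal (median ≈ 7000, log-sd 0.55); strata from
an age-pyramid Dirichlet × multinomial so counts are integers summing to
the list; GP density lognormal around 0.6 FTE per 1000 patients; nurse/GP
ratio normal around 0.5; IMD scores lognormal (mean 21, sd 8) cut into
empirical quintiles; a third of practices rural; ~0.5% of staffing records
corrupted below 0.5 FTE to exercise the exclusion. Rosters draw GP ages
N(47, 9.5) on 25–70, roles over {partner, salaried, registrar, retainer,
other}, and individual FTEs summing to the practice total. The patient
survey draws ~125 respondents per practice by default (Poisson) from a
logistic model with practice random effects (sd 0.35, inter-item
correlation 0.6) and fixed case-mix effects; response labels dichotomise
back to the generating binary draw exactly. The career-intention census
has each GP respond independently (default 67%), with categories drawn
from the GP's true leave probability.

**Forward model.** Baseline covariates are pushed through the logistic
linear predictor with the generating coefficients to draw a latent
undersupply indicator `u ~ Bernoulli(expit(Xβ))`; the default β magnitudes
are realistic values for this outcome (worse access, higher workload,
more deprivation raise risk; larger GP teams lower it) with constant
−4.15, giving ≈ 12–15% prevalence. Follow-up access effects and workload
are then generated around `u` (access shifted −1.1, log-workload +0.9
for undersupplied practices), so the tercile-based pipeline outcome is a
noisy realisation of `u`. Crucially, follow-up depends on baseline *only
through* `u`: with zero generating coefficients, follow-up is independent
of baseline and the fitted model's CV AUROC is chance. The cost of this
design is that real-world temporal persistence of practice quality is not
emulated beyond the modelled pathway, and the tercile outcome attenuates
coefficient estimates relative to the generating values — parameter
recovery is therefore assessed against the latent outcome in `truth`,
which makes it a well-posed coverage check.

What passing tests show: the pipeline recovers known structure under its
own assumptions. What they do not show: performance on real data, where
case-mix coding details, weight tables and survival tables are empirical
quantities this package exposes only as explicit configuration (the
published values behind them are not reproduced here), and where temporal
confounding is richer than the generator's single latent pathway.

## Numerical and design choices

- The mixed-effects logistic case-mix fit uses the variational-Bayes
  binomial mixed GLM from statsmodels with L-BFGS-B optimisation (the
  dense-BFGS default scales quadratically in the number of practices);
  its stochastic initialisation is pinned so the fit is a pure function
  of the data. Practice scores are posterior means, centred unweighted so
  the average practice is exactly 0; practices with no respondents are
  scored missing, never zero.
- Weight tables and deprivation factors are explicit configuration: a
  U-shaped age curve with a 10% female uplift, normalised so the
  reference-population-weighted mean weight is 1; deprivation factors ramp
  linearly 1.00→1.20 across quintiles. The survival table declines
  smoothly with GP age (women slightly lower mid-career).
- Complete-case analysis throughout; incomplete practices are dropped and
  counted. No imputation, no penalisation, no development/validation
  split.
- CV fold assignment is simple random from the seed; a fold missing an
  outcome class triggers refolding (≤5 attempts). Small panels with few
  events can exhaust the retries — that is a sample-size signal, not a
  tolerance to widen.
- `calibration_by_decile` splits on ranks with a stable sort, so constant
  predictions yield ten equal groups rather than one degenerate decile.

## Problem sizes

Test and reproduction runs use scaled-down panels chosen as the package's
own defaults: structural tests at 150–400 practices, truth-level model
checks at 2000–5000 practices (where the mixed-model step is bypassed via
the generator's zero-respondent mode), and the end-to-end reproduction
script at 1500 practices × 60 respondents. The respondent scale-down
(versus ~125 in a full national survey wave) adds sampling noise to the
practice scores and is the main reason end-to-end discrimination sits
below what truth-level covariates achieve.

## Known limitations

- The generator's case-mix covariates are independent of the practice
  random effects, so adjusted and unadjusted rankings nearly coincide on
  synthetic data; the adjustment machinery is exercised, but its
  real-data consequences are not.
- The survey-based and demographic retention estimates share the same
  underlying truth probabilities, which makes their high rank agreement
  partly by construction.
- Recruitment difficulty has no direct measure; scenarios A/B/E/F encode
  it only through the retention-coefficient perturbation.
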