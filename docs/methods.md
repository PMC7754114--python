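# Methods

## Anchored indirect comparison

Two treatments A and B, each compared directly with a common anchor regimen
C in its own data source, are compared indirectly on the log hazard-ratio
scale:

    log HR_AB = log HR_AC − log HR_BC,     SE_AB² = SE_AC² + SE_BC².

Confidence intervals and p-values use the normal approximation with
z = 1.96 throughout, matching the arithmetic by which printed hazard ratios
and intervals can be checked by hand (`se_from_ci` backs an SE out of a
printed 95% CI as (ln U − ln L)/3.92). The correlation between two direct
estimates that share the same anchor arm is ignored (independent-SE sum);
this is the standard approximation for anchored comparisons and slightly
overstates the combined SE when both contrasts come from the same source.

The validity conditions are those of any anchored comparison: the two
populations must be comparable on relative-effect modifiers (addressed by
shared eligibility criteria and propensity weighting), while absolute
prognostic differences between sources cancel through the anchor. The
package deliberately exposes the combination as plain arithmetic on
`HREstimate` objects so that published results can be fed in directly: the
within-source direct hazard ratios of the motivating study come from
access-restricted patient-level data and cannot be recomputed here; they
enter only as printed inputs and as simulation truths.

## Synthetic cohorts

The generator produces a paired randomized trial (two arms, 1:1) and a
real-world cohort sharing one covariate vocabulary: age, sex, race, ISS
stage, cytogenetic risk, ECOG performance status, creatinine clearance, and
months from diagnosis to first-line therapy. Defaults mirror the reported
baseline table of the motivating population (e.g. age ≈ N(74.3, 5.3²)
truncated at 65, ISS I/II/III ≈ 27/44/29%, high cytogenetic risk ≈ 14.5%).

* **Outcomes.** Event times are Weibull proportional hazards,
  S(t|x) = exp(−(t/λ)^k e^{η}), sampled by closed-form inversion. The
  default is exponential (k = 1) with λ = 43 months, putting the anchor-arm
  median near 30 months. The linear predictor η adds the regimen's true log
  HR versus the anchor (defaults 0.54, 0.80, 1.14 — the published direct
  estimates used as plausible truths), optional prognostic main effects of
  centered covariates, and optional treatment × covariate effect
  modification.
* **Censoring.** Three independent competing processes: an administrative
  cap (48.5 months, the trial's maximum follow-up), exponential loss to
  follow-up per source, and exponential non-progression treatment
  discontinuation per source × regimen, with higher default rates in the
  real-world source (routine care does not treat to progression) and the
  highest for the real-world triplet. Real-world clinics carry a lognormal
  frailty on the discontinuation rate so that clinic-level follow-up
  restrictions have something to find. Both the on-treatment observation
  (follow-up ends at discontinuation) and the extended intent-to-treat
  observation are stored per record, which is what real re-analysis of
  trial data would have available.
* **Confounded assignment.** Real-world treatment follows a multinomial
  logistic model on centered covariates (default: fitter, younger patients
  are likelier to receive the triplet), with intercepts calibrated by fixed
  point so mean assignment probabilities match the target regimen counts;
  realized counts are therefore multinomial around the targets.
* **Missingness.** Per-covariate rates follow the reported pattern —
  real-world: race 8%, cytogenetic risk 30%, ECOG 40%, ISS stage 47%,
  creatinine clearance 20% (a mid-range stand-in for the 13–27% lab
  missingness); trial: cytogenetic risk 13%. The default mechanism is MAR
  conditional on age (always observed): missingness probability is logistic
  in the age z-score with unit slope, intercept solved by root finding to
  hit the target marginal rate. MCAR is available for calibration tests.
* The optional per-source event-detection probability (imperfect real-world
  progression ascertainment) defaults to off: no published value exists to
  default to, and anchored comparison is insensitive to proportional
  under-ascertainment.

What passing tests on these cohorts do **not** show: robustness to
informative (outcome-dependent) discontinuation, to non-proportional
hazards, to missing-not-at-random covariates, or to real EHR data-quality
artifacts (none of which the generator produces).

## Eligibility

Criteria are evaluated in a fixed order (age, transplant flag, ECOG, renal
function, response assessment, lab bounds, comorbidity flags, then regimen
share on the post-clinical-criteria real-world population); attrition is
attributed to the first failing criterion. A record missing the covariate a
criterion reads is not excluded: eligibility precedes imputation, and high
missingness among included patients is expected. Exact thresholds for
"adequate bone marrow reserve and liver function" are configuration
placeholders (`lab_bounds`), not asserted defaults.

## Multiple imputation and pooling

Chained equations with 10 cycles and m = 10 datasets by default. Continuous
covariates use type-0 predictive-mean matching with k = 5 donors (robust to
skewed labs); binary and multi-level categoricals are drawn from fitted
(multinomial) logistic probabilities. Every conditional model uses all other
baseline covariates plus the event indicator and log follow-up time as
predictors — the standard choice when the analysis model is a survival
model. Convergence of the chains is not formally tested; the cycle count is
exposed in the configuration. Implemented in-package because no installed
routine offers this exact contract (multinomial categorical draws plus
k-donor PMM).

Downstream analyses run once per imputed dataset — weights re-estimated per
dataset — and log hazard ratios are pooled at the end by Rubin's rules:
point = mean, total variance T = W + (1 + 1/m)B, df = (m−1)(1 + W/((1+1/m)B))²,
t-based intervals (normal when B = 0). By default the anchored combination
happens per imputation and the combined log HRs are pooled
(`pool_before_combine` flips the order; the two differ only in how
between-imputation covariance is allocated).

## Weighting

Weights target the trial population (the two randomized arms pooled, which
is how the baseline table is laid out): for each real-world treatment group
separately, a logistic trial-membership model on the pooled sample yields
p(trial|x), and group patients receive odds weights w = p/(1−p), normalized
to sum to the group's n. The effective sample size (Σw)²/Σw² ≤ n quantifies
the cost of weighting. No truncation by default; optional percentile capping
is exposed. The default membership covariates are the full baseline set;
the demographics-only subset (age, sex, race) reproduces the sensitivity
analysis that avoids covariates with heavy missingness.

Balance is read off standardized mean differences (target minus group;
weighted group moments use the Σw−1 denominator so the measure is exactly
antisymmetric under unit weights). |SMD| > 0.1 flags an imbalance and marks
the group for doubly robust estimation (weights plus outcome-model
adjustment).

## Survival models

Cox proportional-hazards fits go through lifelines with convergence
tightened to |Δ| < 1e−9 so that small-sample estimates agree with a
brute-force partial-likelihood grid search to well under 1e-3. Ties are
handled by Efron's method; simulated times are continuous, where Efron and
Breslow coincide, and the test oracle uses tie-free data. Weighted fits
always report the robust sandwich variance with weights treated as fixed
(the defensible default under estimated weights; it ignores the
weight-estimation step itself). The proportional-hazards diagnostic is the
Wald test of a treatment × log(time) interaction in an episode-split
time-varying model — report-only, no automatic action. Subgroup analyses
parameterize treatment, subgroup, and their interaction in one model;
stratum hazard ratios and the interaction Wald p come from the joint
covariance. The interaction p for an *indirect* subgroup contrast treats
the two sources' interaction estimates as independent.

## Numerical choices and degenerate inputs

* z = 1.96 for all 95% intervals (normal approximation), so printed results
  can be checked by hand; pooled intervals use t quantiles when
  between-imputation variance is positive.
* Monotone likelihoods (an arm without events, a constant covariate, or a
  diverging coefficient |β| > 15) raise a typed error instead of returning a
  spurious estimate; perfect separation in the membership model raises an
  error naming the offending covariate.
* Follow-up times are continuous and strictly positive (floored at 1e−6
  months); an optional uniform jitter (< 1e−9 by default off) is available
  for externally supplied tied data.
* Probabilities from the membership model are clipped to (1e−12, 1−1e−12)
  before forming odds.

## Problem sizes used in the checks

The replicate studies in the test suite use 200 simulated pairs at 500
patients per trial arm and 500 per real-world regimen for recovery/coverage,
and 100 runs at 700/500 for the balance property — sizes chosen to put
Monte-Carlo error well below the effect sizes being verified while keeping
the default test run quick.

## Known limitations

* The anchor-arm correlation between two same-source direct estimates is
  ignored in the combination (conservative for the variance of their
  difference in the contrasts reported here).
* No network meta-analysis beyond two sources, no Bayesian combination, no
  time-varying covariates or stratified baselines, no multilevel imputation
  by clinic, and no entropy-balancing/method-of-moments weight variants.
* Doubly robust estimation adjusts for baseline covariates only; it does not
  model covariate-dependent censoring directly.
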