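# Methods

This note documents the models implemented in `cmburden`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Exposure representation

The five maltreatment types are ordered PA, SA, EA, N, EDV and a pattern is
the 5-character 0/1 code in that bit order (`"10110"` = PA + EA + N).  The
32 patterns are enumerated by the integer value of the code, so the
unexposed pattern `"00000"` is always first and the ordering is stable
across runs and files.

Relative risks are estimated per exposure *level*, not per pattern.  Two
codings map patterns to levels:

* `count_of_types` — levels `0`–`5`, the number of types experienced;
* `six_common_patterns` — the six most frequently observed multi-type
  patterns (EDV+EA+PA+SA, EDV+EA+PA, EDV+EA, all five, EDV+PA, EDV+SA) each
  get their own level; the remaining 26 patterns are too rare to estimate
  pattern-specific RRs and fall back to their count-of-types level.  The
  fallback is this package's choice; it rests on the empirical observation
  that RR magnitude is driven mainly by the number of types experienced
  rather than the specific combination.

Both codings partition the 32 patterns, so expanding level RRs to patterns
is total and unambiguous (property-tested).

## Synthetic survey generator

Five correlated binary exposures are drawn from a quadratic exponential
(log-linear) joint model: cell log-weight = Σ αᵢxᵢ + Σ λᵢⱼxᵢxⱼ over the 32
cells, sampled by exact enumeration (no MCMC — 32 cells are trivially
normalisable).  Defaults are calibrated at run time, once, deterministically:

* main effects αᵢ are fitted (damped iterative proportional fitting on the
  one-way margins) so per-type marginal prevalences equal the national
  estimates for the surveyed population: PA 32.0%, SA 28.5%, EA 30.9%,
  N 8.9%, EDV 39.6%;
* a common two-way coefficient λ is bisected per gender so that
  any-maltreatment prevalence equals 67.0% (women) and 59.3% (men).
  P(any) is monotone decreasing in λ at fixed margins (clustering
  concentrates exposure in fewer people), so bisection is valid.  Multi-type
  prevalence is not targeted; it emerges at ≈ 40%, close to the ≈ 39%
  reported for this population — a useful consistency check.

An age profile g(a) = 0.9·ln a − 0.00025·a² (mean-centred over the survey
ages 16–85) shifts every type's main effect, so exposure prevalence peaks in
the 40–44-year band as observed.  Binary confounders (childhood financial
stress, geographical remoteness, other adverse childhood experiences,
bullying victimisation) shift the count-of-types term of the exposure model
and multiply outcome risks, creating genuine positive confounding with
configurable strength.  Because both the age and confounder shifts act on
the count term, a respondent's 32-cell distribution is
softmax(base_gender + shift·n_types), which keeps sampling fully vectorised.

Outcomes are Bernoulli with risk p₀ × RR(level) × confounder multipliers,
capped at 1 − 10⁻⁶; capping indicates misconfiguration and emits a warning
with the event count.  Default baseline risks and dose–response ladders are
chosen once as plausible for lifetime/current mental-health outcomes in a
general adult population (e.g. PTSD p₀ = 0.02 with ladder 1…14; suicide
attempt p₀ = 0.02 with gender-specific level-5 RRs 11.2 / 10.3, matching
the published simply-adjusted estimates for that level).

Ground truth is exported exactly: stratum pattern probabilities marginalise
the generating model over integer ages within each band and over the
confounder distribution, and true PAFs apply the PAF formula to that truth.

**What the generator does not emulate:** the real sampling frame and
nonresponse, post-stratification weighting (weights default to 1; a variable
lognormal mode exists to exercise weighted estimators), the national age
pyramid (ages are uniform), diagnostic-instrument measurement error, item
wording, and comorbidity between outcomes.  Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed data-generating
structure, not robustness to survey-design artefacts.

## Prevalence smoothing

The production estimator is a Poisson log-linear regression on the
32 × strata table of weighted cell counts with a free intercept per stratum
(equivalent to stratum-wise multinomial logit; fitted stratum sums equal
observed totals at the MLE, and each stratum's fitted cells are renormalised
to sum to one, asserted at 10⁻⁹).  Covariates: per-type main effects, each
interacted with gender and with a standardised FP2 age basis of the
age-group midpoint (82.5 for 80+); all ten two-way type×type interactions,
optionally gender-specific (default on).  The FP powers default to (0, 2) —
ln age and age²; an exhaustive deviance search over the 36 standard FP2
pairs is available but off by default since the power pair is known.
Higher-order type interactions are deliberately excluded.

Survey weights are rescaled within stratum to sum to the stratum respondent
count, so the weight scale cannot distort totals; effective sample size per
stratum is the Kish ratio (Σw)²/Σw², which feeds the Dirichlet concentration
in the uncertainty stage.  Zero cells receive no added constant — the
unsaturated structure yields positive fitted values.  A `saturated` option
(free parameter per pattern) exists for validation: on a single stratum it
reproduces direct weighted proportions to 10⁻⁶.

Age is entered as the group midpoint, not exact age; with 5-year bands the
within-band mixture effect is negligible relative to sampling noise.  The
smoother is validated against the generator: on within-family data at
n = 200,000 the fitted cells are within 0.01 of truth, and at realistic
per-stratum sizes (n ≈ 250) its mean squared error is below that of direct
estimation.  With confounder-driven exposure heterogeneity the generator
leaves the two-way family (the mixture induces higher-order dependence);
the resulting smoothing bias is small (≈ 0.01 max cell error) but visible at
very large n — an intended feature of the test conditions, since real
surveys are never exactly in the model family.

## Relative risks

Log-link binomial GLM with the exposure level as categorical dummies
(reference: no maltreatment, RR ≡ 1), standardised ln-age and age² terms,
and the adjustment covariates ("simply": financial stress + remoteness;
"fully": + other ACEs + bullying; age is in both).  Fitting starts from the
empirical log-prevalence intercept.  If Fisher scoring fails, produces
boundary fitted probabilities, or yields non-finite standard errors, the
model is refit as a Poisson regression with HC1 sandwich variance — the
standard log-binomial rescue, which preserves the RR interpretation — and
flagged in the `fallback` column.  When both converge the two agree on
log-RR to within 0.05 on simulated data (tested).  CIs are Wald on the log
scale, matching the lognormal resampling model used downstream.  Levels with
no cases or no non-cases raise a quasi-separation error naming the level
rather than returning an unstable estimate.

A dose–response diagnostic (`rr_trend_check`) reports whether RRs are
non-decreasing in the number of types; violations are flagged, never
rejected — sampling noise can and does produce small dips.

## PAF

For a categorical exposure the attributable fraction against the
zero-exposure counterfactual is PAF = Σpᵢ(RRᵢ−1) / (1 + Σpᵢ(RRᵢ−1)).  This
is the unique formula consistent with a degenerate counterfactual
distribution and categorical RRs, and it is property-tested against an
enumerated-population oracle (mean risk now vs mean risk with everyone
unexposed) to 10⁻³ over random inputs.  The same RRs apply to every age
group, so PAF age patterns mirror prevalence age patterns.  One PAF per
outcome is applied identically to deaths, YLL and YLD.  All-ages PAFs are
burden-weighted averages of age-specific PAFs (weights: the cause's DALYs
by age), not prevalence-weighted ones.

## Burden attribution

Attributable measure = PAF × measure; attributable DALY = attributable YLL +
attributable YLD (exact by construction).  Anxiety burden is disaggregated
by a PTSD share s (default 0.28, a scalar per run, configurable per gender
or per stratum): attribution = PAF_PTSD·s·B + PAF_GAD·(1−s)·B.  The share is
an external input in reality (a national mental-health survey split); its
granularity by age/gender is a user decision.  The suicide-attempt PAF
scales the entire self-harm envelope — fatal and non-fatal — which assumes
the RR for attempts transfers to suicide mortality.  Smoking enters only
through burden already attributable to smoking; passing a total-burden
table unflagged is a hard error because it would double count.  Burden rows
for ages under 15 receive PAF 0 (the survey starts at 16; its youngest
band is aligned to the 15–19 burden band).

## Uncertainty propagation

Per iteration: each stratum's pattern distribution is drawn from
Dirichlet(α = proportion × effective n) — empty cells get α = 0.5, the
minimal pseudo-count that keeps the Dirichlet proper — and each RR from
exp(N(ln RR, σ)) with σ = (ln UCL − ln LCL)/(2·z₀.₉₇₅).  One RR draw per
outcome × gender × level is shared across all age groups per iteration;
because the point RRs are age-constant, independent per-age draws would
understate between-age correlation and spuriously narrow aggregate UIs.
Prevalence draws are independent across strata (the Dirichlet construction
is stratum-wise by definition); correlation across ages induced by the
smoothing model's coefficient uncertainty is not propagated.  Burden
envelopes are fixed — only exposure and RR sampling uncertainty propagate.

UIs are 2.5th/97.5th percentiles (linear interpolation between closest
ranks, checked against an independent sort-based oracle) of 2,000 iterations
by default.  Percentile intervals need not bracket the point estimate by
construction; non-finite iterations are dropped with a warning and more
than 1% failures is a hard error.  Everything is a pure function of the
seed; identical seeds give bitwise-identical outputs.

## Problem sizes used in validation

The test suite exercises: estimator recovery at n = 100,000 (RRs within
3 SE, PAFs within 3 Monte Carlo SE of truth); smoother consistency at
n = 200,000 (cells within 0.01 of truth); CI calibration over 200 replicates
at n = 20,000 (pooled coverage of true RRs {1, 2, 5} within [92%, 98%]); UI
coverage over 200 single-stratum replicates of n = 2,000 with 500 iterations
each (coverage within [90%, 99%]); and the PAF oracle over 1,000 random
draws.  These sizes give Monte Carlo error comfortably below the tested
tolerances while keeping the suite fast.

## Known limitations

* The six-common-pattern coding's fallback for rare patterns (count-of-types
  RR) is a modelling choice, not an estimated quantity.
* Mediation is not modelled; adjusted RRs are total-effect estimates under
  the no-mediation-adjustment convention.
* Comorbidity between outcomes is ignored, so summed attributable burden
  across mental-health causes can overstate the joint burden.
* Design-based variance for complex survey weights is not implemented; the
  Kish effective n is a first-order proxy.
* The burden generator produces envelope-shaped tables for pipeline
  exercise; its magnitudes are nominal, so attributable-DALY shares from
  synthetic runs characterise the pipeline, not any real population.
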