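# cmburden

Comparative risk assessment of the disease burden attributable to child
maltreatment, treated as a single polytomous exposure.

Five maltreatment types — physical abuse (PA), sexual abuse (SA), emotional
abuse (EA), neglect (N) and exposure to domestic violence (EDV) — co-occur
strongly, and risk of adverse mental-health outcomes rises steeply with the
number of types experienced.  Adding up burden estimated separately per type
overstates the total (double counting of multi-type victims), while a single
any/none dichotomy understates it (it ignores the dose–response).  `cmburden`
implements the alternative: the joint exposure is the set of 2⁵ = 32 mutually
exclusive maltreatment *patterns*, each mapped to an exposure level (number
of types 0–5, or the six most common multi-type patterns), and burden is
attributed against a zero-exposure counterfactual.

The package is aimed at epidemiologists doing burden-of-disease or
risk-factor quantification work who need the full chain as tested,
reusable code rather than spreadsheets: survey microdata in, attributable
burden with uncertainty intervals out.

## The method

1. **Pattern prevalence.** Weighted prevalence of the 32 patterns per gender
   × 5-year age group is estimated with a smoothed log-linear model (Poisson
   regression on the 32 × strata table of weighted cell counts): type main
   effects × gender × a second-order fractional-polynomial age basis
   (default powers (0, 2): ln age and age²), plus all ten two-way type×type
   interactions.  Direct cell proportions are too noisy at this
   disaggregation; the model borrows strength across ages.
2. **Relative risks.** Log-binomial regression (binomial GLM, log link) of
   each binary outcome — MDD, GAD, PTSD, alcohol use disorder, current
   smoking, suicide attempt — on exposure level, separately by gender,
   adjusted for age plus childhood financial stress and geographical
   remoteness ("simply") or additionally other adverse childhood experiences
   and bullying victimisation ("fully").  A Poisson/robust-sandwich refit is
   the convergence fallback.  The same RRs apply across all age groups.
3. **PAFs.** For pattern prevalences p_i and relative risks RR_i (reference
   "no maltreatment", RR = 1), the population attributable fraction per
   outcome × gender × age group is

       PAF = Σᵢ pᵢ(RRᵢ − 1) / (1 + Σᵢ pᵢ(RRᵢ − 1)),

   the proportional risk reduction under the theoretical-minimum-risk
   counterfactual of zero exposure.
4. **Attribution.** PAF × burden (deaths, YLL, YLD; DALY = YLL + YLD) per
   cause, with three wrinkles: anxiety burden is split into PTSD and other
   anxiety (GAD proxy) by an external PTSD share; the suicide-attempt PAF is
   applied to the whole intentional self-harm envelope; the smoking PAF is
   applied only to burden *already attributable to smoking* (two-step chain,
   guarded against double counting).
5. **Uncertainty.** Monte Carlo (default 2,000 iterations): Dirichlet draws
   of each stratum's pattern distribution (α = proportion × effective n) and
   lognormal RR draws reconstructed from the 95% CIs, with the full chain
   recomputed per iteration; 95% uncertainty intervals are the 2.5th/97.5th
   percentiles.

Real microdata of this kind is embargoed, so the package ships a first-class
synthetic generator (`cmburden.synthetic`) that reproduces the study
conditions — five correlated exposures with any-maltreatment prevalence
67.0% (women) / 59.3% (men), multi-type ≈ 39–40%, prevalence peaking at ages
40–44, confounded dose–response outcomes — and exports the exact generating
truth for recovery tests.  See `docs/methods.md` for model details and
limitations.

## Worked example

```python
from cmburden.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, out_dir="out", iterations=2000))

paf = res["paf"]
print(paf[paf.age_group == "40–44"]
      .pivot(index="outcome", columns="gender", values="paf").round(3))
print(res["uncertainty"].share_all_dalys.round(2).to_string(index=False))
```

prints (seed 1):

```
gender             men  women
outcome
aud              0.571  0.536
gad              0.734  0.613
mdd              0.609  0.557
ptsd             0.812  0.819
smoking          0.494  0.501
suicide_attempt  0.771  0.849

gender  pct  ui_lower  ui_upper
   men 3.12      3.01      3.23
 women 2.08      2.02      2.16
```

The first block is the attributable fraction per outcome in the 40–44-year
band — the age where exposure prevalence, and hence the PAF, peaks (e.g.
81.9% of women's PTSD risk in that band is attributable to maltreatment
under the synthetic conditions).  The second block is the share of *all*
DALYs (here from the synthetic burden envelope) attributable to child
maltreatment per gender, with its 95% uncertainty interval.

The same stages are available from the shell:

```sh
cmburden simulate --seed 1 --n 8377 --out-dir out
cmburden prevalence --microdata out/microdata.csv --out out/prev.csv
cmburden rr --microdata out/microdata.csv --coding count --adjustment simply --out out/rr.csv
cmburden paf --prevalence out/prev.csv --rr out/rr.csv --out out/paf.csv
cmburden run-all --seed 1 --out-dir out
```

Supplying pre-computed prevalence and RR CSVs to `cmburden paf` (or
`PipelineConfig(prevalence_csv=..., rr_csv=...)`) skips the estimation
stages entirely and runs the attribution chain on external tables — e.g.
published supplementary tables placed under `data/published/` (see the
README there for the expected schemas).

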