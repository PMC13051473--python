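# Methods

## Estimand and model

The pipeline estimates, separately by sex, the incremental annualized total
healthcare cost (THC) of cognitive impairment and splits it into a direct
component and an indirect component attributable to explanatory variables,
by the regression **difference method**:

- *Total*: marginally standardized cost contrast from a gamma/log GLM of
  annualized THC on the impairment indicator plus age (linear), race
  (3 categories, reference non-Hispanic White), geographic region
  (categorical, reference first alphabetically), and comorbidity count
  (linear).
- *Direct*: the same contrast after additionally adjusting for the
  explanatory set — ADL impairment count (categorical 0–4, reference 0),
  frailty category (robust/pre-frail/frail, reference robust), CFI
  (linear), or all three.
- *Indirect* = total − direct, so additivity holds exactly by construction.
  The indirect share is reported as a percentage of the total and flagged
  undefined when the total is non-positive.

Marginal standardization is by recycled predictions: every participant's
cost is predicted with the exposure set to 1 and to 0, and the two sets of
predictions are averaged. This is the predictive-margins convention standard
in cost modelling (margins at covariate means would answer a different
question for a log-link model).

Education is never a model covariate — it enters the definition of
cognitive impairment (education-stratified test norms), and the config
validator rejects it.

This is a regression decomposition, not a causal-mediation analysis: no
exposure–mediator interactions, no natural direct/indirect effects. On data
where mediators and confounders interact or mediator–outcome confounding
exists, the components have only the descriptive "adjusted-away"
interpretation.

## Fitting

The gamma/log GLM is solved by IRLS. With a log link and gamma variance the
working weights are identically 1, so every iteration is an OLS solve of
the working response `z = eta + (y − mu)/mu` against a fixed design; the
normal-equations Cholesky factor is computed once per design and reused,
and bootstrap replicates warm-start from the full-data coefficients. This
makes a replicate refit ~100× cheaper than a cold fit, which is what keeps
the bootstrap and the coverage studies tractable on one CPU. Convergence is
declared at max |Δβ| < 1e-8 or relative deviance change < 1e-10 (max 100
iterations, step-halving on deviance increase); initialization is the OLS
fit to log(y) clipped below at log(0.1). Dispersion is Pearson χ²/(n−p); it
does not affect point estimates or marginal means. Rank-deficient designs
raise an error naming the aliased columns. The solver is cross-checked
against an independent statsmodels gamma GLM in the test suite.

Gamma support excludes zero costs. The default rule replaces y = 0 with $1
(alternatives: shift all outcomes by δ, exclude, or refuse), applied once
before resampling and logged with counts.

## Bootstrap

Percentile bootstrap (not BCa — the simplest method consistent with
"bootstrap" interval estimation), default 1,000 replicates, resampling
participants with replacement within sex strata. Replicate r draws from RNG
substream r of the configured seed (`numpy` `SeedSequence.spawn`), so
results are bit-reproducible and order-independent. Both models are refit
per replicate; the indirect interval is the 2.5th/97.5th percentile of
replicate-wise total − direct differences, preserving the within-replicate
correlation of the two fits. Replicates whose refit fails (e.g. a covariate
level absent from the resample) are dropped and counted, with a warning
above 5%. Phenotypes and cognitive-test norms are fixed before resampling:
the decomposition is of costs given phenotypes.

Sex pooling combines components as `w_f·x_f + w_m·x_m` (equal weights or
proportional to sample size). When both sides carry the same number of
bootstrap replicates the intervals are taken on pooled replicates;
otherwise interval endpoints are weighted and the result flagged
approximate.

## Phenotype rules and boundary conventions

- Cognitive impairment (cohort rule): diagnosis OR score ≤ stratum mean −
  1.5·SD. The boundary is **inclusive** ("at least 1.5 SD below");
  configurable. Norms default to the supplied cohort's participants aged
  65–69 per education stratum and can be overridden with fixed values.
- NHATS rule: (diagnosis AND AD8 > 2, i.e. ≥ 3) OR ≥ 2 of 3 impaired
  domains; domain flags are consumed as precomputed booleans.
- Frailty components use strict inequalities exactly as printed: grip
  < 32 kg (men) / < 20 kg (women); gait < 0.8 / < 0.6 m/s or walking aid;
  weight loss ≥ 5% or ≥ 10 lb or BMI < 18.5; plus reported poor energy and
  low activity. A gait of exactly 0.6 m/s in a woman is therefore *not*
  slow.
- Comorbidity counts intersect the participant's conditions with a
  sex-specific vocabulary (12 conditions for women, 11 for men); unknown
  labels warn rather than fail.
- Records missing any required phenotype or cost input are excluded before
  modelling (missing-data exclusions are counted before enrollment
  exclusions, so the two counts are order-dependent; the order is logged).
- Annualization divides cumulative cost by follow-up (months/12), with
  follow-up truncated at death; survivors must carry the full 36 months.
  Zero-exposure records (death at day 0) cannot be annualized and are
  excluded with a logged reason. Inflation standardization is a plain
  year → multiplier table (multiplier 1 at the reference year 2023);
  claims-line price standardization is out of scope.

## The synthetic cohort

The generator emulates the *descriptive structure* of a pooled
Medicare-linked multi-cohort study of community-dwelling adults 65+, not
its claims micro-data. Per sex, with all parameters in
`synthetic_cohort.py`:

- Exogenous covariates: age (normal, women 79.9 ± 6.5, men 78.4 ± 6.0,
  clipped at 65), race (women 76.7/19.7/3.6% White/Black/other; men
  80.9/13.8/5.3%), region (4 categories), education (15/45/40% across
  <9 / 9–12 / >12 years), and 12 (11) chronic-condition Bernoulli flags
  with mean count ≈ 1.4.
- Cognitive impairment: logistic in age, race and comorbidity count,
  intercepts solved so prevalence is 12.1% (women) and 10.9% (men). This
  makes race and comorbidity *confounders* (they raise impairment risk),
  which reproduces the observed descriptive contrasts (impaired group
  older, less often White, more comorbid) while keeping the base-model
  adjustment set causally meaningful; drawing them conditional on
  impairment instead would have made them mediators and contaminated the
  decomposition oracle.
- Mediators conditional on impairment: ADL count by cumulative logit
  (cut points fixed to the unimpaired margins; a single proportional-odds
  impairment effect of 1.5 — it cannot match both the "none" and the "3–4"
  impaired margins at once, so only directional contrasts are asserted);
  five frailty-component Bernoullis with a common impairment log-odds shift
  solved exactly (Poisson-binomial) so that P(frail) hits 30.7→60.1%
  (women) and 16.4→40.4% (men); CFI ~ Beta with impairment-shifted mean
  (0.16→0.21 women, 0.15→0.18 men, concentration 50).
- Cost: cumulative cost ~ Gamma(shape, mean = follow-up years ×
  exp(linear predictor)), so the annualized outcome is gamma with a mean
  independent of follow-up. Mediator and exposure coefficients were solved
  (once, in closed form given simulated covariates) so the unimpaired group
  means, the impaired/unimpaired mean ratios, and the all-three indirect
  share match the emulated study's descriptive targets (women ≈ $13.7k,
  ratio 1.74, share 63.4%; men ≈ $14.1k, ratio 2.01, share 58.2%). Gamma
  shapes (0.354 women, 0.304 men) match the unimpaired group cost SDs —
  costs are strongly right-skewed, SD ≈ 1.8× the mean.
- Death: probability 0.11 (unimpaired) vs 0.32 (impaired) over 36 months;
  decedent follow-up uniform on (0, 36] months.
- Raw measures (grip, gait, BMI, weight loss, cognitive scores, ADL flags)
  are emitted consistent with the drawn statuses, so generated tables
  round-trip *exactly* through the phenotyping rules — asserted in tests.

What the generator does **not** emulate: claims-level utilization events,
cost components, survey weights, correlated mediators beyond their common
dependence on impairment, time-varying status, and measurement error in the
raw instruments. Passing tests therefore demonstrate the correctness and
calibration of the estimation machinery under a faithful-margins synthetic
model — not the substantive validity of any particular real-data estimate.

Calibration matches the *descriptive* margins (group means, ratios, share
of the all-three indirect component), not the adjusted totals themselves:
baseline confounding strength is matched only directionally, so the
covariate-adjusted incremental cost — especially in men, where the emulated
study's adjustment removed about half of the crude group difference — comes
out larger here than the study's printed estimate. Comparisons in the test
suite are therefore always against the generator's own oracle, never
against the emulated study's adjusted numbers.

Presets: `paper-like` (above), `null` (mediator laws identical in both
groups — all indirect paths off), `pure-mediation` (direct cost coefficient
zero).

## The generative-truth oracle

`oracle()` evaluates the true decomposition by Monte-Carlo g-computation on
the generative law: the total contrast sets the exposure to 1 vs 0 with
mediators drawn from their exposure-conditional laws; the direct contrast
holds the explanatory mediators at their unexposed law (mediators outside
the set still respond). Cost noise integrates out, so contrasts are
evaluated on exp(eta); Monte-Carlo SEs are reported per component.

The difference method and this mediational contrast coincide only
approximately under a log link: the adjusted model's contrast averages the
mediator terms over the *observed* mixture rather than the unexposed law.
On the paper-like preset the gap is ≈ 10% of the indirect component for
single-mediator sets (measured at n = 40,000). It vanishes on the
pure-mediation preset with the all-three adjustment (both estimands reduce
to the same collapsible total), which is why that configuration is used
where a test needs estimand-exact truth.

## Validation suite and known limitations

- Coefficient recovery within 3 SE at n = 5,000; vectorized recycled
  predictions vs a literal per-row loop at 1e-10 relative; decomposition
  vs oracle within 3 combined Monte-Carlo SEs at n = 20,000 (plus the
  null-mediation and pure-mediation limits); exact additivity and the
  exhaustive 32-case frailty truth table; bit-reproducibility under fixed
  seeds. Simulation sizes (n = 20,000 oracle comparisons; 200 repetitions
  at n = 2,000 and B = 300 for interval calibration) were chosen to resolve
  the assertions at useful precision while keeping the default suite a
  few minutes on one CPU.
- **Interval calibration**: across 200 simulated cohorts (n = 2,000,
  B = 300, pure-mediation preset, estimand-exact truth) the percentile
  bootstrap covers the true indirect effect 92.0% of the time against the
  95% nominal level — and identically 92.0% at B = 1,000, so the shortfall
  is not the replicate count. With gamma shape ≈ 0.35 and ~12% exposure
  prevalence, the exposed-group mean rests on ~240 heavily skewed
  observations, a regime where percentile intervals are known to
  undercover by a few percent. The point estimator is unbiased (mean
  4,037 vs truth 4,040 over 400 simulations, SE 57). Users wanting tighter
  calibration at small n should increase n or prefer a variance-stabilized
  interval; at the emulated study's n ≈ 4,000–8,000 per sex the effect is
  correspondingly smaller.
- The CMS-HCC score and CFI are consumed (or simulated) as numbers;
  recomputing them from claims codes is out of scope, as are survey
  weights, pharmacy/long-term-SNF costs, and cause-of-death analyses.
- Annualization after death truncation can overstate person-year costs of
  decedents, who are over-represented in the impaired group; the pipeline
  reproduces this design choice rather than correcting it.
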