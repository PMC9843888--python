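# Methods

## Model

One simulated target population represents the pool from which both a
single-arm trial and its external control arm are drawn. Per individual:

```
U  ~ Normal(0.5, 1)                           unmeasured confounder
C  ~ Normal(50, 50)                           measured continuous covariate
L  | U        ~ Bernoulli(expit(a0 + aU·U))   measured binary covariate
A  | L, C, U  ~ Bernoulli(expit(b0 + bL·L + bC·(C−50) + bU·U))
Ya | A, C, U  = g0 + gA·A + gC·C + gU·U + Normal(0, σ)
Yb | A, C, U  ~ Bernoulli(expit(h0 + hA·A + hC·C + hU·U))
T  | A, C, U  ~ Exponential(rate λ0·exp(kA·A + kC·(C−50) + kU·U))
Yc = min(T, τ),  D = 1{T ≤ τ}                 administrative censoring only
```

`bU = 0` in scenarios 1–2 (U reaches treatment only through L, so
conditioning on L blocks the path) and `bU > 0` in scenario 3 (an open,
unblockable path). Scenario 1 weakens U's links to L and to every outcome
relative to scenarios 2–3; scenarios 2 and 3 share identical L- and
outcome-models and differ only in the treatment model. C is centered at
its mean of 50 in the treatment and hazard linear predictors so that
intercepts are interpretable; the other two outcome models take C raw and
absorb the shift into their intercepts. All link functions are
linear-in-covariates; the event time is exponential proportional hazards.
These are the simplest forms consistent with the published description of
the process; the original generating constants were never published.

## Estimand and truth

The estimand is the marginal ATE: mean difference for `Ya`, log odds ratio
of the averaged counterfactual risks for `Yb`, and a marginal log hazard
ratio for `Yc`. The canonical truth evaluates the generating models at
A=1 and A=0 for every individual of a large draw (default 200,000) with
shared noise, then contrasts marginally; the survival truth fits a
univariate Cox model to the stacked counterfactual event data — the same
device the g-computation estimator uses, so truth and estimator target one
estimand (a conditional Cox coefficient would not be comparable, because
the hazard ratio is non-collapsible). An independent regression route
(outcome models fit on a realized population *including U*, then
standardized) cross-checks the truth in the test suite; the two routes
agree within Monte-Carlo tolerance on all calibrated sets.

## Calibration

The free coefficients are recovered from published population summaries by
staged one-dimensional solves on a 200,000-individual evaluation
population built from common random numbers, making each target statistic
a deterministic, monotone function of the coefficient being solved
(`brentq` for cheap statistics; secant iteration where each evaluation
needs a Cox fit). Stages: (1) treatment/covariate block against the
between-arm gaps in U, C, L, the marginal L prevalence and a 50/50 arm
split — scenario 3 re-solves `(b0, bU)` against r(U,A)=0.24 and the
L-adjusted U odds ratio 1.34; (2) continuous outcome against the true
effect (3.99 / 4.04, which the linear model meets exactly with `gA`), the
population-level unadjusted bias (−0.800 / −1.086) and r(Ya,U) (−0.15 /
−0.44); (3) binary outcome against the marginal log OR truth (1.21 /
1.17), the unadjusted bias and r(Yb,U); (4) survival against the marginal
log HR truth (−0.83), the unadjusted bias and r(Yc,U).

Closure constraints fix the remaining scale parameters, stated here as the
package's own choices:

* **σ** (continuous residual SD) is set so the adjusted linear estimator's
  sampling SD at n=200 equals the published RMSE (0.351 scenario 1, 0.408
  scenario 2), via the exact OLS variance formula on the evaluation
  population. Both scenarios independently land at σ ≈ 2.0 — evidence of a
  single underlying σ in the source process.
* **τ** (censoring horizon) is set so the control-arm event proportion is
  0.87. Three published facts jointly pin a high event rate: the
  unadjusted survival CI width (0.662 at n=200) implies ≈145 events per
  sample; the survival TMLE evaluates risk at the *median survival of all
  individuals*, which only exists if more than half the population events;
  and the reported TMLE attenuation (−0.68 vs −0.83) emerges numerically
  from the RR at that median (≈0.57) pushed through the d=0.4 conversion —
  at a 0.4 event rate the median is never reached and the attenuation
  disappears. The constant d=0.4 itself is kept exactly as printed in the
  RR→HR formula.
* **P(A=1)** is 0.5 (never published; consistent with the published CI
  widths), the binary control-arm risk is 0.30 (free intercept; reproduces
  the published binary CI widths ≈1.2), the continuous control-arm mean is
  20 (pure location), and λ0 = 0.1 (the time unit is arbitrary).

The shipped sets (`ecasim/data/scenario{1,2,3}.yaml`) reproduce, on
independent draws, the published arm means/SDs of U and C, the U–outcome
and covariate–treatment correlations, the adjusted odds ratios (1.00,
1.00, 1.34) and the standardized mean differences — using this summary
table's SMD convention `|Δmean|/sqrt(var_t + var_c)` (a factor √2 smaller
than Cohen's d; the published C and U rows only reproduce under this
denominator). The published L-row SMDs are not reproducible from their own
arm percentages under any standard convention and were not targeted; the
percentages themselves were.

## Estimators

All estimators see only (C, L, A, outcome). Non-converged replicates
(separation, zero-event cells, weighted effective sample size < 10 in an
arm, |log OR| > 15) are flagged, dropped from aggregates and counted.

* **raw** — outcome on A alone (OLS / logistic / Cox), Wald 95% CI.
* **g-computation** — outcome model on (A, C, L); contrast of averaged
  counterfactual predictions. Survival: simulate each individual's event
  time under both arms from the fitted Cox model (shared unit-exponential
  draws inverted through the predicted cumulative hazard, 8 draws per
  individual pooled to suppress simulation noise), censor at the observed
  horizon, fit a univariate Cox model on the stacked data. CI: 200
  nonparametric bootstrap resamples supplying a variance for a Wald
  interval (g-computation has no closed-form variance). The bootstrap
  *percentile* interval is available as an option; at 200 resamples its
  tail quantiles are noisy and it measured ~1% lower coverage, so the
  normal form is the default.
* **IPTW / SMR / OW** — logistic propensity on (C, L); weights exactly
  `1/p, 1, 1−p` (treated) and `1/(1−p), p/(1−p), p` (control); weighted
  outcome-on-A fits with sandwich variances (HC1; robust score variance
  for Cox). No trimming or truncation anywhere — overlap weights' inherent
  robustness to extreme scores is part of what the benchmark measures.
* **TMLE** — parametric main-effects working models (no machine-learning
  ensemble): logistic propensity, logistic initial outcome fit (continuous
  outcomes linearly scaled to [0,1] with a 10% range cushion so logits
  stay finite), one-parameter ML fluctuation with the clever covariate,
  influence-curve variance delta-method-propagated to the reporting scale.
  Survival: event status binarized at the median follow-up of all
  individuals, binary TMLE for the two counterfactual risks, RR→HR with
  d=0.4. This conversion — not the targeting — is what attenuates the
  survival TMLE toward the null, reproducing the published deviation.

## Study engine and problem sizes

One population per scenario per study; replicate samples are uniform draws
without replacement (200 ≪ 20,000 makes the with/without distinction
negligible); replicate seeds derive counter-style from
`(master_seed, scenario, replicate)`, so any subset reproduces exactly and
execution order cannot matter. Full-study defaults follow the source
design (20,000 population, 3,000 replicates of n = 200, with n = 100 as a
sensitivity setting). The shipped verification uses scaled-down sizes
chosen for single-CPU runs: `scripts/acceptance.py` uses 500 replicates
(Monte-Carlo SE of a coverage estimate ≈ 0.01) and the acceptance tests
use 1,500. Tolerances in those tests are 3 Monte-Carlo SEs, where the SE
includes both the replicate component and the component contributed by the
single finite study population (estimated from the population-level fit's
standard error) — the published values carry the same two noise sources.

## What the generator does and does not emulate

It emulates the confounding *structure* (one hidden and two observed
confounders, blockable vs unblockable paths), calibrated effect sizes and
realistic n=200 sampling noise. It does not emulate: non-linear or
interaction effects (all links are main-effects linear, so every
estimator's outcome model is correctly specified up to the hidden U —
real-data misspecification bias is out of frame); treatment-effect
heterogeneity (IPTW/SMR/OW target different populations yet coincide here
because the effect is homogeneous); random dropout (censoring is purely
administrative); time-varying confounding; measurement error. Passing
tests therefore certify the estimators' behaviour under hidden
confounding with well-specified working models, not their robustness to
model misspecification.

## Numerical choices and degenerate inputs

Propensity scores from a converged logistic fit lie strictly in (0,1);
score 0/1 or weights outside (0,∞) raise errors rather than being
truncated. TMLE predictions are clipped to [1e−8, 1−1e−8] on the working
scale. Cox fits use lifelines' default Efron tie handling (simulated
continuous times make ties measure-zero). Samples below 20 individuals
warn; a population whose realized arms are empty is rejected with a
diagnostic. Bootstrap resamples that lose an arm are skipped; a replicate
whose resamples are mostly degenerate is flagged non-converged. The SMD is
undefined (error) when both groups have zero spread.

## Known limitations

* The calibrated coefficients are one consistent solution, not a unique
  recovery; any set reproducing the published summaries is observationally
  equivalent for the benchmark's purposes.
* GC bootstrap CIs at 200 resamples measure coverage ≈ 0.94 where the
  source reports 0.95; the residual gap traces to unknown details of the
  original CI machinery.
* The weighted-Cox robust variance choice may differ from the original
  (naive vs robust was never stated); robust is used.
* SMR targets the treated population; it is scored against the overall ATE
  (as in the source design), which is only fair under the homogeneous
  effects simulated here.
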