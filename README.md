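# ecasim

Monte-Carlo benchmark of bias-adjustment estimators for externally
controlled trials with measured and unmeasured confounders.

## The problem

In rare diseases, single-arm trials are often compared against an
**external control arm (ECA)** built from real-world data. Without
randomization, measured *and unmeasured* baseline differences confound the
comparison, and the analyst must adjust for whatever was measured. `ecasim`
is for methodologists and trial statisticians who want to quantify how much
of that confounding the standard adjustment toolbox actually removes.

The package simulates a target population of 20,000 individuals with

* an unmeasured confounder `U ~ N(0.5, 1)`,
* measured covariates `C ~ N(50, 50)` and binary `L` with
  `logit P(L=1) = a0 + aU·U`,
* treatment `A` with `logit P(A=1) = b0 + bL·L + bC·(C−50) (+ bU·U)`,
* three outcomes driven by `(A, C, U)`: continuous
  `Ya = g0 + gA·A + gC·C + gU·U + ε`, binary
  `logit P(Yb=1) = h0 + hA·A + hC·C + hU·U`, and an exponential
  proportional-hazards event time with administrative censoring.

Three confounding scenarios are shipped as calibrated coefficient sets:
small and blocked paths (U reaches A only through L), medium and blocked
paths, and one large **unblocked** path (a direct U→A arrow). On each of
thousands of replicate samples (n = 200, with U hidden), six strategies
estimate the average treatment effect (ATE):

| method | idea |
| --- | --- |
| raw | unadjusted two-group contrast |
| GC | g-computation: outcome model on (A, C, L), contrast averaged counterfactual predictions |
| IPTW / SMR / OW | propensity `p = P(A=1 | C, L)`; weights `1/p, 1, 1−p` (treated) and `1/(1−p), p/(1−p), p` (control) |
| TMLE | targeted maximum likelihood: initial outcome fit updated along the clever covariate `H = A/p − (1−A)/(1−p)` by `logit(Ŷ*) = logit(Ŷ) + ε·H` |

Effects are reported as a mean difference (continuous), marginal log odds
ratio (binary) and marginal log hazard ratio (survival); survival TMLE
estimates the relative risk RR at the median follow-up and converts it via
`HR = log(1 − d·RR)/log(1 − d)` with reference event proportion `d = 0.4`.
Replicate estimates are scored against population-level true effects by
bias, RMSE, 95%-CI coverage and CI width.

## Worked example

```python
import ecasim

coeffs = ecasim.load_frozen(1)                  # calibrated scenario 1
pop = ecasim.generate_population(coeffs, size=20_000, seed=42)
truth = ecasim.true_effects_counterfactual(coeffs, size=200_000, seed=0)
print("true effects:", round(truth.ate_continuous, 2),
      round(truth.ate_binary, 2), round(truth.ate_survival, 2))

records = ecasim.run_replicates(
    pop, scenario_id=1, n_replicates=200, sample_size=200,
    methods=("raw", "GC", "OW"), outcomes=("continuous",),
    gc_bootstrap_reps=200, master_seed=7,
)
summary = ecasim.summarize(records, {(1, "continuous"): truth.ate_continuous})
print(summary[["method", "n_used", "bias", "rmse", "coverage", "width"]]
      .round(3).to_string(index=False))
```

prints

```
true effects: 3.99 1.21 -0.83
method  n_used   bias  rmse  coverage  width
    GC     200  0.023 0.360     0.940  1.413
    OW     200  0.019 0.358     0.960  1.458
   raw     200 -0.784 0.837     0.275  1.211
```

Reading: the population truth is a mean difference of 3.99. Ignoring the
confounders (raw) underestimates it by ~0.78 and the nominal 95% interval
covers the truth only ~28% of the time, while g-computation and overlap
weighting are essentially unbiased with near-nominal coverage — scenario 1
is the setting where the measured covariate L successfully blocks the
unmeasured confounder's path.

The same machinery is available from the shell:

```bash
ecasim truth --scenario 1                 # print true marginal effects
ecasim simulate --scenario all --n-reps 3000 --outdir out/   # full study
ecasim calibrate --scenario all --outdir coeffs/  # rebuild coefficient sets
ecasim report --replicates out/replicates.csv --truths out/truths.csv --out t2.csv
```

`simulate` writes plain-CSV reports: the performance table
(`summary.csv`), per-replicate estimates (`replicates.csv`, the source for
density plots), confounder balance (`confounders.csv`), truths and a
provenance block. Identical configurations reproduce byte-identical CSVs.

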