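# maihda

Area-level MAIHDA (Multilevel Analysis of Individual Heterogeneity and
Discriminatory Accuracy) for small-area environmental inequality: build
intersectional strata from area covariates, fit two-level random-intercept
models by maximum likelihood, and summarise between-stratum inequality via
variance partition coefficients, proportional change in variance, and
empirical-Bayes stratum "interaction effects".

The package implements the ecological variant of the method: geographic
areas (e.g. census neighbourhoods) are the level-1 units, nested in strata
defined by the cross-classification of categorised area covariates
(deprivation, % minority ethnic, % degree-educated, rural/urban, % aged
65+). A synthetic-data generator emulates a national-scale area table so
the full pipeline runs without any external data.

## What it does

1. **`maihda.strata`** — categorise continuous covariates (fixed-proportion
   20/60/20 splits, equal-count tertiles, binary thresholds) and assign
   every area a concatenated digit code (e.g. `21301`); maintain the
   occupied-stratum registry and the list of structurally possible but
   empty strata.
2. **`maihda.lmm`** — exact marginal ML for the Gaussian random-intercept
   model `y_ij = x_j'b + u_j + e_ij`, computed from per-stratum sufficient
   statistics with beta and the residual variance profiled out (a 1-D
   optimisation); Wald inference; empirical-Bayes shrunken stratum
   residuals with comparative standard errors.
3. **`maihda.analysis`** — the five-model ladder (null/main-effects on the
   4-variable strata, null/main-effects on the 5-variable strata, plus an
   interaction model), VPC/PCV, ranked stratum predictions, and the list
   of strata whose EB 95% interval excludes zero.
4. **`maihda.simulate`** — Gaussian-copula covariate generator with skewed
   marginals, additive category effects, per-stratum random draws, and
   optional injected stratum-specific ("interaction") effects; truth is
   returned on a separate channel from the data.
5. **`maihda.cli`** — `simulate | build-strata | fit | report | run-all`
   subcommands reading/writing CSV + JSON.

## CLI

```bash
# simulate a study-like table and run the whole model sequence
maihda run-all --preset study-like --n 10000 --seed 1 --out results/run1

# or step by step
maihda simulate --n 10000 --seed 1 --out results/sim
maihda build-strata --input results/sim/areas.csv --out results/strata
maihda fit --input results/sim/areas.csv --model 2b --out results/fit
maihda report --summary results/run1/summary.json
```

`run-all` writes `model_comparison.csv` (coefficient table with CI
brackets and significance stars, one column per model), per-model
`stratum_predictions_*.csv` / `interaction_flags_*.csv` /
`coefficients_*.csv`, and a full-precision `summary.json`. A YAML config
(`--config`) can remap input column names and override simulation
parameters; unknown keys are rejected. Exit codes: 0 OK, 2
configuration/data error, 3 estimation error.

## Conventions worth knowing

- Quantile cut points are nearest-rank empirical quantiles; values exactly
  on a cut go to the lower category. Ordinal categories are 1..k
  low-to-high (deprivation category 3 = most deprived 20%); binaries are
  0/1. The ageing threshold is inclusive (>= 25%).
- Estimation is ML (not REML); AIC counts both variance parameters.
- All 95% intervals use the 1.96 normal multiplier. Stratum-prediction
  intervals reflect EB posterior uncertainty only, and interaction-effect
  flags (EB interval excluding zero) carry no multiplicity correction.
- A stratum-level variance estimate at the 0 boundary is clamped and
  flagged; the VPC is then 0.
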