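# bmtsim

Monte-Carlo evaluation of covariate-inclusion strategies when estimating a
biomarker–treatment interaction from a randomized trial with a
time-to-event outcome.

## The problem

Treatment individualization hinges on detecting an interaction between a
continuous baseline biomarker *B* and treatment *T*: does the treatment
effect depend on the biomarker value?  In survival analysis this is asked
through a Cox proportional-hazards model with a product term,

    λ(t | T, B, X) = λ₀(t) · exp(β_T·T + β_B·B + β_{T×B}·T·B + Σₖ βₖ·Xₖ),

where X₁…X_K are further prognostic covariates.  Interaction tests are
chronically underpowered, and analysts must decide which of the K
covariates to adjust for.  This package simulates randomized trials under
that hazard and compares six covariate-inclusion strategies:

| strategy       | prognostic covariates included |
|----------------|--------------------------------|
| `main`         | none — T, B, T×B only |
| `true`         | exactly those with nonzero true βₖ (oracle) |
| `aic_a`        | forward selection by AIC with {T, B, T×B} protected |
| `aic_b`        | forward selection from {T} with B excluded; B and T×B added afterwards |
| `significance` | every Xⱼ significant (p < 0.05) in a univariate Cox model |
| `full`         | all K |

Each strategy's final model always contains T, B and T×B.  The study grid
crosses K ∈ {12, 24, 36}, two censoring bands (30–40 % and 60–70 %
censored), three interaction strengths (β_{T×B} ∈ {0, ln 1.1, ln 1.33}),
three correlation structures between B and the Xₖ (independent,
exchangeable 0.5, block) and two prognostic-effect patterns (all ln 1.1, or
cycling ln 1.2 / ln 1.1 / 0) — 108 scenarios, each a 500-subject trial with
β_T = ln 0.75, β_B = ln 1.25, unit baseline hazard, administrative
censoring at 5 years plus exponential random censoring calibrated to the
band.  Evaluated per scenario and strategy: type-I error / power of the
Wald interaction test, 95 % CI coverage of β_{T×B}, estimator bias, number
of covariates selected, and non-convergence counts.

## Worked example

`examples/simulate_single_trial.py` simulates one trial under a qualitative
interaction (β_{T×B} = ln 1.33 = 0.285) with block-correlated covariates and
fits the interaction-only model:

```
scenario k12-low-qualitative-sigma3-beta_v
calibrated exponential censoring rate: 0.4102 per year
subjects: 500, events: 321, censored fraction: 0.358
interaction estimate: 0.243 (true value 0.285)
95% CI: (0.020, 0.466), Wald p = 0.0331
```

The calibrated rate puts the realized censored fraction (0.358) inside the
30–40 % target band; the Wald test detects the interaction in this draw at
the 5 % level.  `examples/compare_strategies.py` applies all six strategies
to one cohort, and `examples/mini_grid.py` runs a two-scenario subset at
200 replications and prints type-I error, power and coverage per strategy.

Larger runs go through the CLI, e.g. the full K=12 stratum at 1000
replications per scenario:

```
bmtsim grid --master-seed 1 --scenarios k=12 --out results/k12
```

which writes per-scenario record CSVs (resumable — rerunning skips finished
scenarios), summary tables in long and wide layout, and a manifest that
reproduces every output bit-for-bit.

## Design notes

See `docs/methods.md` for the model and its assumptions, the censoring
calibration, the Newton–Raphson partial-likelihood engine, seeding scheme,
problem sizes and known limitations.
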