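# Methods

## Data-generating model

Each simulated trial has n = 500 subjects.  The biomarker B and the K
candidate prognostic covariates X₁…X_K are jointly multivariate normal with
mean 0, unit variance and one of three correlation structures:

* **sigma1** — identity: B and all Xₖ mutually independent.
* **sigma2** — exchangeable: every pairwise correlation 0.5.
* **sigma3** — block: B and the first block correlate at 0.7 (within and
  between), a second block at 0.4, a third at 0.1, and a final block is
  independent.  At K = 12 the block sizes are (3, 4, 3, 2) covariates; for
  K = 24 and K = 36 every block scales by K/12 (proportional scaling is a
  package choice — only the K = 12 matrix is fully specified by the study
  design — and preserves both the block fractions and the biomarker's
  correlation profile).  Cross-block correlation equals the weaker block's
  level.

Treatment T is Bernoulli(0.5), independent of all covariates (a randomized
trial).  Event times are exponential with subject-specific rate

λᵢ = λ₀ · exp(β_T·Tᵢ + β_B·Bᵢ + β_{T×B}·Tᵢ·Bᵢ + Σₖ βₖ·Xᵢₖ),  λ₀ = 1/year.

Because the hazard is time-constant within subject, the exponential inverse
transform is the exact sampler.  Fixed effects: β_T = ln 0.75, β_B =
ln 1.25.  The interaction takes one of three values — 0 (null),
ln 1.1 ≈ 0.095 (quantitative: effect magnitude varies with B) and
ln 1.33 ≈ 0.285 (qualitative: effect changes sign across B).  The
prognostic coefficients are either **beta_eq** (all ln 1.1) or **beta_v**
(cycling ln 1.2, ln 1.1, 0, so exactly 2K/3 covariates are truly
associated).

## Censoring

Censoring is the minimum of an administrative cutoff at 5 years and an
independent exponential time whose rate is calibrated per scenario so that
the expected censored fraction hits the midpoint of the scenario's band
(0.35 for the low band 30–40 %, 0.65 for the high band 60–70 %).
Calibration draws 10⁵ subjects' hazards under the scenario (deterministic
given a dedicated calibration seed), then bisects the closed-form censored
fraction

P(censored | λ) = 1 − λ/(λ+c) · (1 − e^{−(λ+c)·5})

averaged over the sampled hazards; the function is strictly increasing in
the censoring rate c, so bisection converges to machine precision.  This
integrates the censoring mechanism analytically instead of re-simulating at
each bisection step: same estimand, no Monte-Carlo noise in the root-find.
If even c = 0 censors more than the band's upper limit, calibration fails
loudly (the administrative floor is reported); with the study's horizons and
hazards this does not occur.  The realized censored fraction of a 500-subject
trial then falls inside the band in well over 95 % of runs.

Exact ties between event and censoring time have probability zero; the
implementation resolves a tie as an observed event (event time ≤ censoring
time).

## Model fitting

Coefficients are estimated by maximizing the Cox partial log-likelihood
with a damped Newton–Raphson iteration implemented in numpy.  The data are
sorted once per cohort by decreasing follow-up time so risk sets are array
prefixes; the gradient and observed information are then O(np) and O(np²)
per iteration — the information's risk-set second-moment term is evaluated
as Xᵀ·diag(w·r)·X, where r is a reverse cumulative sum of inverse risk-set
totals over events, avoiding any (n, p, p) intermediate.  This matters
because forward selection fits hundreds of models per cohort; warm starts
from the parent model cut the typical fit to three or four iterations.  The
engine agrees with lifelines' `CoxPHFitter` to its convergence tolerance
and with a brute-force risk-set evaluation to 10⁻⁸ on small fixtures (both
checks are in the test suite).

Convergence: relative partial-log-likelihood change < 10⁻⁹, at most 100
iterations, step halving (≤ 25) whenever a step would decrease the
objective.  A fit is declared non-converged when the iteration limit is
hit, the information matrix is singular, any coefficient or standard error
is non-finite, any |β| exceeds 50 (monotone-likelihood divergence), or any
covariance diagonal is non-positive.  Non-convergence is recorded per
strategy per run and excluded from all aggregates; it is never raised as an
exception from a strategy.

Event and censoring times are continuous, so tied event times occur with
probability zero.  The likelihood is evaluated in its no-ties form, which
coincides with both Efron's and Breslow's tie corrections on tie-free data;
if tied times are ever supplied, risk sets follow Breslow's approximation.
Variance estimates are the inverse observed information at the maximum; the
95 % interval for the interaction coefficient is β̂ ∓ 1.959964·SE, and its
two-sided Wald p-value drives all rejection proportions (α = 0.05, strict
inequality).

## Selection strategies — implementation choices

* Forward selection adds, at each step, the candidate giving the largest
  value of the criterion 2·loglik − 2·p, provided it *strictly* exceeds the
  current model's value; ties break to the lowest candidate index, so
  selection is deterministic given the cohort.  Candidates whose augmented
  fit does not converge are skipped at that step.  (The criterion is the
  sign-flipped, maximized form of the conventional AIC; rankings are
  identical.)
* In `aic_b`, the biomarker is excluded from candidacy and the base model
  is {T} alone; B and T×B are appended after selection and the final model
  refitted.
* The significance screen fits each Xⱼ in a model containing *only* Xⱼ (no
  treatment), keeping it at two-sided p < 0.05.  The 0.05 level is a package
  choice; it is the level used everywhere else in the study.  Screening
  fits that fail to converge count as not selected (and are tallied).

## Scenario grid and seeding

The factorial (K × censoring band × interaction × correlation ×
coefficients) yields 108 scenarios, enumerated lexicographically with
factor levels in their declared order; the order is frozen.  Per-run seeds
come from a `numpy` `SeedSequence` whose spawn key encodes the master seed,
the scenario's factor-level indices and the replication index — not the
enumeration position — so any subset of the grid, run in any order,
reproduces the corresponding rows of a full run bit-for-bit.  Censoring
calibration uses a reserved stream index disjoint from all replication
indices.

## Evaluation

Per scenario × strategy: rejection proportion (type-I error under the null,
power otherwise), CI coverage of the true β_{T×B}, mean selected-covariate
count, mean bias and estimate quartiles, all over converged runs only;
non-converged runs are tallied separately and never silently dropped.
Cells with zero converged runs are emitted as missing, not zero.  Pooled
table cells (aggregation over correlation and coefficient structures) are
run-weighted: pooled counts over pooled denominators, which equals the
simple mean when replication counts match.  A null-scenario rejection
proportion strictly above 7 % is flagged as inflated.

## Problem sizes

The published grid uses 1000 replications per scenario (108 000 trials).
The packaged acceptance checks reproduce selected cells at desk scale:
pooled type-I error of the `main` strategy at 6×1000 replications, `aic_b`
at 6×300, `aic_a` at 6×150, selected-covariate means at 300–450
replications, and oracle-model calibration at 2000 replications; the
acceptance script uses slightly smaller counts.  Tolerances are three
Monte-Carlo standard errors at the replication count actually run.  A full
108-scenario, 1000-replication reproduction is a few CPU-hours through
`bmtsim grid` and is resumable per scenario.

## What the generator does and does not emulate

It emulates the study conditions exactly: normal biomarkers, linear
log-hazard effects, proportional hazards, exponential baseline,
non-informative censoring.  It does not emulate skewed or categorical
biomarkers, non-linear or time-varying effects, informative censoring, or
multiple competing biomarkers — conclusions from passing tests are
statements about estimator behaviour under the stated model, not about
robustness to its violation.

## Known limitations

* Wald inference only; likelihood-ratio or score alternatives are not
  implemented.
* The non-convergence *counts* depend on optimizer implementation details
  (tolerances, damping); they are bookkept and reported but not treated as
  a reproducible quantity.
* Backward/stepwise-both selection, BIC, penalized fits, stratified or
  time-dependent Cox models are out of scope.
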