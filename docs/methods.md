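# Methods

## The selection problem

Individual annual healthcare costs conditional on use are strictly
positive, right-skewed and heteroscedastic, and the appropriate estimator
differs by service line. Two candidate classes cover most practice:

- **log-OLS** — `log Y = α + Xβ + ε`, ordinary least squares on log costs.
  Robust to heavy tails, but EUR-scale conditional means require a
  retransformation factor `E[e^ε | x]`, which is where the difficulty
  concentrates.
- **log-link GLM** — `E[Y|X] = exp(α + Xβ)` fitted by quasi-likelihood
  under a power variance function `V(μ) = μ^λ`, λ ∈ {0 (Gaussian),
  1 (Poisson), 2 (gamma), 3 (inverse Gaussian)}. No retransformation is
  needed, but the quasi-likelihood estimator loses badly in precision when
  the log-scale error distribution is heavy-tailed.

The selection rule implemented here routes on the raw (Pearson) kurtosis
`m₄/m₂²` of the log-scale residuals of a preliminary log-link gamma GLM:
kurtosis ≤ 3 keeps the GLM class; values in (3, 3.25) keep the GLM but set
a `borderline_kurtosis` flag so an analyst can confirm the precision
statistics look reasonable; kurtosis ≥ 3.25 routes to log-OLS. The
thresholds `tau_low = 3.0` (the normal reference value) and
`tau_high = 3.25` are parameters of `ManningMullahySelector` /
`PipelineOptions`.

On the GLM branch the variance family is chosen by the Park test: the
slope λ of a log-link quasi-likelihood (gamma-family) regression of the
squared raw residuals `(y − μ̂)²` on `log μ̂`, clamped to [0, 3] and mapped
to the nearest integer; half-integer ties round up to the higher-variance
family as the conservative choice. An OLS-of-logs variant is available via
`park_test(..., variant="ols_log")`.

## Robustness battery

- **Modified Hosmer–Lemeshow.** Rows ranked by fitted mean, cut into 10
  quantile bins (stable order breaks ties); raw residuals regressed on the
  bin indicators with no intercept; the classical OLS F-test of the joint
  null that all bin means are zero (df = groups, n − groups). The
  HC-robust Wald variant was measured to *under*-reject (type-I ≈ 0.02 at
  n = 2,000 under a correctly specified gamma GLM) because per-bin t
  statistics are biased downward two-sided under right-skewed residuals;
  the classical F measures ≈ 0.045 and is the default.
- **MAPE / MEDAPE.** `PEᵢ = (yᵢ − ŷᵢ)/yᵢ` with the observed cost as the
  denominator (always positive for positive-cost models); MAPE is the mean
  of |PE|, MEDAPE the median, both reported as proportions. MEDAPE is the
  outlier-robust member of the pair.
- **Pregibon link test** (GLM branch): refit the same-family GLM on the
  centered linear predictor and its square; the reported statistic is the
  coefficient of the squared term with its Wald p-value. Centering leaves
  that coefficient unchanged while keeping the refit well conditioned.
- **Breusch–Pagan** (log-OLS branch): Koenker's studentized form, `n·R²`
  of the auxiliary regression of squared residuals on the design,
  χ²(non-intercept columns); delegated to
  `statsmodels.stats.diagnostic.het_breuschpagan`. A constant squared
  residual vector returns LM = 0, p = 1 by convention.

When Breusch–Pagan rejects at 0.05 the pipeline (a) reports Huber–White
sandwich standard errors for the log-OLS coefficients and (b) replaces the
global Duan smearing factor `mean(exp ε̂)` with a per-individual
`exp(v̂(x)/2)` built from a **secondary variance model**: OLS of
`log ε̂²` on the design, exponentiated fitted values rescaled by a
method-of-moments constant so their mean equals the mean squared residual.
Exact zero residuals are replaced by the smallest positive |residual|
before the log, with a warning and a count on the result. With an
intercept-only design this reduces to the homoscedastic normal-theory
factor `exp(σ̂²/2)` to machine precision.

The heteroscedastic factor is *normal-theory*: when the log-scale errors
are genuinely heavy-tailed (e.g. Student-t with 3 degrees of freedom) the
true smearing moment `E[e^ε]` exceeds `exp(σ²/2)` substantially and the
retransformed predictions systematically undershoot the observed mean.
This is a documented limitation of the construction, not of the
implementation; the calibration guarantee (mean predicted / mean observed
within ±2% at n = 50,000) applies to lognormal heteroscedastic worlds and
is asserted there.

## Fitting

The log-link GLM is fitted by an IRLS solver authored in
`costlines.models`: working weights `μ^(2−λ)` (expected information),
working response `η + (y − μ)/μ`, step-halving on the quasi-deviance, the
linear predictor clipped to ±250, and the response rescaled by its
geometric mean before iteration (log-link power-family fits are
scale-equivariant, so only the intercept shifts back). Starting values come
from OLS on `log y`; the stopping rule is a relative quasi-deviance change
below 1e-8 or 100 iterations, with a `ConvergenceError` carrying the
deviance trace on failure. The safeguards matter: generic IRLS
implementations overflow on the heavy-tailed synthetic worlds this package
must handle (costs spanning ten orders of magnitude), which is why the
solver is in-house; it is cross-checked in the test suite against
statsmodels GLM on well-behaved data and against direct likelihood
maximization on small fixtures. Dispersion for the non-Gaussian families is
the Pearson moment estimate and affects standard errors only. Model-based
covariance is `φ·(XᵀWX)⁻¹`; the Huber–White sandwich uses the expected
information as bread and squared score residuals as meat (HC0 form; it
therefore differs from observed-Hessian sandwiches by O(n^-1/2) relative
terms under the non-canonical log link).

Effects are reported as `exp(β̂)` per term against fixed baselines (female;
ACRG3 "1-0" healthy), age per year of life; p-values use the Huber–White
covariance on the log-OLS branch (model-based p-values are unreliable
under the heteroscedasticity that branch exists to handle) and the
model-based covariance on the GLM branch, both Wald-normal at level 0.05.

## Synthetic cohort generator

`generate_cohort` draws, per individual: an ACRG3 category from a
configurable probability map (default: the published cross-sectional
population mix over 44 populated status × severity cells, normalized to
sum exactly 1); sex (male probability 0.49 in the preset); and age from a
truncated normal (mean 42, SD 23, support [0, 100]) mimicking a population
clustered in the central ages. Per service line, the individual is a user
with probability `use_prob[line][category]`, independently across lines
given the category; non-users have cost exactly 0. Positive cost is

```
base_cost[line] × effect[category] × sex_effect^[male]
               × age_slope^(age − mean age) × exp(ε)
```

with `ε` from one of three log-scale error families, its SD scaled by a
per-category heteroscedasticity coefficient:

- `lognormal`: ε ~ N(0, (σh)²); exact retransformation moment
  `exp(σ²h²/2)`.
- `gamma`: `exp(ε) ~ Gamma(k/h²)/(k/h²)` — mean exactly 1 for every h, so
  the GLM-gamma model is correctly specified; `Var(log Gamma(k)) ≈ 1/k`
  motivates the `k/h²` scaling.
- `log_t`: ε = σh·T with T a standardized Student-t(df), df > 2,
  truncated at |T| ≤ 8 (in SD units). The truncation is essential, not
  cosmetic: an unbounded t has no moment generating function, so
  `E[e^ε]` would be infinite and no mean model would exist. The
  retransformation moment is computed by numerical quadrature on the
  truncated law. At df = 3 the finite-sample kurtosis of the log residuals
  sits far above 3.25 (typically 5–15 at n = 20,000), reliably exercising
  the log-OLS branch.

`true_expected_cost` returns the exact generative `E[Y | X, Y > 0]` for
any profile and is the oracle for every parameter-recovery and calibration
test.

### Presets (the reference conditions of the test suite)

- `table1_preset()` — seven service lines, the published category mix, use
  probabilities interpolated on the log-odds scale from a healthy level to
  a catastrophic level per line, and a single exponent calibrated by
  bisection so the expected fraction of individuals with any positive cost
  is 76,360/92,498 ≈ 0.8255 (the reference population's user share). Morbidity
  effects are multiplicative in status and severity (1 up to ≈ 230 for the
  worst catastrophic cell), sex effect 0.87, age slope 1.005 per year,
  lognormal σ = 1 errors. Per-line magnitudes are illustrative, not
  calibrated to any published per-line figure.
- `gamma_world()` — five categories with effects {1, 2, 5, 20, 100},
  mean-one gamma noise with shape 20. A log-gamma is always slightly
  leptokurtic (excess ≈ 2/k), so a gamma world with kurtosis strictly
  below 3 does not exist; shape 20 puts the kurtosis near 3.1, safely
  below the 3.25 routing threshold (possibly borderline-flagged, which
  still selects the GLM).
- `heavy_tail_world()` — log-t₃ errors, σ = 0.8, heteroscedasticity
  coefficients up to 1.5 across categories: kurtosis ≫ 3.25 and
  Breusch–Pagan power ≈ 1 at n = 20,000.
- The retransformation-calibration world uses lognormal errors with
  log-scale SDs 0.3–0.7 across four categories: strongly heteroscedastic,
  while keeping the Monte-Carlo noise of the observed arithmetic mean
  (~0.7% at n = 50,000) small against the ±2% calibration band. With
  heavier tails that band would measure sampling noise, not calibration.

### What the generator does not emulate

Cross-line use correlation beyond what the shared morbidity category
induces (lines are conditionally independent); longitudinal structure;
non-linear age effects; any real cost accounting. Passing tests therefore
demonstrate that the pipeline recovers the truth of *this* generative
family at the stated sizes — they do not validate the published per-line
estimates, which derive from undeposited person-level records.

## Problem sizes and numerical choices

The acceptance suite runs: Park-slope recovery at 100 replicates of
n = 5,000; end-to-end routing at 100 replicates of n = 20,000 per world;
effect recovery at 100 replicates of n = 50,000; diagnostic calibration at
1,000 replicates of n = 2,000, with single power cases at n = 20,000.
These sizes make every Monte-Carlo band decisive (binomial SE of a 5%
rate at 1,000 replicates is 0.7 points) while the whole suite stays in the
tens of seconds on one CPU.

Tie-breaks and degenerate inputs: kurtosis requires ≥ 4 finite values and
positive variance; Park requires positive fitted means and some nonzero
residual; HL bins reduce (with a warning) until every bin has ≥ 2 rows;
`min_n = 50` positive-cost rows gates each line; categories with < 2
positive rows are dropped from the design with a warning and recorded;
zero-variance columns are dropped to keep the design full rank.

## Known limitations

- The kurtosis router inherits the preliminary fit: when extreme
  heteroscedastic heavy tails drive the GLM's fitted category means far
  from the log-scale means, the per-category residual offsets inflate m₂
  and can *dilute* the measured kurtosis. The shipped worlds stay in the
  regime where routing is reliable; arbitrarily extreme worlds are not.
- The heteroscedastic retransformation is normal-theory (see above).
- The two-part structure (probability of use) is generated but not
  modelled: positive costs only, as the selection procedure prescribes.
- No multiplicity correction across service lines.
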