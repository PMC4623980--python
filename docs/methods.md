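# Methods

This note documents the statistical models implemented in `tunabio`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter when
reproducing results.

## Standardization

Pooled bluefin records mix five length and five weight measurement types.
Pairwise conversions `y = a + b·x` are fitted by iteratively reweighted
least squares with the Tukey bisquare influence function (tuning constant
4.685, the conventional 95%-efficiency value), started from the OLS
solution and iterated to coefficient convergence (tolerance 1e-8, at most
50 iterations); `statsmodels.RLM` provides the IRLS engine. On exactly
collinear data the robust scale estimate degenerates, so the OLS
coefficients (already exact) are kept. `r²` is reported as the squared
Pearson correlation of observed and fitted values and the residual SE as
`sqrt(SSE/(n−2))` on unweighted residuals.

Only conversions with `r² ≥ 0.98` (configurable gate) may be applied when
standardizing. Measured SFL and RWT always pass through untouched; SFL is
otherwise derived from CFL, and RWT from the stock's processed-weight
priority order — East: GWT then GGWT, West: DWT. GWT is tried before GGWT
because gutted weight is the less-processed state, hence the shorter
extrapolation to round weight. Conversions are fitted per stock and never
pooled. Head, preopercular and first-dorsal lengths are fitted and
reported but never used for standardization (their `r²` sits below any
defensible gate). Beyond the robust fit's own downweighting no outlier
removal is applied by default; an optional pre-filter drops records whose
observed (x, y) pair sits more than 5 residual SEs off a gated conversion.

## Weight-length relationship

The annual relation is `W = α·L^β` (W in kg, L in cm SFL). Weight
variance at size is strongly size-structured, so the production fit
minimizes `Σ wᵢ (Wᵢ − α·Lᵢ^β)²` with `wᵢ = 1/CV(bin(Lᵢ))`, the inverse of
the sample CV of weight in the fish's half-open 5 cm length bin
`[L, L+5)` (bins indexed from 0 cm; the weight is 1/CV, not 1/CV², with a
`cv_power` switch for the squared variant). Bins with fewer than 10 fish,
an undefined CV, or a zero CV are imputed with the mean CV of the
reliable bins; if no reliable bin exists the fit degenerates to equal
weights.

The minimizer is a Gauss-Newton iteration with step halving, initialized
at the log-log OLS estimate and stopped when the relative change in
weighted SSE falls below 1e-10 (at most 100 iterations);
non-convergence raises rather than returning a silent result. RMSE and
the residual SE are reported on unweighted residuals; AIC uses a Gaussian
likelihood on unweighted residuals with k = 3 (α, β, σ²); the parameter
covariance comes from the weighted normal equations at the optimum.

### Quantile regression

Conditional quantile curves `α_τ·L^β_τ` minimize the pinball loss
`Σ ρ_τ(Wᵢ − α·Lᵢ^β)`. The loss is non-smooth, so it is minimized by
Nelder-Mead in (log α, β) space (tolerances 1e-8, one restart from the
first solution to escape simplex stalls), started at the least-squares
fit. Quantiles are equivariant under monotone transforms, so the fit is
cross-checked in the tests against the back-transformed linear quantile
regression of log W on log L (`statsmodels.QuantReg`); the two estimators
coincide asymptotically but differ in finite samples by an amount of the
order of their sampling error, so the equivalence test runs in a
light-noise regime (lognormal σ = 0.01, n = 20,000) where that
finite-sample difference is second-order.

### Bootstrap schemes

Two nonparametric schemes, each replicate refitted exactly like the point
estimate (including recomputing bin CV weights on the replicate):

- `EQUAL_PROB`: n draws from n with replacement — sampling error under
  the empirical size composition.
- `UNIFORM_PER_BIN`: a fixed number of draws (default 100) with
  replacement from every occupied 5 cm bin in [30, 300) cm — a "what if
  the size composition were balanced" experiment.

Summaries per parameter: mean, bias against the point estimate,
2.5/97.5 percentile interval and skewness. In weight-space least squares
the influence of an observation scales with its absolute residual and
gradient magnitude, so small fish carry almost no influence regardless of
their count; the balanced scheme visibly degrades the large-fish fit only
when the empirical composition is large-fish-heavy (sparse sub-adult bins
get upweighted) and the sub-adults deviate from the adult allometry.
The scheme-contrast test constructs exactly that configuration.

## Sampling representativeness

An equilibrium age-structured population: `N₁ = 1`,
`N_{a+1} = N_a·e^{−Z_a}` with `Z = M + F` (F defaults to 0 — the
reference run is an unfished population), and an optional plus-group that
closes the oldest age with the geometric sum `N_A·e^{−Z_A}/(1−e^{−Z_A})`.
Length-at-age is Normal(μ_a, cv·μ_a) with cv = 0.125 by default; the
expected per-1 cm sampling proportion is the survivorship-weighted
mixture of normal bin integrals, with mass below zero (negligible at this
cv) clipped and the distribution renormalized. Knife-edge selectivity
zeroes every bin starting below the threshold, then renormalizes.
Observed compositions are compared via CDFs and the KS distance
(maximum absolute CDF gap).

Ages are whole years with no within-year growth; the month of capture
affects condition only, not size-at-age.

## Seasonal condition

Scaled residuals `(obs − pred)/pred` against the annual CV-weighted fit
are bounded below by −1 and grow with plumpness; values strictly greater
than 1 (observed more than double the prediction) are excluded in a
single pass (exactly 1 is retained; the annual fit is not refitted after
exclusion). Maturity is assigned by stock-specific size thresholds
(East ≥ 130 cm, West ≥ 185 cm SFL) and areas map to broad regions: east
Atlantic; western-central Mediterranean including the Strait of
Gibraltar; eastern Mediterranean; one western group (the Gulf of Mexico
sample is too thin to stand as its own factor level).

The condition model is OLS with length continuous and sum-to-zero
(effects) coded factors, so factor coefficients read as departures from
the annual mean; per-factor deviance is the Type III sum of squares. Year
is supported as a diagnostic factor (the month-over-year deviance ratio)
but excluded from the final monthly model. The LSMean for month m is the
model prediction averaged over a balanced grid of all other factor
levels with length fixed at its overall mean, centered to mean zero —
robust to the (severe) monthly imbalance of fishery sampling. The
monthly table is

    β_m = β_annual + LSMean_m × MSE,

with MSE the residual mean square, applied as written; whether the
intended scale is the mean square or its root is ambiguous, so an
`exponent_scale="rmse"` switch exposes the alternative. Note that with
this scaling the recovered seasonal amplitude is a strongly shrunken
version of an injected exponent cycle (LSMean ≈ offset × mean log-length,
then × MSE ≈ 0.01), so end-to-end recovery checks assert sign and rank
patterns, not amplitudes.

## Synthetic-data generator

The generator defines the study conditions for every simulation-based
test. Per fish: age drawn with survivorship probabilities (plus-group at
the oldest configured age); capture month uniform on 1–12 and year
uniform on 1998–2012; SFL ~ Normal(μ_age, 0.125·μ_age), redrawn if
non-positive; and

    RWT = α · SFL^(β + offset[month]) · e^ε,  ε ~ Normal(0, σ(SFL)),

with `σ = sqrt(ln(1 + CV(SFL)²))` so the realized CV of weight at fixed
length equals the configured profile. The CV profiles are
piecewise-linear in SFL — East: 20% for small fish easing to 9% at
100–150 cm then 12.5% at 300 cm; West: 13% below 120 cm, a 35% hump at
160–200 cm, 12.5% at 300 cm — matching the size-structure of weight
variance the analysis is designed around (the exact knots are a generator
choice). Monthly exponent offsets are centered to mean zero on
construction; the defaults are the centered deviations of the packaged
monthly reference exponents, so default seasonality has realistic
magnitude (~±0.008).

Mortality and growth defaults are user-supplied, assessment-style values,
not estimates: East M-at-age 0.49, 0.24 (ages 2–5), 0.20, 0.175, 0.15,
0.125, then 0.10; West flat 0.14; von Bertalanffy growth East
(L∞ = 318.85 cm, k = 0.093, t₀ = −0.97), West (314.9, 0.089, −1.13);
ages 1–20 with a plus-group. Because the simulated population's size
composition depends directly on these inputs, absolute composition
figures (e.g. the fraction of fish below some size) are configuration
statements, not reproduction targets.

A fleet layer turns latent fish into field records: each fleet records a
subset of measurement types, produced by deterministic conversion of the
latent truth (identity for SFL/RWT; the packaged reference conversions in
the latent-to-observed direction otherwise) plus optional additive
Gaussian measurement noise, then knife-edge minimum-size retention
(default 75 cm East, 170 cm West), an optional logistic selectivity
curve, and the fleet's active months. All randomness flows from a single
seeded stream in fixed stage order, so configuration + seed reproduces a
dataset byte for byte.

What the generator does **not** emulate: spatial movement and area-specific
abundance, within-year growth, size-dependent maturity effects on the
weight noise, correlated measurement errors, and recording errors beyond
symmetric noise. Passing tests therefore demonstrate that the estimators
recover known structure under the stated noise model, not that real
fishery data satisfy that model.

### A note on recovery bias

The generator's weight noise is median-parameterized (mean-zero in the
log), so `E[W | L] = α L^β e^{σ(L)²/2}`. With a size-varying CV profile
the correction factor varies with L, and the mean-regression exponent
therefore carries a small systematic offset (~+0.006 under East
defaults) from the median-curve β. Combined with the heavy-tailed
influence of plus-group giants this puts the per-seed spread of the
recovered exponent near ±0.015 at n = 20,000; the median estimate over
seeds stays within ±0.01 of the generating value, which is what the
recovery checks assert.

## Problem sizes and tolerances

Simulation-based tests use 15,000–100,000 fish and 60–1,000 bootstrap
replicates, chosen so each check resolves its effect with a comfortable
Monte-Carlo margin; the bootstrap-precision analysis uses n = 50,000 and
B = 200 replicates over a 60–280 cm grid in 10 cm steps. All stochastic
tests fix their seeds. Statistical assertions use bounds of 3–5 standard
errors; oracle equivalences use the tolerances stated inline
(grid-optimum dominance to 1e-12 relative, plus-group closure to 1e-9,
LSMeans brute-force agreement to 1e-10).
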