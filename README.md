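# tunabio

Biometric relationships and seasonal condition analysis for Atlantic
bluefin tuna (*Thunnus thynnus*), built for fisheries scientists who need
to pool heterogeneous dockside measurements into stock-level weight-length
relationships, audit how sensitive those relationships are to sampling
imbalance, and express seasonal condition cycles as monthly coefficients.

Bluefin sampling programmes record whichever measurement is practical:
straight or curved fork length (SFL, CFL, cm), snout-to-dorsal or head
lengths, and round, gutted, gutted-and-gilled or dressed weights (RWT,
GWT, GGWT, DWT, kg). `tunabio` implements the full analysis chain for the
two management stocks (East Atlantic + Mediterranean, and West Atlantic):

1. **Standardization** — pairwise length-length and weight-weight
   conversions `y = a + b·x` fitted by robust (Tukey-bisquare IRLS) linear
   regression; only conversions with `r² ≥ 0.98` are used to express
   records in the standard units `SFL_std` / `RWT_std`.
2. **Weight-length relationship (WLR)** — the allometric power law
   `RWT_std = α · SFL_std^β`, fitted by Gauss-Newton nonlinear least
   squares with each observation weighted by the inverse coefficient of
   variation (CV) of weight in its 5 cm length bin, because weight-at-size
   variance is strongly size-structured.
3. **Sensitivity analyses** — nonlinear quantile regression (pinball
   loss) for distributional curves; two nonparametric bootstrap schemes
   (equal-probability resampling, and a uniform number of draws per 5 cm
   bin that emulates a balanced size composition).
4. **Sampling representativeness** — an age-structured population
   simulator (survivorship under natural/fishing mortality, normal
   length-at-age with 12.5% CV, optional knife-edge minimum-size
   selectivity) giving the expected per-1 cm sampling distribution, with
   Kolmogorov-Smirnov comparison against observed compositions.
5. **Seasonal condition** — scaled residuals `(obs − pred)/pred` from the
   annual WLR modelled by an effects-coded linear model with length,
   month, maturity and broad area; monthly least-squares means (LSMeans)
   feed the monthly equation
   `RWT_std,m = α · SFL_std^(β + LSMean_m · MSE)`.
6. **Synthetic fishery generator** — a first-class, seeded generator that
   emulates the statistical structure of pooled fishery sampling (ages by
   survivorship, size-dependent lognormal weight noise, mixed measurement
   types per fleet, minimum-size truncation, monthly condition cycles) so
   the whole chain is testable end to end.

The published coefficient tables for both stocks ship as JSON fixtures
(`tunabio.fixtures`) and serve as evaluation references and generator
defaults.

## Worked example

Run the full workflow on a 20,000-fish synthetic Eastern dataset:

```bash
tunabio all --stock EAST --n-fish 20000 --seed 1 -B 200 out/
```

which prints (abridged):

```
stock EAST  seed 1  config c745b2623c6c4ed7
records 14608  standardized 14608  WLR input 14608

annual WLR (CV-weighted):  W = 3.295e-05 * L^2.8913   rmse 25.020 kg
annual WLR (unweighted):   W = 3.268e-05 * L^2.8928   rmse 25.020 kg

quantile fits (tau: alpha, beta):
   0.025: 3.518e-05, 2.8379
     0.5: 3.434e-05, 2.8827
   0.975: 3.445e-05, 2.9235

bootstrap EQUAL_PROB (B=200): beta mean 2.8904, 95% CI [2.8699, 2.9117], skew 0.068
bootstrap UNIFORM_PER_BIN (B=200): beta mean 2.878, 95% CI [2.8547, 2.9033], skew 0.318

monthly exponents:
  month  5: beta 2.89190914
  month  8: beta 2.89094868
```

Reading the output: 20,000 simulated fish leave 14,608 records after the
75 cm minimum-size retention; the CV-weighted fit recovers an exponent
near the generating value (β = 2.8785 with a small mean-vs-median offset,
see `docs/methods.md`); the equal-probability bootstrap distribution is
near-symmetric (skew 0.07) and tight; the monthly exponents peak in May
(fish in best condition) and dip in July-August, mirroring the seasonal
cycle injected by the generator defaults. The output directory holds the
machine-readable `report.json` (byte-reproducible for a given
configuration and seed), standardized records, the residual table and the
monthly coefficient CSV.

The same stages are available as library calls (`generate_dataset`,
`standardize_records`, `fit_power_law`, `bootstrap_wlr`,
`fit_power_quantile`, `expected_size_distribution`, `scaled_residuals`,
`lsmeans_month`, `monthly_wlr_table`) and as individual subcommands
(`simulate`, `standardize`, `fit-wlr`, `sensitivity`, `popsim`,
`condition`, `report`).

Evaluating the packaged reference curves directly:

```python
>>> import tunabio as tb
>>> from tunabio import fixtures
>>> east = fixtures.reference_wlr(tb.Stock.EAST)
>>> round(tb.predict_weight(east, 100.0), 2)   # kg at 100 cm
20.06
>>> west = fixtures.reference_wlr(tb.Stock.WEST)
>>> cmp = tb.compare_wlrs(east, west, [110.0], denominator="B")
>>> round(float(cmp.pct_diff[0]), 1)           # East heavier by ~11%
11.3
```

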