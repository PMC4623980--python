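"""Power-law weight-length fitting, quantile regression, bootstraps and
curve comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import tunabio as tb
from tunabio.errors import FitError
from tunabio.types import Measurement, Stock
from tunabio.wlr import BinCV, bin_cv_profile

from conftest import make_std


# ---------------------------------------------------------------------------
# binned CV profile


def test_bin_cv_constant_and_spread_bins():
    df = make_std([52, 53, 54, 61, 62, 63], [12, 12, 12, 10, 12, 14])
    bins = {b.bin_lower: b for b in bin_cv_profile(df)}
    assert bins[50.0].cv == pytest.approx(0.0)
    assert bins[60.0].mean_w == pytest.approx(12.0)
    assert bins[60.0].sd_w == pytest.approx(2.0)
    assert bins[60.0].cv == pytest.approx(2.0 / 12.0)


def test_bin_cv_empty_and_sparse_bins_flagged():
    df = make_std([52, 53, 54, 71], [10, 11, 12, 30])
    bins = {b.bin_lower: b for b in bin_cv_profile(df)}
    assert bins[60.0].n == 0 and bins[60.0].flagged
    assert np.isnan(bins[60.0].cv)
    assert bins[70.0].flagged          # single fish: CV undefined
    assert bins[50.0].flagged          # n=3 below the default min count
    assert bin_cv_profile(make_std([], [])) == []


def test_bin_cv_matches_groupby_oracle():
    rng = np.random.default_rng(2)
    L = rng.uniform(40, 120, 500)
    W = rng.uniform(5, 60, 500)
    df = make_std(L, W)
    got = {b.bin_lower: b for b in bin_cv_profile(df) if b.n}
    oracle = df.groupby(np.floor(df.sfl_std / 5) * 5)["rwt_std"]
    for lower, grp in oracle:
        assert got[lower].n == len(grp)
        assert got[lower].mean_w == pytest.approx(grp.mean())
        if len(grp) >= 2:
            assert got[lower].cv == pytest.approx(grp.std() / grp.mean())


# ---------------------------------------------------------------------------
# power-law fit


@pytest.mark.parametrize("weighting", ["NONE", "INV_CV"])
def test_noise_free_power_law_recovered_exactly(weighting):
    L = np.linspace(40, 280, 60)
    fit = tb.fit_power_law(make_std(L, 2e-5 * L**3.0), weighting=weighting)
    assert fit.alpha == pytest.approx(2e-5, rel=1e-6)
    assert fit.beta == pytest.approx(3.0, rel=1e-6)
    assert fit.converged
    assert fit.rmse == pytest.approx(0.0, abs=1e-8)


def test_optimum_beats_brute_force_parameter_grid():
    rng = np.random.default_rng(10)
    L = np.exp(rng.uniform(np.log(50), np.log(280), 2000))
    W = 2e-5 * L**2.9 * np.exp(rng.normal(0, 0.12, L.size))
    fit = tb.fit_power_law(make_std(L, W), weighting="NONE")

    def sse(a, b):
        return np.sum((W - a * L**b) ** 2)

    best = sse(fit.alpha, fit.beta)
    for fa in np.linspace(0.99, 1.01, 21):
        for fb in np.linspace(0.99, 1.01, 21):
            assert sse(fit.alpha * fa, fit.beta * fb) >= best * (1 - 1e-12)


def test_constant_bin_cvs_reduce_to_unweighted_fit():
    rng = np.random.default_rng(3)
    L = rng.uniform(40, 200, 800)
    W = 3e-5 * L**2.9 * np.exp(rng.normal(0, 0.1, L.size))
    df = make_std(L, W)
    flat = [BinCV(lo, 100, 1.0, 0.1, 0.1, False)
            for lo in np.arange(40.0, 205.0, 5.0)]
    weighted = tb.fit_power_law(df, weighting="INV_CV", bins=flat)
    plain = tb.fit_power_law(df, weighting="NONE")
    assert weighted.alpha == pytest.approx(plain.alpha, rel=1e-9)
    assert weighted.beta == pytest.approx(plain.beta, rel=1e-9)


def test_generator_defaults_single_seed_recovery_within_003():
    config = tb.GeneratorConfig.default(
        tb.Stock.EAST, n_fish=20000, seed=12, true_beta=2.9)
    records = tb.generate_dataset(config)
    df = make_std(records["sfl_cm"], records["rwt_kg"]).dropna()
    for weighting in ("NONE", "INV_CV"):
        fit = tb.fit_power_law(df, weighting=weighting)
        assert fit.beta == pytest.approx(2.9, abs=0.03)


@pytest.mark.parametrize(
    "bad",
    [
        make_std(np.linspace(50, 60, 5), np.linspace(5, 6, 5)),  # n < 10
        make_std(np.full(20, 100.0), np.full(20, 20.0)),         # < 3 bins
    ],
)
def test_fit_rejects_inadequate_data(bad):
    with pytest.raises(FitError):
        tb.fit_power_law(bad)


def test_fit_rejects_non_positive_measurements():
    df = make_std(np.linspace(-50, 280, 30), np.linspace(1, 300, 30))
    with pytest.raises(FitError):
        tb.fit_power_law(df)


# ---------------------------------------------------------------------------
# prediction


def test_predict_published_coefficients(east_ref, west_ref):
    # independent hand evaluations of the printed coefficients
    assert tb.predict_weight(east_ref, 100.0) == pytest.approx(20.059,
                                                               abs=0.01)
    assert tb.predict_weight(west_ref, 200.0) == pytest.approx(142.58,
                                                               abs=0.05)
    assert tb.predict_weight(east_ref, 1.0) == pytest.approx(east_ref.alpha)


def test_predict_rejects_non_positive_length(east_ref):
    with pytest.raises(ValueError):
        tb.predict_weight(east_ref, 0.0)
    with pytest.raises(ValueError):
        tb.predict_weight(east_ref, np.array([100.0, -1.0]))


# ---------------------------------------------------------------------------
# quantile regression


@pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
def test_quantile_fit_degenerates_without_noise(tau):
    L = np.linspace(40, 280, 80)
    df = make_std(L, 2e-5 * L**3.0)
    q = tb.fit_power_quantile(df, tau)
    assert q.alpha == pytest.approx(2e-5, rel=1e-4)
    assert q.beta == pytest.approx(3.0, rel=1e-5)
    assert q.pinball_loss == pytest.approx(0.0, abs=1e-6)


def test_quantile_fit_matches_log_linear_oracle():
    """Conditional quantiles are equivariant under the log transform, so
    the pinball fit in weight space must agree with the back-transformed
    linear quantile fit of log-weight on log-length.  The check runs in a
    light-noise regime where finite-sample estimator differences are
    second order."""
    rng = np.random.default_rng(11)
    n = 20000
    L = np.exp(rng.uniform(np.log(40), np.log(300), n))
    W = 2e-5 * L**3.0 * np.exp(rng.normal(0, 0.01, n))
    q = tb.fit_power_quantile(make_std(L, W), 0.5)
    oracle = smf.quantreg(
        "lw ~ ll", pd.DataFrame({"lw": np.log(W), "ll": np.log(L)})
    ).fit(q=0.5)
    assert q.alpha == pytest.approx(float(np.exp(oracle.params["Intercept"])),
                                    rel=5e-3)
    assert q.beta == pytest.approx(float(oracle.params["ll"]), rel=5e-3)


def test_median_fit_below_least_squares_under_lognormal_noise():
    """The median of a lognormal lies below its mean, so the tau=0.5 curve
    must predict less than the least-squares curve at every length."""
    rng = np.random.default_rng(6)
    L = np.exp(rng.uniform(np.log(50), np.log(280), 5000))
    W = 2e-5 * L**2.9 * np.exp(rng.normal(0, 0.3, L.size))
    df = make_std(L, W)
    ls = tb.fit_power_law(df, weighting="NONE")
    med = tb.fit_power_quantile(df, 0.5, start=ls)
    grid = np.linspace(60, 270, 20)
    assert np.all(tb.predict_weight(med, grid) < tb.predict_weight(ls, grid))


def test_quantile_predictions_monotone_in_tau():
    rng = np.random.default_rng(14)
    L = np.exp(rng.uniform(np.log(50), np.log(280), 4000))
    W = 2.5e-5 * L**2.9 * np.exp(rng.normal(0, 0.15, L.size))
    df = make_std(L, W)
    start = tb.fit_power_law(df, weighting="NONE")
    grid = np.linspace(60, 270, 15)
    prev = None
    for tau in (0.025, 0.25, 0.5, 0.75, 0.975):
        pred = tb.predict_weight(tb.fit_power_quantile(df, tau, start=start),
                                 grid)
        if prev is not None:
            assert np.all(pred >= prev * (1 - 1e-9))
        prev = pred


def test_quantile_tau_domain():
    df = make_std(np.linspace(50, 150, 60), np.linspace(5, 60, 60))
    with pytest.raises(ValueError):
        tb.fit_power_quantile(df, 1.2)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_zero_noise_returns_point_estimate_every_replicate():
    L = np.linspace(40, 280, 200)
    df = make_std(L, 2e-5 * L**3.0)
    for scheme, kwargs in (("EQUAL_PROB", {}),
                           ("UNIFORM_PER_BIN", {"m_per_bin": 20})):
        boot = tb.bootstrap_wlr(df, scheme=scheme, B=8, seed=1,
                                weighting="NONE", **kwargs)
        np.testing.assert_allclose(boot.alpha, boot.point.alpha, rtol=1e-6)
        np.testing.assert_allclose(boot.beta, boot.point.beta, rtol=1e-7)


def test_equal_prob_bootstrap_mean_consistent_with_point_estimate():
    rng = np.random.default_rng(8)
    n = 5000
    L = np.exp(rng.uniform(np.log(50), np.log(290), n))
    W = 2e-5 * L**2.95 * np.exp(rng.normal(0, 0.12, n))
    boot = tb.bootstrap_wlr(make_std(L, W), scheme="EQUAL_PROB", B=200,
                            seed=99, weighting="INV_CV")
    mc_se = boot.beta.std(ddof=1) / np.sqrt(boot.B)
    assert abs(boot.beta.mean() - boot.point.beta) < 2 * mc_se


def test_uniform_per_bin_degrades_large_fish_fit():
    """Forcing equal bin occupancy shifts influence from the abundant large
    fish toward sparse smaller-fish bins; when the sub-adults deviate from
    the adult allometry the balanced-composition fit serves the largest
    fish worse, and the replicate-sample error grows."""
    seed = 3
    rng = np.random.default_rng(seed)
    n = 15000
    nm = int(0.2 * n)
    mid = np.exp(rng.uniform(np.log(60), np.log(190), nm))
    big = np.exp(rng.uniform(np.log(190), np.log(298), n - nm))
    L = np.concatenate([mid, big])
    light = np.where(L < 190, 0.94, 1.0)   # sub-adults run lighter
    W = 2e-5 * L**3.0 * light * np.exp(rng.normal(0, 0.08, n))
    df = make_std(L, W)
    eq = tb.bootstrap_wlr(df, scheme="EQUAL_PROB", B=60, seed=seed + 1)
    ub = tb.bootstrap_wlr(df, scheme="UNIFORM_PER_BIN", B=60, seed=seed + 2)
    sel = L >= np.quantile(L, 0.9)

    def top_decile_mar(boot):
        preds = boot.predict(L[sel])
        return float(np.mean(np.abs(W[sel][None, :] - preds)))

    assert top_decile_mar(ub) > top_decile_mar(eq)


def test_uniform_per_bin_requires_occupied_bins():
    df = make_std(np.linspace(320, 380, 40), np.linspace(400, 600, 40))
    with pytest.raises(FitError):
        tb.bootstrap_wlr(df, scheme="UNIFORM_PER_BIN", B=2, seed=0,
                         weighting="NONE")


def test_bootstrap_summary_shape():
    L = np.linspace(40, 280, 100)
    rng = np.random.default_rng(0)
    df = make_std(L, 2e-5 * L**3.0 * np.exp(rng.normal(0, 0.1, L.size)))
    boot = tb.bootstrap_wlr(df, scheme="EQUAL_PROB", B=25, seed=5,
                            weighting="NONE")
    s = boot.summary()
    assert set(s) == {"alpha", "beta", "rmse"}
    assert s["beta"]["ci_2.5"] <= s["beta"]["mean"] <= s["beta"]["ci_97.5"]


# ---------------------------------------------------------------------------
# comparisons


def test_identical_fits_differ_by_zero_percent(east_ref):
    cmp = tb.compare_wlrs(east_ref, east_ref, [60, 110, 200])
    np.testing.assert_allclose(cmp.pct_diff, 0.0)
    assert cmp.mean_abs_pct == 0.0


def test_east_west_percent_differences(east_ref, west_ref):
    # evaluations of the printed coefficients at the sizes where the two
    # stocks' curves are compared
    at110 = tb.compare_wlrs(east_ref, west_ref, [110.0], denominator="B")
    at170 = tb.compare_wlrs(east_ref, west_ref, [170.0], denominator="B")
    assert at110.pct_diff[0] == pytest.approx(11.34, abs=0.02)
    assert at170.pct_diff[0] == pytest.approx(5.54, abs=0.02)


def test_fixed_factor_divergences():
    conv = tb.fixtures.reference_conversion(
        Stock.EAST, Measurement.GGWT, Measurement.RWT)
    assert tb.compare_fixed_factor(conv, 1.13, 239.0) == pytest.approx(
        15.07, abs=0.01)
    assert tb.compare_fixed_factor(conv, 1.16, 239.0) == pytest.approx(
        12.82, abs=0.01)


def test_fixed_factor_identical_models_diverge_zero():
    line = tb.LinearConversion(Measurement.GGWT, Measurement.RWT,
                               alpha=0.0, beta=1.25, x_range=(10, 500))
    for x in (20.0, 100.0, 400.0):
        assert tb.compare_fixed_factor(line, 1.25, x) == 0.0


def test_fixed_factor_warns_outside_fitted_range():
    conv = tb.fixtures.reference_conversion(
        Stock.EAST, Measurement.GGWT, Measurement.RWT)
    with pytest.warns(UserWarning):
        tb.compare_fixed_factor(conv, 1.13, 500.0)
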