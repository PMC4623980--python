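"""Weight-length relationship (WLR) fitting and sensitivity analyses.

The allometric power law ``W = alpha * L^beta`` links round weight (kg) to
straight fork length (cm).  Weight variance grows with length, and for
bluefin the coefficient of variation (CV) of weight at length is itself
size-structured, so the production fit weights each observation by the
inverse of the CV of weight in its 5 cm length bin.  The minimizer is a
Gauss-Newton iteration started at the log-log OLS estimate.

Sensitivity tools: nonlinear quantile regression (pinball loss), two
nonparametric bootstrap schemes (equal-probability resampling, and a
uniform number of draws per 5 cm bin), and utilities to compare fitted
curves against each other or against fixed multiplicative conversion
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError
from .standardize import LinearConversion

BIN_WIDTH_CM = 5.0
UNIFORM_BIN_RANGE = (30.0, 300.0)


# ---------------------------------------------------------------------------
# binned CV of weight at length


@dataclass(frozen=True)
class BinCV:
    """Weight statistics in one half-open length bin [lower, lower+width).

    ``flagged`` marks bins too sparse (n below the minimum count) or with an
    undefined CV; flagged bins are imputed with the profile-wide mean CV
    when used for weighting.
    """

    bin_lower: float
    n: int
    mean_w: float
    sd_w: float
    cv: float
    flagged: bool


def _extract(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    for col in ("sfl_std", "rwt_std"):
        if col not in records.columns:
            raise FitError(f"records lack required column {col!r}")
    L = records["sfl_std"].to_numpy(dtype=float)
    W = records["rwt_std"].to_numpy(dtype=float)
    ok = np.isfinite(L) & np.isfinite(W)
    L, W = L[ok], W[ok]
    if np.any(L <= 0) or np.any(W <= 0):
        raise FitError("lengths and weights must be strictly positive")
    return L, W


def bin_cv_profile(
    records: pd.DataFrame,
    bin_width: float = BIN_WIDTH_CM,
    min_count: int = 10,
) -> list[BinCV]:
    """Sample mean, SD (n-1 denominator) and CV of weight per length bin.

    Bins span the observed length range contiguously; empty or sparse bins
    are flagged.  Returns an empty list for empty input.
    """
    if len(records) == 0:
        return []
    L, W = _extract(records)
    if L.size == 0:
        return []
    idx = np.floor(L / bin_width).astype(np.int64)
    out: list[BinCV] = []
    for k in range(int(idx.min()), int(idx.max()) + 1):
        sel = idx == k
        n = int(sel.sum())
        if n == 0:
            out.append(BinCV(k * bin_width, 0, np.nan, np.nan, np.nan, True))
            continue
        mean = float(W[sel].mean())
        sd = float(W[sel].std(ddof=1)) if n >= 2 else np.nan
        cv = sd / mean if n >= 2 and mean > 0 else np.nan
        out.append(BinCV(k * bin_width, n, mean, sd, cv,
                         flagged=n < min_count or not np.isfinite(cv)))
    return out


def _weights_from_bins(
    bins: Sequence[BinCV],
    L: np.ndarray,
    bin_width: float,
    cv_power: float,
) -> np.ndarray:
    """Per-observation weights 1/CV^cv_power with sparse-bin imputation.

    Flagged (or zero-CV) bins take the mean CV of the reliable bins; if no
    reliable positive CV exists the fit degenerates to equal weights.
    """
    cv_by_lower = {b.bin_lower: b for b in bins}
    good = [b.cv for b in bins if not b.flagged and np.isfinite(b.cv) and b.cv > 0]
    mean_cv = float(np.mean(good)) if good else np.nan
    if not np.isfinite(mean_cv) or mean_cv <= 0:
        return np.ones_like(L)
    lowers = np.floor(L / bin_width) * bin_width
    cv = np.full(L.shape, mean_cv)
    for i, lo in enumerate(lowers):
        b = cv_by_lower.get(lo)
        if b is not None and not b.flagged and np.isfinite(b.cv) and b.cv > 0:
            cv[i] = b.cv
    return cv ** (-cv_power)


# ---------------------------------------------------------------------------
# Gauss-Newton power-law fit


@dataclass
class PowerLawFit:
    """Fitted allometric relation ``W = alpha * L^beta`` with diagnostics.

    ``residual_se``, ``rmse`` and ``aic`` are computed on the unweighted
    residuals; ``param_cov`` is the (alpha, beta) covariance from the
    weighted normal equations at the optimum.
    """

    alpha: float
    beta: float
    weighting: str = "INV_CV"
    n: int | None = None
    residual_se: float | None = None
    aic: float | None = None
    rmse: float | None = None
    param_cov: np.ndarray | None = None
    converged: bool = True
    iterations: int = 0

    def predict(self, sfl):
        return predict_weight(self, sfl)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta,
            "weighting": self.weighting, "n": self.n,
            "residual_se": self.residual_se, "aic": self.aic,
            "rmse": self.rmse,
            "param_cov": None if self.param_cov is None
            else np.asarray(self.param_cov).tolist(),
            "converged": self.converged, "iterations": self.iterations,
        }


def _loglog_start(L: np.ndarray, W: np.ndarray) -> tuple[float, float]:
    b, a = np.polyfit(np.log(L), np.log(W), 1)
    return float(np.exp(a)), float(b)


def _gauss_newton(L, W, w, alpha0, beta0, tol, max_iter):
    """Weighted Gauss-Newton for W ~ alpha * L^beta with step halving."""
    logL = np.log(L)
    sw = np.sqrt(w)

    def sse(a, b):
        return float(np.sum(w * (W - a * np.power(L, b)) ** 2))

    a, b = alpha0, beta0
    cur = sse(a, b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = a * np.power(L, b)
        r = W - f
        J = np.column_stack(((f / a) * sw, f * logL * sw))
        try:
            delta, *_ = np.linalg.lstsq(J, r * sw, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            break
        step = 1.0
        new = np.inf
        while step >= 1.0 / 1024:
            na, nb = a + step * delta[0], b + step * delta[1]
            if na > 0:
                new = sse(na, nb)
                if new <= cur:
                    break
            step /= 2
        if not np.isfinite(new) or new > cur:
            converged = True  # no descent direction left: at the optimum
            break
        a, b = a + step * delta[0], b + step * delta[1]
        if cur - new <= tol * max(cur, np.finfo(float).tiny):
            cur = new
            converged = True
            break
        cur = new
    return a, b, converged, it


def fit_power_law(
    records: pd.DataFrame,
    weighting: str = "INV_CV",
    bins: Sequence[BinCV] | None = None,
    cv_power: float = 1.0,
    bin_width: float = BIN_WIDTH_CM,
    min_count: int = 10,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PowerLawFit:
    """Fit ``W = alpha * L^beta`` by (weighted) Gauss-Newton.

    ``weighting="INV_CV"`` weights each observation by the inverse CV of
    weight in its length bin (``cv_power=2.0`` switches to inverse squared
    CV); ``"NONE"`` is ordinary nonlinear least squares.  The iteration
    starts at the log-log OLS estimate and stops when the relative change
    in weighted SSE drops below ``tol``.
    """
    if weighting not in ("NONE", "INV_CV"):
        raise ValueError(f"unknown weighting {weighting!r}")
    L, W = _extract(records)
    n = L.size
    if n < 10:
        raise FitError(f"need at least 10 records, got {n}")
    if np.unique(np.floor(L / bin_width)).size < 3:
        raise FitError("records must span at least 3 length bins")

    if weighting == "INV_CV":
        if bins is None:
            bins = bin_cv_profile(records, bin_width, min_count)
        w = _weights_from_bins(bins, L, bin_width, cv_power)
    else:
        w = np.ones(n)

    alpha0, beta0 = _loglog_start(L, W)
    alpha, beta, converged, iters = _gauss_newton(
        L, W, w, alpha0, beta0, tol, max_iter
    )
    if not converged:
        raise FitError(
            f"Gauss-Newton did not converge in {max_iter} iterations"
        )

    f = alpha * np.power(L, beta)
    resid = W - f
    sse = float(np.sum(resid**2))
    k = 3  # alpha, beta, residual variance
    aic = n * np.log(2 * np.pi * max(sse, np.finfo(float).tiny) / n) \
        + n + 2 * k
    sw = np.sqrt(w)
    J = np.column_stack((np.power(L, beta) * sw, f * np.log(L) * sw))
    wsse = float(np.sum(w * resid**2))
    try:
        cov = wsse / (n - 2) * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = None
    return PowerLawFit(
        alpha=float(alpha), beta=float(beta), weighting=weighting, n=n,
        residual_se=float(np.sqrt(sse / (n - 2))), aic=float(aic),
        rmse=float(np.sqrt(sse / n)), param_cov=cov,
        converged=converged, iterations=iters,
    )


def predict_weight(fit, sfl):
    """Predicted round weight (kg) at ``sfl`` (cm) for a power-law fit or
    any object with ``alpha``/``beta`` attributes."""
    sfl_arr = np.asarray(sfl, dtype=float)
    if np.any(sfl_arr <= 0):
        raise ValueError("sfl must be strictly positive")
    out = fit.alpha * np.power(sfl_arr, fit.beta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# quantile regression


@dataclass(frozen=True)
class QuantileFit:
    """Power-law conditional quantile: minimizer of the pinball loss."""

    tau: float
    alpha: float
    beta: float
    pinball_loss: float


def _pinball(u: np.ndarray, tau: float) -> float:
    return float(np.sum(u * (tau - (u < 0))))


def fit_power_quantile(
    records: pd.DataFrame,
    tau: float,
    start: PowerLawFit | None = None,
) -> QuantileFit:
    """Fit the tau-th conditional quantile curve ``alpha * L^beta``.

    The pinball objective is non-smooth, so it is minimized by Nelder-Mead
    in (log alpha, beta) space, started from the least-squares fit and
    restarted once from its own solution.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    L, W = _extract(records)
    if L.size < 50:
        raise FitError(f"need at least 50 records, got {L.size}")
    if start is None:
        start = fit_power_law(records, weighting="NONE")

    def loss(theta):
        return _pinball(W - np.exp(theta[0]) * np.power(L, theta[1]), tau)

    x0 = np.array([np.log(start.alpha), start.beta])
    for _ in range(2):  # one restart to escape simplex stalls
        res = optimize.minimize(
            loss, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8,
                     "maxiter": 5000, "maxfev": 5000},
        )
        x0 = res.x
    return QuantileFit(
        tau=tau, alpha=float(np.exp(res.x[0])), beta=float(res.x[1]),
        pinball_loss=float(res.fun),
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Replicated power-law fits under a resampling scheme.

    ``EQUAL_PROB`` resamples n observations from n with replacement;
    ``UNIFORM_PER_BIN`` draws the same number from every occupied 5 cm bin
    in [30, 300) cm, emulating a balanced size composition.
    """

    scheme: str
    B: int
    weighting: str
    seed: int | None
    point: PowerLawFit
    alpha: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    rmse: np.ndarray = field(repr=False)

    def predict(self, grid) -> np.ndarray:
        """(B, len(grid)) matrix of replicate-predicted weights."""
        grid = np.asarray(grid, dtype=float)
        if np.any(grid <= 0):
            raise ValueError("grid lengths must be positive")
        return self.alpha[:, None] * np.power(grid[None, :],
                                              self.beta[:, None])

    def summary(self) -> dict:
        out = {}
        for name, vals, point in (
            ("alpha", self.alpha, self.point.alpha),
            ("beta", self.beta, self.point.beta),
            ("rmse", self.rmse, self.point.rmse),
        ):
            out[name] = {
                "mean": float(np.mean(vals)),
                "bias": float(np.mean(vals) - point),
                "ci_2.5": float(np.percentile(vals, 2.5)),
                "ci_97.5": float(np.percentile(vals, 97.5)),
                "skewness": float(stats.skew(vals)),
            }
        return out


def bootstrap_wlr(
    records: pd.DataFrame,
    scheme: str = "EQUAL_PROB",
    B: int = 1000,
    seed: int | None = None,
    weighting: str = "INV_CV",
    m_per_bin: int = 100,
    bin_range: tuple[float, float] = UNIFORM_BIN_RANGE,
    bin_width: float = BIN_WIDTH_CM,
    cv_power: float = 1.0,
    min_count: int = 10,
) -> BootstrapResult:
    """Bootstrap the power-law fit under one of two resampling schemes.

    Each replicate is refitted exactly as the point estimate (including
    recomputing the bin CV weights on the replicate sample).
    """
    if scheme not in ("EQUAL_PROB", "UNIFORM_PER_BIN"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if B < 1:
        raise ValueError("B must be at least 1")
    point = fit_power_law(records, weighting=weighting, cv_power=cv_power,
                          bin_width=bin_width, min_count=min_count)
    L, W = _extract(records)
    n = L.size
    rng = np.random.default_rng(seed)

    if scheme == "UNIFORM_PER_BIN":
        lo, hi = bin_range
        lowers = np.arange(lo, hi, bin_width)
        members = []
        for b_lo in lowers:
            idx = np.flatnonzero((L >= b_lo) & (L < b_lo + bin_width))
            if idx.size:
                members.append(idx)
        if not members:
            raise FitError(
                f"no occupied {bin_width:g} cm bins in [{lo:g}, {hi:g})"
            )

    df = pd.DataFrame({"sfl_std": L, "rwt_std": W})
    alphas = np.empty(B)
    betas = np.empty(B)
    rmses = np.empty(B)
    for r in range(B):
        if scheme == "EQUAL_PROB":
            take = rng.integers(0, n, size=n)
        else:
            take = np.concatenate(
                [idx[rng.integers(0, idx.size, size=m_per_bin)]
                 for idx in members]
            )
        rep = df.iloc[take]
        fit = fit_power_law(rep, weighting=weighting, cv_power=cv_power,
                            bin_width=bin_width, min_count=min_count)
        alphas[r], betas[r], rmses[r] = fit.alpha, fit.beta, fit.rmse
    return BootstrapResult(
        scheme=scheme, B=B, weighting=weighting, seed=seed, point=point,
        alpha=alphas, beta=betas, rmse=rmses,
    )


# ---------------------------------------------------------------------------
# comparisons


@dataclass(frozen=True)
class WLRComparison:
    """Per-length percent weight differences between two fitted curves."""

    grid: np.ndarray
    pct_diff: np.ndarray
    mean_abs_pct: float


def compare_wlrs(
    fit_a, fit_b, grid: Sequence[float], denominator: str = "B"
) -> WLRComparison:
    """Percent difference ``100 * (W_a - W_b) / W_denom`` over a length grid.

    The summary is the mean absolute percent difference across the grid.
    """
    if denominator not in ("A", "B"):
        raise ValueError("denominator must be 'A' or 'B'")
    grid = np.asarray(grid, dtype=float)
    wa = predict_weight(fit_a, grid)
    wb = predict_weight(fit_b, grid)
    denom = wa if denominator == "A" else wb
    pct = 100.0 * (wa - wb) / denom
    return WLRComparison(grid=grid, pct_diff=pct,
                         mean_abs_pct=float(np.mean(np.abs(pct))))


def compare_fixed_factor(linear: LinearConversion, factor: float, x):
    """Percent divergence of a fixed multiplicative conversion factor from a
    fitted linear conversion, ``100 * |linear(x) - factor*x| / linear(x)``.

    Values of ``x`` outside the conversion's fitted range are still
    evaluated but trigger a warning (extrapolation).
    """
    x_arr = np.asarray(x, dtype=float)
    if linear.x_range is not None:
        lo, hi = linear.x_range
        if np.any(x_arr < lo) or np.any(x_arr > hi):
            warnings.warn(
                f"x outside the fitted range [{lo:g}, {hi:g}] of "
                f"{linear.x_type.value}->{linear.y_type.value}; "
                "extrapolating", stacklevel=2,
            )
    pred = linear.alpha + linear.beta * x_arr
    out = 100.0 * np.abs(pred - factor * x_arr) / pred
    return float(out) if out.ndim == 0 else out
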