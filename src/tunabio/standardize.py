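"""Measurement standardization.

Fishery sampling programmes record whichever length and weight type is
practical dockside, so a pooled dataset mixes curved fork lengths, gutted
weights, dressed weights and so on.  This module fits the pairwise
length-length (LLR) and weight-weight (WWR) conversions by robust linear
regression and uses the high-confidence ones (r² at or above a gate,
0.98 by default) to express every record in the two standard units:
straight fork length ``sfl_std`` (cm) and round weight ``rwt_std`` (kg).

Conversions that fail the gate are fitted and reported but never applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, SchemaError
from .types import COLUMN_FOR, Measurement, Stock

logger = logging.getLogger(__name__)

#: r² threshold above which a fitted conversion may be used to standardize.
DEFAULT_GATE = 0.98

#: Tukey bisquare tuning constant for the robust linear fit.
BISQUARE_TUNING = 4.685

#: Conversion priority for obtaining rwt_std when RWT is not measured.
#: The less-processed weight state (closer to round weight) is tried first.
RWT_PRIORITY: dict[Stock, tuple[Measurement, ...]] = {
    Stock.EAST: (Measurement.GWT, Measurement.GGWT),
    Stock.WEST: (Measurement.DWT,),
}

#: Length conversion priority for obtaining sfl_std.
SFL_PRIORITY: tuple[Measurement, ...] = (Measurement.CFL,)

#: Pairs fitted by default when calibration data are available.
DEFAULT_PAIRS: tuple[tuple[Measurement, Measurement], ...] = (
    (Measurement.CFL, Measurement.SFL),
    (Measurement.SFL, Measurement.CFL),
    (Measurement.GWT, Measurement.RWT),
    (Measurement.RWT, Measurement.GWT),
    (Measurement.GGWT, Measurement.RWT),
    (Measurement.RWT, Measurement.GGWT),
    (Measurement.DWT, Measurement.RWT),
    (Measurement.RWT, Measurement.DWT),
)


@dataclass(frozen=True)
class LinearConversion:
    """A fitted linear relation ``y = alpha + beta * x`` between two
    measurement types, with fit diagnostics."""

    x_type: Measurement
    y_type: Measurement
    alpha: float
    beta: float
    r2: float | None = None
    residual_se: float | None = None
    n: int | None = None
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    method: str = "ROBUST"

    def predict(self, x):
        """Evaluate the conversion at ``x`` (scalar or array)."""
        out = self.alpha + self.beta * np.asarray(x, dtype=float)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "x_type": self.x_type.value, "y_type": self.y_type.value,
            "alpha": self.alpha, "beta": self.beta, "r2": self.r2,
            "residual_se": self.residual_se, "n": self.n,
            "x_range": list(self.x_range) if self.x_range else None,
            "y_range": list(self.y_range) if self.y_range else None,
            "method": self.method,
        }


def fit_linear_conversion(
    x: Sequence[float],
    y: Sequence[float],
    x_type: Measurement = Measurement.SFL,
    y_type: Measurement = Measurement.SFL,
    method: str = "ROBUST",
) -> LinearConversion:
    """Fit ``y = alpha + beta * x``.

    ``method="ROBUST"`` uses iteratively reweighted least squares with the
    Tukey bisquare influence function (tuning 4.685), started from the OLS
    solution and iterated to coefficient convergence (tol 1e-8, at most 50
    iterations).  ``method="OLS"`` is plain least squares.

    r² is reported as the squared Pearson correlation between observed and
    fitted values, and ``residual_se`` as sqrt(SSE / (n - 2)) on the
    unweighted residuals of the final coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise FitError(f"need at least 3 (x, y) pairs, got {n}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise FitError("measurements must be strictly positive")
    if np.ptp(x) == 0:
        raise FitError("zero variance in x: conversion is not identifiable")
    if method not in ("ROBUST", "OLS"):
        raise ValueError(f"unknown method {method!r}")

    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    coefs = ols.params
    sse_ols = float(np.sum((y - X @ coefs) ** 2))
    if method == "ROBUST" and sse_ols > 1e-12 * max(1.0, float(np.sum(y**2))):
        rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
        coefs = rlm.fit(maxiter=50, tol=1e-8, conv="coefs").params
    # exactly collinear data keep the OLS coefficients (the robust scale
    # estimate is degenerate there)

    fitted = X @ coefs
    resid = y - fitted
    sse = float(np.sum(resid**2))
    if np.ptp(fitted) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    return LinearConversion(
        x_type=x_type, y_type=y_type,
        alpha=float(coefs[0]), beta=float(coefs[1]),
        r2=min(1.0, r2),
        residual_se=float(np.sqrt(sse / (n - 2))),
        n=int(n),
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
        method=method,
    )


def fit_conversions(
    records: pd.DataFrame,
    pairs: Iterable[tuple[Measurement, Measurement]] = DEFAULT_PAIRS,
    method: str = "ROBUST",
    min_n: int = 3,
) -> list[LinearConversion]:
    """Fit every conversion in ``pairs`` for which the records contain at
    least ``min_n`` complete (x, y) observations on the same fish."""
    out: list[LinearConversion] = []
    for x_t, y_t in pairs:
        cx, cy = COLUMN_FOR[x_t], COLUMN_FOR[y_t]
        if cx not in records.columns or cy not in records.columns:
            continue
        sub = records[[cx, cy]].dropna()
        if len(sub) < max(min_n, 3):
            continue
        try:
            out.append(
                fit_linear_conversion(sub[cx], sub[cy], x_t, y_t, method)
            )
        except FitError as err:
            logger.warning("conversion %s->%s not fitted: %s",
                           x_t.value, y_t.value, err)
    return out


def _gated(conv_map, x_t, y_t, gate):
    conv = conv_map.get((x_t, y_t))
    if conv is None:
        return None
    if conv.r2 is None or conv.r2 < gate:
        logger.info(
            "conversion %s->%s refused: r2=%s below gate %.3f",
            x_t.value, y_t.value, conv.r2, gate,
        )
        return None
    return conv


def standardize_records(
    records: pd.DataFrame,
    conversions: Iterable[LinearConversion],
    gate: float = DEFAULT_GATE,
    outlier_filter: bool = False,
) -> pd.DataFrame:
    """Standardize mixed-type fish records to ``sfl_std`` / ``rwt_std``.

    Measured SFL and RWT pass through unchanged.  Otherwise SFL is derived
    from CFL and RWT from the stock's processed-weight priority order, each
    only through a conversion whose r² meets the gate.  Records yielding
    neither value are dropped (they remain usable for conversion fitting
    from the raw table).  The provenance of each standardized value is
    recorded in ``sfl_source`` / ``rwt_source``.

    With ``outlier_filter=True``, records carrying both sides of a gated
    conversion whose observed pair deviates from the fitted line by more
    than 5 residual SEs are dropped (off by default: outliers are otherwise
    left to the robust fit's downweighting).
    """
    required = {"fish_id", "stock", "month"}
    missing = required - set(records.columns)
    if missing:
        raise SchemaError(f"records are missing columns: {sorted(missing)}")
    stocks = set(records["stock"].dropna().unique())
    if len(stocks) > 1:
        raise SchemaError(
            f"standardize one stock at a time, got {sorted(stocks)}"
        )
    stock = Stock(next(iter(stocks))) if stocks else Stock.EAST

    conv_map = {(c.x_type, c.y_type): c for c in conversions}
    n = len(records)
    out = records.copy()

    if outlier_filter:
        keep = np.ones(n, dtype=bool)
        for (x_t, y_t), conv in conv_map.items():
            if conv.r2 is None or conv.r2 < gate or not conv.residual_se:
                continue
            cx, cy = COLUMN_FOR[x_t], COLUMN_FOR[y_t]
            if cx not in out.columns or cy not in out.columns:
                continue
            both = out[cx].notna() & out[cy].notna()
            dev = np.abs(out[cy] - conv.predict(out[cx].to_numpy()))
            flagged = both & (dev > 5 * conv.residual_se)
            keep &= ~flagged.to_numpy()
        dropped = int(n - keep.sum())
        if dropped:
            logger.info("outlier pre-filter dropped %d records", dropped)
        out = out[keep].copy()
        n = len(out)

    def column(m: Measurement) -> np.ndarray:
        col = COLUMN_FOR[m]
        if col in out.columns:
            return out[col].to_numpy(dtype=float)
        return np.full(n, np.nan)

    sfl = column(Measurement.SFL).copy()
    sfl_source = np.where(np.isfinite(sfl), "MEASURED", "").astype(object)
    for src in SFL_PRIORITY:
        conv = _gated(conv_map, src, Measurement.SFL, gate)
        if conv is None:
            continue
        vals = column(src)
        use = ~np.isfinite(sfl) & np.isfinite(vals)
        sfl[use] = conv.predict(vals[use])
        sfl_source[use] = f"CONVERTED({src.value})"

    rwt = column(Measurement.RWT).copy()
    rwt_source = np.where(np.isfinite(rwt), "MEASURED", "").astype(object)
    for src in RWT_PRIORITY[stock]:
        conv = _gated(conv_map, src, Measurement.RWT, gate)
        if conv is None:
            continue
        vals = column(src)
        use = ~np.isfinite(rwt) & np.isfinite(vals)
        rwt[use] = conv.predict(vals[use])
        rwt_source[use] = f"CONVERTED({src.value})"

    # converted values must stay physically meaningful
    sfl = np.where(np.isfinite(sfl) & (sfl <= 0), np.nan, sfl)
    rwt = np.where(np.isfinite(rwt) & (rwt <= 0), np.nan, rwt)

    keep_cols = [c for c in ("fish_id", "stock", "area", "gear", "year",
                             "month", *("age", "sfl_true", "rwt_true"))
                 if c in out.columns]
    std = out[keep_cols].copy()
    std["sfl_std"] = sfl
    std["rwt_std"] = rwt
    std["sfl_source"] = np.where(np.isfinite(sfl), sfl_source, "")
    std["rwt_source"] = np.where(np.isfinite(rwt), rwt_source, "")

    neither = ~(np.isfinite(sfl) | np.isfinite(rwt))
    if neither.any():
        logger.info(
            "%d records had neither an obtainable sfl_std nor rwt_std and "
            "were dropped from the standardized table", int(neither.sum()),
        )
    return std[~neither].reset_index(drop=True)


def wlr_input(standardized: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for weight-length fitting: both standardized values
    present and positive."""
    ok = (
        standardized["sfl_std"].notna() & standardized["rwt_std"].notna()
        & (standardized["sfl_std"] > 0) & (standardized["rwt_std"] > 0)
    )
    return standardized[ok].reset_index(drop=True)
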