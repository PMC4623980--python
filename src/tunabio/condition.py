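"""Seasonal condition analysis.

Fish condition is measured as the scaled departure of observed from
predicted weight at length, ``(obs - pred) / pred``, against the annual
CV-weighted weight-length fit.  Scaled residuals above 1 (observed more
than double the prediction) are excluded as implausible.  The retained
residuals are modelled by an ordinary linear model with length as a
continuous predictor and month, maturity and broad geographic area as
effects-coded fixed factors.  Monthly least-squares means (balanced-grid
averages, robust to unbalanced sampling) feed a monthly weight-length
table in which the month enters as an additive perturbation of the
exponent:

    W_m = alpha * L ^ (beta + LSMean_m * MSE)

with MSE the residual mean square of the condition model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import FitError, SchemaError
from .types import AREA_GROUP, MATURITY_THRESHOLD_CM, Maturity, Stock
from .wlr import PowerLawFit, predict_weight

logger = logging.getLogger(__name__)

#: Scaled residuals above this are excluded (strictly greater; 1 is kept).
EXCLUSION_THRESHOLD = 1.0


def scaled_residuals(
    records: pd.DataFrame,
    fit: PowerLawFit,
    maturity_thresholds: dict[Stock, float] | None = None,
    area_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Scaled residuals with condition-model factor assignments.

    Input rows need ``sfl_std`` and ``rwt_std``; rows lacking either are
    skipped (logged).  Maturity is assigned by the stock's size threshold
    (at or above is MATURE) and areas are mapped to broad groups.
    """
    maturity_thresholds = maturity_thresholds or MATURITY_THRESHOLD_CM
    area_groups = area_groups if area_groups is not None else AREA_GROUP
    for col in ("stock", "month", "sfl_std", "rwt_std"):
        if col not in records.columns:
            raise SchemaError(f"records lack required column {col!r}")

    ok = records["sfl_std"].notna() & records["rwt_std"].notna()
    skipped = int((~ok).sum())
    if skipped:
        logger.info("skipping %d records without both standardized values",
                    skipped)
    df = records[ok].reset_index(drop=True)

    pred = predict_weight(fit, df["sfl_std"].to_numpy())
    value = (df["rwt_std"].to_numpy() - pred) / pred
    thr = df["stock"].map(
        lambda s: maturity_thresholds[Stock(s)]
    ).to_numpy(dtype=float)
    maturity = np.where(df["sfl_std"].to_numpy() >= thr,
                        Maturity.MATURE.value, Maturity.IMMATURE.value)
    if "area" in df.columns:
        group = df["area"].map(area_groups)
    else:
        group = pd.Series(pd.NA, index=df.index)

    out = pd.DataFrame({
        "fish_id": df["fish_id"] if "fish_id" in df.columns
        else np.arange(len(df)),
        "sfl_std": df["sfl_std"].to_numpy(),
        "month": df["month"].astype(int).to_numpy(),
        "year": df["year"].astype(int).to_numpy()
        if "year" in df.columns else pd.NA,
        "maturity": maturity,
        "area_group": group.to_numpy(),
        "value": value,
        "excluded": value > EXCLUSION_THRESHOLD,
    })
    n_excl = int(out["excluded"].sum())
    if n_excl:
        logger.info("flagged %d scaled residuals > %g for exclusion "
                    "(%.2f%% of retained rows)", n_excl,
                    EXCLUSION_THRESHOLD, 100 * n_excl / max(len(out), 1))
    return out


@dataclass
class ConditionModel:
    """Fitted condition linear model (effects-coded factors).

    ``deviance`` maps each model term to its Type III sum of squares;
    ``mse`` is the residual mean square used to scale LSMeans into
    exponent perturbations.
    """

    result: object  # statsmodels RegressionResults
    factors: tuple[str, ...]
    include_sfl: bool
    sfl_mean: float
    levels: dict[str, list]
    mse: float
    deviance: dict[str, float]
    n: int

    @property
    def coefficients(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.result.params.items()}


def fit_condition_model(
    residuals: pd.DataFrame,
    factors: tuple[str, ...] = ("month", "maturity", "area_group"),
    include_sfl: bool = True,
    include_year: bool = False,
) -> ConditionModel:
    """OLS on retained scaled residuals with sum-to-zero factor coding.

    Excluded residuals are removed first.  Each requested factor must have
    at least two observed levels; the error names any factor (or empty
    level) that makes the model inestimable.  ``include_year`` adds a year
    factor for the month-vs-year deviance diagnostic; it is not part of the
    final monthly model.
    """
    df = residuals.loc[~residuals["excluded"]].copy()
    if include_year:
        factors = tuple(factors) + ("year",)
    terms = []
    levels: dict[str, list] = {}
    for f in factors:
        if f not in df.columns:
            raise SchemaError(f"residuals lack factor column {f!r}")
        df = df[df[f].notna()]
    if len(df) == 0:
        raise FitError("no retained residuals to fit")
    for f in factors:
        obs = sorted(df[f].unique().tolist())
        if len(obs) < 2:
            raise FitError(
                f"factor {f!r} has fewer than 2 observed levels: {obs}"
            )
        levels[f] = obs
        terms.append(f"C({f}, Sum)")
    if include_sfl:
        terms.insert(0, "sfl_std")
    formula = "value ~ " + " + ".join(terms) if terms else "value ~ 1"
    res = smf.ols(formula, data=df).fit()
    if np.isnan(res.params).any():
        bad = [k for k, v in res.params.items() if np.isnan(v)]
        raise FitError(f"inestimable coefficients (empty cells): {bad}")

    aov = anova_lm(res, typ=3)
    deviance = {}
    for f in factors:
        deviance[f] = float(aov.loc[f"C({f}, Sum)", "sum_sq"])
    if include_sfl:
        deviance["sfl_std"] = float(aov.loc["sfl_std", "sum_sq"])
    return ConditionModel(
        result=res,
        factors=tuple(f for f in factors),
        include_sfl=include_sfl,
        sfl_mean=float(df["sfl_std"].mean()) if include_sfl else np.nan,
        levels=levels,
        mse=float(res.mse_resid),
        deviance=deviance,
        n=int(len(df)),
    )


def lsmeans_month(
    model: ConditionModel,
    months: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Least-squares mean scaled residual per month, centered to mean 0.

    The LSMean for a month is the model prediction averaged over a balanced
    grid of every other factor's levels, with length fixed at its overall
    mean.  ``months`` defaults to the observed month levels; requesting an
    unobserved month raises an error naming it.
    """
    if "month" not in model.factors:
        raise FitError("the condition model has no month factor")
    observed = model.levels["month"]
    if months is None:
        months = tuple(observed)
    missing = [m for m in months if m not in observed]
    if missing:
        raise FitError(f"no observations for month(s) {missing}: "
                       "LSMeans are inestimable there")

    others = [f for f in model.factors if f != "month"]
    combos = list(itertools.product(*(model.levels[f] for f in others)))
    rows = []
    for m in months:
        for combo in combos:
            row = {"month": m}
            row.update(dict(zip(others, combo)))
            if model.include_sfl:
                row["sfl_std"] = model.sfl_mean
            rows.append(row)
    grid = pd.DataFrame(rows)
    pred = np.asarray(model.result.predict(grid), dtype=float)
    means = pred.reshape(len(months), max(len(combos), 1)).mean(axis=1)
    return means - means.mean()


@dataclass
class MonthlyWLR:
    """Monthly weight-length coefficients: shared alpha, one exponent per
    calendar month (January..December)."""

    alpha: float
    beta_by_month: np.ndarray

    def __post_init__(self):
        self.beta_by_month = np.asarray(self.beta_by_month, dtype=float)
        if self.beta_by_month.size != 12:
            raise SchemaError("beta_by_month must hold 12 exponents")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": np.arange(1, 13),
            "alpha": self.alpha,
            "beta": self.beta_by_month,
        })


def monthly_wlr_table(
    annual: PowerLawFit,
    lsmeans: np.ndarray,
    mse: float,
    exponent_scale: str = "mse",
) -> MonthlyWLR:
    """Monthly exponents ``beta_m = beta + LSMean_m * MSE``.

    ``exponent_scale="rmse"`` scales by the root mean square error instead
    (the additive-perturbation equation is ambiguous about which is meant;
    the mean square is the literal reading and the default).
    """
    lsmeans = np.asarray(lsmeans, dtype=float)
    if lsmeans.size != 12:
        raise SchemaError(f"need 12 monthly LSMeans, got {lsmeans.size}")
    if exponent_scale == "mse":
        scale = mse
    elif exponent_scale == "rmse":
        scale = float(np.sqrt(mse))
    else:
        raise ValueError(f"unknown exponent_scale {exponent_scale!r}")
    return MonthlyWLR(alpha=annual.alpha,
                      beta_by_month=annual.beta + lsmeans * scale)


def predict_monthly_weight(monthly: MonthlyWLR, sfl, month: int):
    """Predicted round weight (kg) at length for a calendar month."""
    if not (isinstance(month, (int, np.integer)) and 1 <= month <= 12):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    sfl_arr = np.asarray(sfl, dtype=float)
    if np.any(sfl_arr <= 0):
        raise ValueError("sfl must be strictly positive")
    out = monthly.alpha * np.power(sfl_arr, monthly.beta_by_month[month - 1])
    return float(out) if out.ndim == 0 else out
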