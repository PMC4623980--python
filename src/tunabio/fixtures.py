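"""Packaged reference coefficients.

The published biometric tables for both stocks ship with the package as
JSON fixtures: the robust linear length-length and weight-weight
conversions, the annual power-law weight-length fits, and the monthly
weight-length coefficient table.  These are evaluation references and
generator defaults; nothing in the fitting code depends on them.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .condition import MonthlyWLR
from .standardize import LinearConversion
from .types import Measurement, Stock
from .wlr import PowerLawFit

_FILES = {Stock.EAST: "east_biometrics.json",
          Stock.WEST: "west_biometrics.json"}


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    path = resources.files("tunabio").joinpath("fixtures", name)
    return json.loads(path.read_text())


def reference_conversions(stock: Stock) -> list[LinearConversion]:
    """All published linear conversions (LLR and WWR) for a stock."""
    rows = _load(_FILES[Stock(stock)])["linear"]
    return [
        LinearConversion(
            x_type=Measurement(r["x"]), y_type=Measurement(r["y"]),
            alpha=r["alpha"], beta=r["beta"], r2=r["r2"],
            residual_se=r["residual_se"], n=r["n"],
            x_range=tuple(r["x_range"]), y_range=tuple(r["y_range"]),
            method="ROBUST",
        )
        for r in rows
    ]


def reference_conversion(
    stock: Stock, x_type: Measurement, y_type: Measurement
) -> LinearConversion:
    for conv in reference_conversions(stock):
        if conv.x_type == x_type and conv.y_type == y_type:
            return conv
    raise KeyError(f"no published {x_type.value}->{y_type.value} "
                   f"conversion for {Stock(stock).value}")


def reference_wlr(stock: Stock) -> PowerLawFit:
    """The published annual CV-weighted standardized weight-length fit."""
    rows = _load(_FILES[Stock(stock)])["power"]
    for r in rows:
        if r.get("standardized"):
            return PowerLawFit(
                alpha=r["alpha"], beta=r["beta"], weighting="INV_CV",
                n=r["n"], residual_se=r["residual_se"], converged=True,
            )
    raise KeyError(f"no standardized WLR row for {Stock(stock).value}")


def reference_power_laws(stock: Stock) -> list[dict]:
    """All published power-law rows (including unstandardized ones)."""
    return [dict(r) for r in _load(_FILES[Stock(stock)])["power"]]


def reference_monthly_wlr(stock: Stock) -> MonthlyWLR:
    """The published monthly weight-length coefficient table."""
    entry = _load("monthly_wlr.json")[Stock(stock).value]
    return MonthlyWLR(alpha=entry["alpha"],
                      beta_by_month=np.asarray(entry["beta_by_month"]))
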