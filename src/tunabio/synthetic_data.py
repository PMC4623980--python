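"""Synthetic fishery-data generator.

Emulates the statistical structure of pooled bluefin biometric sampling so
the whole analysis chain is testable without field data: an age-structured
latent population (survivorship-proportional ages, normal length-at-age,
multiplicative lognormal weight noise whose CV follows a size-dependent
profile, and a monthly condition cycle injected as exponent offsets), a
measurement layer that converts latent truth into whichever length/weight
types each fleet records (plus optional additive measurement noise), and a
fishery-selection layer (knife-edge minimum size, optional logistic
retention, fleet activity months).

All randomness flows from one seeded stream in a fixed stage order, so a
configuration plus seed reproduces a dataset exactly.

Default mortality and growth are user-supplied assessment-style values
(M-at-age vectors and von Bertalanffy parameters of the kind used in
bluefin stock assessments); they are package defaults, not estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .errors import ConfigurationError
from .popsim import PopulationModel, survivorship, von_bertalanffy
from .standardize import LinearConversion
from .types import (COLUMN_FOR, LATENT_COLUMNS, LENGTH_TYPES, RECORD_COLUMNS,
                    Measurement, Stock)

DEFAULT_AGES = tuple(range(1, 21))

#: Assessment-style natural mortality defaults (yr^-1): high age-1 M for the
#: East declining to 0.10 for old fish; flat 0.14 for the West.
DEFAULT_M: dict[Stock, tuple[float, ...]] = {
    Stock.EAST: (0.49, 0.24, 0.24, 0.24, 0.24, 0.20, 0.175, 0.15, 0.125)
    + (0.10,) * 11,
    Stock.WEST: (0.14,) * 20,
}

#: von Bertalanffy growth defaults (L_inf cm, k yr^-1, t0 yr).
DEFAULT_VB: dict[Stock, tuple[float, float, float]] = {
    Stock.EAST: (318.85, 0.093, -0.97),
    Stock.WEST: (314.9, 0.089, -1.13),
}

#: Piecewise-linear CV-of-weight-at-length profiles (SFL cm -> CV fraction):
#: high CV for small eastern fish easing to ~9% at mid sizes then 12.5%;
#: a pronounced mid-size hump for the West.
DEFAULT_CV_KNOTS: dict[Stock, tuple[tuple[float, float], ...]] = {
    Stock.EAST: ((30, 0.20), (60, 0.20), (100, 0.09), (150, 0.09),
                 (300, 0.125)),
    Stock.WEST: ((53, 0.13), (120, 0.13), (160, 0.35), (200, 0.35),
                 (300, 0.125)),
}

#: Knife-edge minimum retention sizes (SFL cm) for the default fleet.
DEFAULT_MIN_SIZE: dict[Stock, float] = {Stock.EAST: 75.0, Stock.WEST: 170.0}

DEFAULT_AREAS: dict[Stock, tuple[str, ...]] = {
    Stock.EAST: ("BB", "AIMA", "SG", "WM", "CM", "EM"),
    Stock.WEST: ("GSL", "MAGESS", "MAB", "WCA", "SABFEC"),
}


@dataclass(frozen=True)
class LogisticSelectivity:
    """Retention probability 1 / (1 + exp(-(L - l50) / slope))."""

    l50: float
    slope: float

    def __call__(self, sfl):
        return 1.0 / (1.0 + np.exp(-(np.asarray(sfl, float) - self.l50)
                                   / self.slope))


@dataclass
class FleetConfig:
    """One sampling fleet: gear, season, retention and what it measures."""

    gear: str
    months_active: tuple[int, ...] = tuple(range(1, 13))
    min_size_cm: float = 0.0
    selectivity: LogisticSelectivity | None = None
    measurement_types: tuple[Measurement, ...] = (Measurement.SFL,
                                                  Measurement.RWT)
    measurement_noise_sd: dict[Measurement, float] = dc_field(
        default_factory=dict)
    areas: tuple[str, ...] = ()
    share: float = 1.0

    def __post_init__(self):
        self.months_active = tuple(int(m) for m in self.months_active)
        if not self.months_active:
            raise ConfigurationError("months_active must be non-empty")
        if any(m < 1 or m > 12 for m in self.months_active):
            raise ConfigurationError("months_active must lie in 1..12")
        if self.min_size_cm < 0:
            raise ConfigurationError("min_size_cm must be >= 0")
        self.measurement_types = tuple(Measurement(t)
                                       for t in self.measurement_types)
        self.measurement_noise_sd = {Measurement(k): float(v)
                                     for k, v in
                                     self.measurement_noise_sd.items()}
        if self.share <= 0:
            raise ConfigurationError("fleet share must be positive")


def cv_profile_from_knots(
    knots: Sequence[tuple[float, float]]
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear CV(SFL) interpolator, clamped at the end knots."""
    xs = np.asarray([k[0] for k in knots], float)
    ys = np.asarray([k[1] for k in knots], float)
    if np.any(np.diff(xs) <= 0):
        raise ConfigurationError("CV profile knots must increase in SFL")
    if np.any(ys < 0):  # zero is allowed: it turns the weight noise off
        raise ConfigurationError("CV profile values must be non-negative")

    def profile(sfl):
        return np.interp(np.asarray(sfl, float), xs, ys)

    return profile


@dataclass
class GeneratorConfig:
    """Full description of a synthetic fishery dataset.

    The monthly exponent offsets are centered to mean zero on
    construction, so the injected seasonality perturbs but never shifts
    the annual allometry.
    """

    stock: Stock
    n_fish: int
    seed: int
    true_alpha: float
    true_beta: float
    ages: tuple[int, ...] = DEFAULT_AGES
    M_at_age: tuple[float, ...] | None = None
    mean_length_at_age: tuple[float, ...] | None = None
    length_cv: float = 0.125
    weight_cv_knots: tuple[tuple[float, float], ...] | None = None
    monthly_exponent_offsets: tuple[float, ...] = (0.0,) * 12
    fleets: tuple[FleetConfig, ...] = ()
    years: tuple[int, int] = (1998, 2012)

    def __post_init__(self):
        self.stock = Stock(self.stock)
        self.ages = tuple(int(a) for a in self.ages)
        if self.true_alpha <= 0:
            raise ConfigurationError("true_alpha must be positive")
        if not 0 < self.length_cv < 0.5:
            raise ConfigurationError("length_cv must lie in (0, 0.5)")
        if self.M_at_age is None:
            self.M_at_age = DEFAULT_M[self.stock][: len(self.ages)]
        self.M_at_age = tuple(float(m) for m in self.M_at_age)
        if len(self.M_at_age) != len(self.ages):
            raise ConfigurationError("M_at_age must align with ages")
        if any(m <= 0 for m in self.M_at_age):
            raise ConfigurationError("all M_at_age must be positive")
        if self.mean_length_at_age is None:
            linf, k, t0 = DEFAULT_VB[self.stock]
            self.mean_length_at_age = von_bertalanffy(
                np.asarray(self.ages), linf, k, t0)
        self.mean_length_at_age = tuple(
            float(x) for x in self.mean_length_at_age)
        if len(self.mean_length_at_age) != len(self.ages):
            raise ConfigurationError(
                "mean_length_at_age must align with ages"
            )
        if self.weight_cv_knots is None:
            self.weight_cv_knots = DEFAULT_CV_KNOTS[self.stock]
        self.weight_cv_knots = tuple(
            (float(x), float(c)) for x, c in self.weight_cv_knots)
        offs = np.asarray(self.monthly_exponent_offsets, float)
        if offs.size != 12:
            raise ConfigurationError(
                f"monthly_exponent_offsets must have 12 entries, "
                f"got {offs.size}"
            )
        self.monthly_exponent_offsets = tuple(
            float(v) for v in offs - offs.mean())
        self.years = (int(self.years[0]), int(self.years[1]))
        self.fleets = tuple(self.fleets)
        for fl in self.fleets:
            if not fl.areas:
                fl.areas = DEFAULT_AREAS[self.stock]

    @classmethod
    def default(cls, stock: Stock, n_fish: int, seed: int,
                **overrides) -> "GeneratorConfig":
        """East- or West-like defaults: the packaged reference annual
        coefficients as truth, the stock's CV profile, a monthly cycle
        matching the reference monthly table, and one all-month fleet
        recording SFL and RWT above the stock's minimum size."""
        stock = Stock(stock)
        ref = fixtures.reference_wlr(stock)
        monthly = fixtures.reference_monthly_wlr(stock)
        offsets = monthly.beta_by_month - monthly.beta_by_month.mean()
        base = dict(
            stock=stock, n_fish=n_fish, seed=seed,
            true_alpha=ref.alpha, true_beta=ref.beta,
            monthly_exponent_offsets=tuple(offsets),
            fleets=(FleetConfig(
                gear="Longline",
                min_size_cm=DEFAULT_MIN_SIZE[stock],
                areas=DEFAULT_AREAS[stock],
            ),),
        )
        base.update(overrides)
        return cls(**base)

    def weight_cv_profile(self) -> Callable[[np.ndarray], np.ndarray]:
        return cv_profile_from_knots(self.weight_cv_knots)

    def population_model(self) -> PopulationModel:
        return PopulationModel(
            ages=np.asarray(self.ages),
            M_at_age=np.asarray(self.M_at_age),
            mean_length_at_age=np.asarray(self.mean_length_at_age),
            length_cv=self.length_cv,
            plus_group=True,
        )

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        spec = dataclasses.asdict(self)
        spec["stock"] = self.stock.value
        for fl in spec["fleets"]:
            fl["measurement_types"] = [m.value
                                       for m in fl["measurement_types"]]
            fl["measurement_noise_sd"] = {
                k.value: v for k, v in fl["measurement_noise_sd"].items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        fleets = []
        for fl in spec.pop("fleets", []):
            sel = fl.get("selectivity")
            if isinstance(sel, dict):
                fl["selectivity"] = LogisticSelectivity(**sel)
            fleets.append(FleetConfig(**fl))
        spec["fleets"] = tuple(fleets)
        return cls(**spec)


_LATENT_SCHEMA = ["fish_id", "stock", "age", "year", "month",
                  "sfl_true", "rwt_true"]


def generate_population(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the latent population: age, capture month/year, true SFL and
    true RWT per fish.

    Ages are drawn with survivorship probabilities; SFL is normal around
    mean length-at-age (sd = cv * mean, resampled to stay positive); RWT is
    ``alpha * SFL^(beta + offset[month])`` times lognormal noise whose
    log-sd is sqrt(log(1 + CV(SFL)^2)), so the realized CV of weight at
    fixed length equals the configured profile.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(config.n_fish)
    if n <= 0:
        return pd.DataFrame({c: pd.Series(dtype="float64")
                             if c not in ("stock",)
                             else pd.Series(dtype="object")
                             for c in _LATENT_SCHEMA})

    props = survivorship(config.population_model())
    ages = rng.choice(np.asarray(config.ages), size=n, p=props)
    month = rng.integers(1, 13, size=n)
    y0, y1 = config.years
    year = rng.integers(y0, y1 + 1, size=n)

    mu = np.asarray(config.mean_length_at_age, float)[
        np.searchsorted(np.asarray(config.ages), ages)
    ]
    sfl = rng.normal(mu, config.length_cv * mu)
    bad = sfl <= 0
    while bad.any():  # truncate at zero by redraw; rare at cv 0.125
        sfl[bad] = rng.normal(mu[bad], config.length_cv * mu[bad])
        bad = sfl <= 0

    cv = config.weight_cv_profile()(sfl)
    sigma = np.sqrt(np.log1p(cv**2))
    offsets = np.asarray(config.monthly_exponent_offsets)
    beta_eff = config.true_beta + offsets[month - 1]
    rwt = config.true_alpha * np.power(sfl, beta_eff) * np.exp(
        rng.normal(0.0, 1.0, size=n) * sigma
    )
    return pd.DataFrame({
        "fish_id": np.arange(n, dtype=np.int64),
        "stock": config.stock.value,
        "age": ages.astype(np.int64),
        "year": year.astype(np.int64),
        "month": month.astype(np.int64),
        "sfl_true": sfl,
        "rwt_true": rwt,
    })


def default_measurement_truth(stock: Stock) -> list[LinearConversion]:
    """Latent->observed conversion truth: the packaged reference
    conversions whose independent variable is SFL or RWT."""
    return [c for c in fixtures.reference_conversions(stock)
            if c.x_type in (Measurement.SFL, Measurement.RWT)]


def apply_measurement_process(
    latent: pd.DataFrame,
    fleet: FleetConfig,
    conversions: Sequence[LinearConversion],
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Turn latent fish into field records carrying only the fleet's
    measurement types.

    Each observed value is the deterministic conversion of the latent truth
    (identity for SFL/RWT) plus optional additive Gaussian noise.  Noised
    values driven non-positive are blanked.  Latent truth columns are kept
    for test oracles; CSV export drops them by default.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_target = {c.y_type: c for c in conversions}
    n = len(latent)
    out = pd.DataFrame(index=latent.index)
    for col in ("fish_id", "stock", "year", "month"):
        out[col] = latent[col].to_numpy()
    out["area"] = (rng.choice(np.asarray(fleet.areas, dtype=object), size=n)
                   if n else np.array([], dtype=object))
    out["gear"] = fleet.gear

    for col in COLUMN_FOR.values():
        out[col] = np.nan
    for mtype in fleet.measurement_types:
        base = latent["sfl_true" if mtype in LENGTH_TYPES
                      else "rwt_true"].to_numpy(float)
        if mtype in (Measurement.SFL, Measurement.RWT):
            val = base.copy()
        else:
            conv = by_target.get(mtype)
            if conv is None:
                raise ConfigurationError(
                    f"fleet {fleet.gear!r} records {mtype.value} but no "
                    "conversion truth defines it"
                )
            val = conv.predict(base)
        sd = fleet.measurement_noise_sd.get(mtype, 0.0)
        if sd > 0:
            val = val + rng.normal(0.0, sd, size=n)
        out[COLUMN_FOR[mtype]] = np.where(val > 0, val, np.nan)

    for col in ("age", "sfl_true", "rwt_true"):
        out[col] = latent[col].to_numpy()
    return out[RECORD_COLUMNS + LATENT_COLUMNS]


def apply_fishery_selection(
    records: pd.DataFrame,
    fleet: FleetConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Retention: drop fish below the knife-edge minimum size, apply the
    optional probabilistic selectivity curve, and keep only the fleet's
    active months.  Requires the latent ``sfl_true`` column."""
    if "sfl_true" not in records.columns:
        raise ConfigurationError(
            "fishery selection needs the latent sfl_true column"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sfl = records["sfl_true"].to_numpy(float)
    keep = sfl >= fleet.min_size_cm
    if fleet.selectivity is not None:
        keep &= rng.random(len(records)) < fleet.selectivity(sfl)
    keep &= records["month"].isin(fleet.months_active).to_numpy()
    return records[keep].reset_index(drop=True)


def generate_dataset(
    config: GeneratorConfig,
    conversions: Sequence[LinearConversion] | None = None,
) -> pd.DataFrame:
    """End-to-end synthetic dataset: latent population, fleet allocation,
    measurement process and fishery selection, all from one seeded stream.
    """
    rng = np.random.default_rng(config.seed)
    latent = generate_population(config, rng)
    fleets = config.fleets or (FleetConfig(gear="Unknown"),)
    if conversions is None:
        conversions = default_measurement_truth(config.stock)
    shares = np.asarray([fl.share for fl in fleets], float)
    shares = shares / shares.sum()
    assignment = rng.choice(len(fleets), size=len(latent), p=shares)
    parts = []
    for i, fleet in enumerate(fleets):
        sub = latent[assignment == i]
        recs = apply_measurement_process(sub, fleet, conversions, rng)
        parts.append(apply_fishery_selection(recs, fleet, rng))
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=RECORD_COLUMNS + LATENT_COLUMNS)
    return out.sort_values("fish_id", kind="stable").reset_index(drop=True)


def write_records_csv(records: pd.DataFrame, path,
                      include_latent: bool = False) -> None:
    """One row per fish; empty field = missing.  ``include_latent`` writes
    a companion view with the latent-truth columns."""
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    if include_latent:
        cols += [c for c in LATENT_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False, float_format="%.6g")


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"stock": "string", "area": "string",
                                    "gear": "string"})
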