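"""Sampling-representativeness simulation.

An age-structured population with instantaneous natural (and optional
fishing) mortality, normally distributed length-at-age (CV 12.5% by
default), and an optional knife-edge minimum-size selectivity yields the
size composition a non-selective (or minimum-size-regulated) sampling
programme should see, per 1 cm straight-fork-length bin.  The expected
composition can then be compared with an observed sample via CDFs and the
Kolmogorov-Smirnov distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .errors import ConfigurationError


def von_bertalanffy(ages, linf: float, k: float, t0: float) -> np.ndarray:
    """Mean length-at-age (cm) under von Bertalanffy growth."""
    ages = np.asarray(ages, dtype=float)
    return linf * (1.0 - np.exp(-k * (ages - t0)))


@dataclass
class PopulationModel:
    """Ages, mortality and growth of a bluefin-like population.

    ``plus_group`` closes the oldest age with the geometric sum of all
    older survivors.  ``F_at_age`` defaults to zero (unfished population).
    """

    ages: np.ndarray
    M_at_age: np.ndarray
    mean_length_at_age: np.ndarray
    length_cv: float = 0.125
    F_at_age: np.ndarray | None = None
    plus_group: bool = False

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.M_at_age = np.asarray(self.M_at_age, dtype=float)
        self.mean_length_at_age = np.asarray(self.mean_length_at_age,
                                             dtype=float)
        a = self.ages.size
        if self.M_at_age.size != a or self.mean_length_at_age.size != a:
            raise ConfigurationError(
                "ages, M_at_age and mean_length_at_age must align"
            )
        if np.any(self.M_at_age <= 0):
            raise ConfigurationError("all M_at_age must be positive")
        if np.any(np.diff(self.mean_length_at_age) <= 0):
            raise ConfigurationError(
                "mean lengths must increase strictly with age"
            )
        if not self.length_cv > 0:
            raise ConfigurationError("length_cv must be positive")
        if self.F_at_age is None:
            self.F_at_age = np.zeros(a)
        else:
            self.F_at_age = np.asarray(self.F_at_age, dtype=float)
            if self.F_at_age.size != a or np.any(self.F_at_age < 0):
                raise ConfigurationError("F_at_age must be >= 0 per age")

    @classmethod
    def from_von_bertalanffy(
        cls, ages, M_at_age, linf: float, k: float, t0: float,
        length_cv: float = 0.125, F_at_age=None, plus_group: bool = False,
    ) -> "PopulationModel":
        ages = np.asarray(ages, dtype=int)
        M = np.asarray(M_at_age, dtype=float)
        if M.ndim == 0:
            M = np.full(ages.size, float(M))
        return cls(ages, M, von_bertalanffy(ages, linf, k, t0),
                   length_cv=length_cv, F_at_age=F_at_age,
                   plus_group=plus_group)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        ages = np.arange(int(spec["age_min"]), int(spec["age_max"]) + 1)
        M = spec["M"]
        growth = spec["growth"]
        kwargs = dict(
            length_cv=float(spec.get("length_cv", 0.125)),
            F_at_age=spec.get("F"),
            plus_group=bool(spec.get("plus_group", False)),
        )
        if isinstance(growth, dict):
            return cls.from_von_bertalanffy(
                ages, M, float(growth["linf"]), float(growth["k"]),
                float(growth["t0"]), **kwargs,
            )
        M = np.asarray(M, dtype=float)
        if M.ndim == 0:
            M = np.full(ages.size, float(M))
        return cls(ages, M, np.asarray(growth, dtype=float), **kwargs)


def survivorship(model: PopulationModel) -> np.ndarray:
    """Equilibrium numbers-at-age proportions.

    N_1 = 1 and N_{a+1} = N_a exp(-Z_a) with Z = M + F; a plus-group adds
    the geometric closure N_A exp(-Z_A) / (1 - exp(-Z_A)) to the last age.
    """
    Z = model.M_at_age + model.F_at_age
    N = np.ones(model.ages.size)
    for i in range(1, N.size):
        N[i] = N[i - 1] * np.exp(-Z[i - 1])
    if model.plus_group:
        zA = Z[-1]
        if zA <= 0:
            raise ConfigurationError(
                "plus-group requires positive total mortality at the "
                "oldest age (the geometric sum diverges otherwise)"
            )
        N[-1] += N[-1] * np.exp(-zA) / (1.0 - np.exp(-zA))
    return N / N.sum()


@dataclass(frozen=True)
class SizeSamplingDistribution:
    """Expected sampling proportion per 1 cm length bin with its CDF."""

    bin_edges: np.ndarray
    proportions: np.ndarray

    def __post_init__(self):
        p = self.proportions
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "proportions must be non-negative and sum to 1"
            )

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.proportions)

    @property
    def bin_lowers(self) -> np.ndarray:
        return self.bin_edges[:-1]


def expected_size_distribution(
    model: PopulationModel,
    knife_edge_cm: float | None = None,
    support: tuple[float, float] | None = None,
    bin_width: float = 1.0,
) -> SizeSamplingDistribution:
    """Expected per-bin sampling proportions of a non-selective sample.

    Each age contributes a Normal(mean length-at-age, cv * mean) component
    weighted by survivorship; per-bin mass is the CDF increment over the
    bin.  Mass outside the support (including below zero) is clipped and
    the distribution renormalized.  A knife-edge threshold zeroes every bin
    starting below it.
    """
    props_age = survivorship(model)
    mu = model.mean_length_at_age
    sigma = model.length_cv * mu
    if support is None:
        hi = float(np.ceil(mu[-1] + 5 * sigma[-1]))
        support = (0.0, hi)
    lo, hi = support
    edges = np.arange(lo, hi + bin_width, bin_width)
    mass = np.zeros(edges.size - 1)
    for p_a, m_a, s_a in zip(props_age, mu, sigma):
        cdf = norm.cdf(edges, loc=m_a, scale=s_a)
        mass += p_a * np.diff(cdf)
    if knife_edge_cm is not None:
        mass[edges[:-1] < knife_edge_cm] = 0.0
    total = mass.sum()
    if total <= 0:
        raise ConfigurationError("no population mass left on the support")
    return SizeSamplingDistribution(bin_edges=edges,
                                    proportions=mass / total)


@dataclass(frozen=True)
class SamplingComparison:
    """Observed vs expected size composition on a common set of bins."""

    actual_proportions: np.ndarray
    expected_proportions: np.ndarray
    actual_cdf: np.ndarray
    expected_cdf: np.ndarray
    ks_distance: float


def compare_sampling(
    actual_counts: Sequence[float],
    expected: SizeSamplingDistribution,
) -> SamplingComparison:
    """Normalize observed per-bin counts and compare CDFs with the expected
    distribution; the KS distance is the maximum absolute CDF gap."""
    counts = np.asarray(actual_counts, dtype=float)
    if counts.size != expected.proportions.size:
        raise ConfigurationError(
            f"actual counts cover {counts.size} bins but the expected "
            f"distribution has {expected.proportions.size}"
        )
    if np.any(counts < 0):
        raise ConfigurationError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ConfigurationError("total actual count is zero")
    actual_p = counts / total
    actual_cdf = np.cumsum(actual_p)
    expected_cdf = expected.cdf
    ks = float(np.max(np.abs(actual_cdf - expected_cdf)))
    return SamplingComparison(
        actual_proportions=actual_p,
        expected_proportions=expected.proportions.copy(),
        actual_cdf=actual_cdf,
        expected_cdf=expected_cdf,
        ks_distance=ks,
    )
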