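"""Configuration-driven workflow.

``run_pipeline`` wires the stages together: acquire data (synthetic or
CSV), fit conversions, standardize, profile binned CVs, fit the annual
weight-length relation (unweighted and CV-weighted), run the quantile and
bootstrap sensitivity analyses, fit the condition model and emit the
monthly coefficient table.  Every run writes a machine-readable JSON
report stamped with a hash of its configuration and the seed, plus a
human-readable summary and CSV exports; rerunning the same configuration
reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import condition as cond
from . import fixtures, synthetic_data, wlr
from .errors import PipelineError
from .standardize import fit_conversions, standardize_records, wlr_input
from .types import Stock

logger = logging.getLogger(__name__)

DEFAULT_TAUS = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class PipelineConfig:
    """What to run and with which knobs.

    Exactly one of ``generator`` / ``input_csv`` supplies the data.  The
    seed drives every stochastic stage; per-stage seeds are derived from it
    and logged.
    """

    stock: Stock
    generator: synthetic_data.GeneratorConfig | None = None
    input_csv: str | None = None
    gate: float = 0.98
    weighting: str = "INV_CV"
    bootstrap_schemes: tuple[str, ...] = ("EQUAL_PROB", "UNIFORM_PER_BIN")
    bootstrap_B: int = 1000
    quantile_taus: tuple[float, ...] = DEFAULT_TAUS
    condition_factors: tuple[str, ...] = ("month", "maturity", "area_group")
    exponent_scale: str = "mse"
    use_reference_conversions: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        self.stock = Stock(self.stock)
        if (self.generator is None) == (self.input_csv is None):
            raise PipelineError(
                "[config] provide exactly one of generator / input_csv"
            )
        if self.bootstrap_B < 1:
            raise PipelineError("[config] bootstrap_B must be >= 1")
        if any(not 0 < t < 1 for t in self.quantile_taus):
            raise PipelineError("[config] quantile taus must lie in (0, 1)")

    def to_jsonable(self) -> dict:
        spec = dataclasses.asdict(self)
        spec["stock"] = self.stock.value
        if self.generator is not None:
            gen = spec["generator"]
            gen["stock"] = self.generator.stock.value
            for fl in gen["fleets"]:
                fl["measurement_types"] = [
                    m.value for m in fl["measurement_types"]]
                fl["measurement_noise_sd"] = {
                    k.value: v
                    for k, v in fl["measurement_noise_sd"].items()}
        return spec

    def config_hash(self) -> str:
        spec = self.to_jsonable()
        spec.pop("outdir", None)  # where results land is not part of identity
        blob = json.dumps(spec, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def demo(cls, seed: int = 0, n_fish: int = 20000,
             stock: Stock = Stock.EAST, **overrides) -> "PipelineConfig":
        """Synthetic demonstration run on generator defaults."""
        base = dict(
            stock=stock,
            generator=synthetic_data.GeneratorConfig.default(
                stock, n_fish=n_fish, seed=seed),
            bootstrap_B=200,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"[{name}] {err}") from err
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the report dictionary.

    If ``config.outdir`` is set, also writes ``report.json``,
    ``summary.txt``, the standardized records, the residual table and the
    monthly coefficient table.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def mark(stage):
        timings[stage] = round(time.perf_counter() - t0, 3)

    # data ------------------------------------------------------------------
    if config.generator is not None:
        records = _stage("data")(synthetic_data.generate_dataset)(
            config.generator)
    else:
        records = _stage("data")(synthetic_data.read_records_csv)(
            config.input_csv)
        missing = {"fish_id", "stock", "month"} - set(records.columns)
        if missing:
            raise PipelineError(
                f"[data] input is missing columns: {sorted(missing)}"
            )
    mark("data")

    # conversions -----------------------------------------------------------
    conversions = _stage("conversions")(fit_conversions)(records)
    if config.use_reference_conversions:
        fitted_pairs = {(c.x_type, c.y_type) for c in conversions}
        conversions += [
            c for c in fixtures.reference_conversions(config.stock)
            if (c.x_type, c.y_type) not in fitted_pairs
        ]
    mark("conversions")

    # standardize -----------------------------------------------------------
    std = _stage("standardize")(standardize_records)(
        records, conversions, gate=config.gate)
    fit_input = wlr_input(std)
    if len(fit_input) < 10:
        raise PipelineError(
            "[standardize] fewer than 10 records have both sfl_std and "
            "rwt_std after gating; nothing to fit"
        )
    mark("standardize")

    # annual fits -----------------------------------------------------------
    bins = _stage("bin_cv")(wlr.bin_cv_profile)(fit_input)
    mark("bin_cv")
    fit_unweighted = _stage("fit")(wlr.fit_power_law)(
        fit_input, weighting="NONE")
    fit_weighted = _stage("fit")(wlr.fit_power_law)(
        fit_input, weighting="INV_CV", bins=bins)
    final_fit = fit_weighted if config.weighting == "INV_CV" \
        else fit_unweighted
    mark("fit")

    # sensitivity -----------------------------------------------------------
    quantiles = [
        _stage("quantile")(wlr.fit_power_quantile)(
            fit_input, tau, start=fit_unweighted)
        for tau in config.quantile_taus
    ]
    mark("quantile")
    seedseq = np.random.SeedSequence(config.seed)
    boot_seeds = [int(s) % (2**31) for s in
                  seedseq.generate_state(len(config.bootstrap_schemes))]
    bootstraps = {}
    for scheme, bseed in zip(config.bootstrap_schemes, boot_seeds):
        logger.info("bootstrap %s with derived seed %d", scheme, bseed)
        bootstraps[scheme] = _stage("bootstrap")(wlr.bootstrap_wlr)(
            fit_input, scheme=scheme, B=config.bootstrap_B, seed=bseed,
            weighting=config.weighting)
    mark("bootstrap")

    # condition -------------------------------------------------------------
    residuals = _stage("condition")(cond.scaled_residuals)(std, final_fit)
    factors = []
    for f in config.condition_factors:
        nlev = residuals.loc[~residuals["excluded"], f].dropna().nunique()
        if nlev >= 2:
            factors.append(f)
        else:
            logger.info("dropping condition factor %r (%d level)", f, nlev)
    model = _stage("condition")(cond.fit_condition_model)(
        residuals, factors=tuple(factors))
    lsm = _stage("condition")(cond.lsmeans_month)(
        model, months=tuple(range(1, 13)))
    monthly = _stage("condition")(cond.monthly_wlr_table)(
        final_fit, lsm, model.mse, exponent_scale=config.exponent_scale)
    mark("condition")

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stock": config.stock.value,
        "n_records": int(len(records)),
        "n_standardized": int(len(std)),
        "n_wlr_input": int(len(fit_input)),
        "conversions": [c.to_dict() for c in conversions],
        "bin_cv": [dataclasses.asdict(b) for b in bins],
        "fit_unweighted": fit_unweighted.to_dict(),
        "fit_weighted": fit_weighted.to_dict(),
        "quantiles": [dataclasses.asdict(q) for q in quantiles],
        "bootstrap": {s: {"B": b.B, "seed": b.seed,
                          "summary": b.summary()}
                      for s, b in bootstraps.items()},
        "condition": {
            "n": model.n,
            "mse": model.mse,
            "deviance": model.deviance,
            "lsmeans_month": [float(v) for v in lsm],
        },
        "monthly_wlr": {
            "alpha": monthly.alpha,
            "beta_by_month": [float(b) for b in monthly.beta_by_month],
        },
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        std.to_csv(outdir / "standardized.csv", index=False,
                   float_format="%.6g")
        residuals.to_csv(outdir / "scaled_residuals.csv", index=False,
                         float_format="%.6g")
        monthly.to_frame().to_csv(outdir / "monthly_wlr.csv", index=False)
        (outdir / "summary.txt").write_text(render_summary(report))
        (outdir / "stages.log").write_text(
            "".join(f"{k}: t+{v:.3f}s\n" for k, v in timings.items()))
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of a pipeline report."""
    fw = report["fit_weighted"]
    fu = report["fit_unweighted"]
    lines = [
        f"stock {report['stock']}  seed {report['seed']}  "
        f"config {report['config_hash']}",
        f"records {report['n_records']}  standardized "
        f"{report['n_standardized']}  WLR input {report['n_wlr_input']}",
        "",
        f"annual WLR (CV-weighted):  W = {fw['alpha']:.4g} * L^{fw['beta']:.5g}"
        f"   rmse {fw['rmse']:.3f} kg",
        f"annual WLR (unweighted):   W = {fu['alpha']:.4g} * L^{fu['beta']:.5g}"
        f"   rmse {fu['rmse']:.3f} kg",
        "",
        "quantile fits (tau: alpha, beta):",
    ]
    for q in report["quantiles"]:
        lines.append(f"  {q['tau']:>6}: {q['alpha']:.4g}, {q['beta']:.5g}")
    lines.append("")
    for scheme, b in report["bootstrap"].items():
        s = b["summary"]["beta"]
        lines.append(
            f"bootstrap {scheme} (B={b['B']}): beta mean {s['mean']:.5g}, "
            f"95% CI [{s['ci_2.5']:.5g}, {s['ci_97.5']:.5g}], "
            f"skew {s['skewness']:.3f}"
        )
    lines.append("")
    lines.append("monthly exponents:")
    for m, beta in enumerate(report["monthly_wlr"]["beta_by_month"], 1):
        lines.append(f"  month {m:2d}: beta {beta:.8f}")
    return "\n".join(lines) + "\n"
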