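"""End-to-end simulation studies: orchestration, aggregation, tables.

Study 1 (continuous auxiliary space, n=4000, m=400) measures how well
spread the recruited samples are under three weight schemes -- zero
("simple random sampling"), uniform ("adjusted sampling 1") and 50-nearest-
neighbor ("adjusted sampling 2") -- crossed with a full and an intercept-only
participation model.

Study 2 (five groups, n=5000, target 500) measures bias, variance, MSE and
95%-interval coverage of the Horvitz--Thompson total under zero weights
versus within-group weights, with a per-group participation model.

Replicate r derives all its randomness from ``base_seed + r``: child
streams for the population, the response oracle, and the invitation
decisions are spawned from that one seed, so every sampler variant within a
replicate faces the same population and the same response randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distance_weights import WeightScheme, build_weights
from .estimators import estimate_total
from .participation_model import ParticipationModel
from .population_io import (
    DesignSpec,
    generate_sim1_population,
    generate_sim2_population,
    make_design_sim2,
)
from .sampler_core import ResponseOracle, run as run_sampler
from .spread_metrics import DEFAULT_NORMALIZATION, sample_spread

__all__ = ["ExperimentConfig", "run_sim1", "run_sim2", "emit_tables"]

SIM1_VARIANTS = {
    "srs": WeightScheme(kind="zero"),
    "uniform": WeightScheme(kind="uniform"),
    "knn50": WeightScheme(kind="knn", k=50),
}
SIM2_VARIANTS = {
    "srs": WeightScheme(kind="zero"),
    "group": WeightScheme(kind="group"),
}
SIM1_MODELS = ("full", "intercept_only")


@dataclass
class ExperimentConfig:
    scenario: str  # sim1 | sim2
    n: int = 0  # 0 -> scenario default (4000 / 5000)
    m: int = 0  # 0 -> scenario default (400 / 500 in expectation)
    replicates: int = 1000
    seed: int = 0
    variants: tuple[str, ...] = ()  # () -> all variants of the scenario
    models: tuple[str, ...] = ()  # sim1 only; () -> ("full",)
    fixed_population: bool = False  # reuse one population across replicates
    normalization: str = DEFAULT_NORMALIZATION

    def __post_init__(self) -> None:
        if self.scenario not in {"sim1", "sim2"}:
            raise ValueError("scenario must be 'sim1' or 'sim2'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        defaults = {"sim1": (4000, 400), "sim2": (5000, 500)}
        dn, dm = defaults[self.scenario]
        self.n = self.n or dn
        self.m = self.m or dm
        valid = SIM1_VARIANTS if self.scenario == "sim1" else SIM2_VARIANTS
        self.variants = tuple(self.variants) or tuple(valid)
        unknown = set(self.variants) - set(valid)
        if unknown:
            raise ValueError(f"invalid variants for {self.scenario}: {sorted(unknown)}")
        if self.scenario == "sim1":
            self.models = tuple(self.models) or ("full",)
            bad = set(self.models) - set(SIM1_MODELS)
            if bad:
                raise ValueError(f"invalid participation models: {sorted(bad)}")


def _replicate_seeds(base_seed: int, r: int):
    ss = np.random.SeedSequence(base_seed + r)
    return ss.spawn(3)  # population, oracle, decisions


def _sim1_model(kind: str) -> ParticipationModel:
    if kind == "full":
        return ParticipationModel(kind="linear", d_z=4)
    return ParticipationModel(kind="intercept_only")


def run_sim1(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run study 1; returns (summary, per-replicate records).

    Summary rows carry the 2.5/50/97.5% quantiles of the spread measure R
    and the mean and standard deviation of the participant count, per
    (variant, model) cell.
    """
    if config.scenario != "sim1":
        raise ValueError("config.scenario must be 'sim1'")
    records = []
    pop = truth = None
    for r in range(config.replicates):
        ss_pop, ss_oracle, ss_dec = _replicate_seeds(config.seed, r)
        if pop is None or not config.fixed_population:
            pop, truth = generate_sim1_population(config.n, ss_pop)
        design = DesignSpec.equal(config.n, config.m)
        weight_cache = {v: build_weights(pop, SIM1_VARIANTS[v]) for v in config.variants}
        for model_kind in config.models:
            for variant in config.variants:
                oracle = ResponseOracle(truth, pop, ss_oracle)
                result = run_sampler(
                    pop, design, weight_cache[variant], oracle,
                    _sim1_model(model_kind), ss_dec,
                )
                if result.n_participants > 0:
                    spread = sample_spread(pop, result.s, design,
                                           normalization=config.normalization)
                    R = spread.R
                    R_pop = float(np.sum((spread.q - 1) ** 2) / config.n)
                else:
                    R = R_pop = np.nan
                records.append(
                    {
                        "variant": variant,
                        "model": model_kind,
                        "replicate": r,
                        "seed": config.seed + r,
                        "R": R,
                        "R_per_population": R_pop,
                        "n_participants": result.n_participants,
                        "n_invited": result.n_invited,
                        "shortfall": result.shortfall,
                    }
                )
    rec = pd.DataFrame.from_records(records)
    summary = (
        rec.groupby(["variant", "model"], sort=False)
        .agg(
            R_q025=("R", lambda v: v.quantile(0.025)),
            R_median=("R", "median"),
            R_q975=("R", lambda v: v.quantile(0.975)),
            participants_mean=("n_participants", "mean"),
            participants_sd=("n_participants", "std"),
            replicates=("R", "size"),
        )
        .reset_index()
    )
    return summary, rec


def run_sim2(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run study 2; returns (summary, per-replicate records).

    Bias is computed against the realized total Y of each replicate's
    population (regenerated per replicate unless ``fixed_population``).
    """
    if config.scenario != "sim2":
        raise ValueError("config.scenario must be 'sim2'")
    records = []
    pop = truth = None
    for r in range(config.replicates):
        ss_pop, ss_oracle, ss_dec = _replicate_seeds(config.seed, r)
        if pop is None or not config.fixed_population:
            pop, truth = generate_sim2_population(config.n, ss_pop)
        design = make_design_sim2(pop)
        Y_true = float(pop.y.sum())
        weight_cache = {v: build_weights(pop, SIM2_VARIANTS[v]) for v in config.variants}
        for variant in config.variants:
            oracle = ResponseOracle(truth, pop, ss_oracle)
            model = ParticipationModel(kind="group", n_groups=5)
            result = run_sampler(pop, design, weight_cache[variant], oracle, model, ss_dec)
            est = estimate_total(pop.y, result.s, design.pi0, true_total=Y_true)
            records.append(
                {
                    "variant": variant,
                    "replicate": r,
                    "seed": config.seed + r,
                    "y_hat": est.y_hat,
                    "var_hat": est.var_hat,
                    "Y_true": Y_true,
                    "bias": est.y_hat - Y_true,
                    "covered": est.covered,
                    "variance_defined": est.variance_defined,
                    "n_participants": result.n_participants,
                    "shortfall": result.shortfall,
                }
            )
    rec = pd.DataFrame.from_records(records)
    summary = (
        rec.groupby("variant", sort=False)
        .agg(
            y_hat_mean=("y_hat", "mean"),
            bias_mean=("bias", "mean"),
            var_hat_mean=("var_hat", "mean"),
            mse=("bias", lambda v: float(np.mean(np.square(v)))),
            coverage=("covered", "mean"),
            participants_mean=("n_participants", "mean"),
            replicates=("y_hat", "size"),
        )
        .reset_index()
    )
    return summary, rec


def emit_tables(
    summaries: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    out_dir: str | Path,
    config_meta: dict | None = None,
) -> dict[str, Path]:
    """Write summary and per-replicate CSV tables plus run metadata.

    ``summaries`` maps scenario name -> (summary, records) as returned by
    :func:`run_sim1` / :func:`run_sim2`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, (summary, records) in summaries.items():
        p_sum = out_dir / f"{name}_summary.csv"
        p_rec = out_dir / f"{name}_replicates.csv"
        summary.to_csv(p_sum, index=False)
        records.to_csv(p_rec, index=False)
        written[f"{name}_summary"] = p_sum
        written[f"{name}_replicates"] = p_rec
    meta = {"seqsample_version": __version__, "config": config_meta or {}}
    p_meta = out_dir / "run_metadata.json"
    p_meta.write_text(json.dumps(meta, indent=2, default=str))
    written["metadata"] = p_meta
    return written
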