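"""Reproducible experiment drivers: config parsing, dispatch, table output.

Every experiment is a pure function of (config, root seed): identical
inputs yield byte-identical result tables.  Tables are plain TSV with a
commented metadata header so diffs stay reviewable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, analytic
from .abm import AbmParams, competition_sweep, init_world, run_abm
from .lattice import LatticeParams, delta_r_statistics, run_lattice_competition
from .params import EnvironmentParams, StrainParams
from .wellmixed import CompetitionParams, run_competition, win_fraction_sweep

MODELS = ("analytic", "wellmixed", "lattice", "abm")

_ALLOWED_KEYS = {
    "analytic": {"formula", "grid"},
    "wellmixed": {
        "mode", "p_plus", "p_minus", "c", "r", "d", "N", "max_rounds", "reps",
        "p_grid", "c_grid", "r_grid", "d_grid",
    },
    "lattice": {
        "mode", "rows", "cols", "target_r", "p", "c", "d", "max_rounds", "reps",
    },
    "abm": {
        "mode", "dims", "K", "disaster_prob", "kill_fraction", "switch_prob",
        "migration_prob", "pcd_prob", "mix", "fill_fraction", "max_steps",
        "reps", "record_every", "d_grid", "m_grid",
    },
}

_FORMULAS = {
    "cost_factor": (analytic.cost_factor, ("c", "r", "t")),
    "expected_switch_counts": (
        lambda p, r, c, m: analytic.expected_switch_counts(p, r, c, m)[0],
        ("p", "r", "c", "m"),
    ),
    "prob_exclusive_diversification": (
        analytic.prob_exclusive_diversification, ("p", "c", "m", "r")
    ),
    "optimal_switch_rate": (analytic.optimal_switch_rate, ("c", "m", "r")),
    "prob_pcd_extinction": (analytic.prob_pcd_extinction, ("c", "m", "r")),
    "benefit_cost_ratio": (analytic.benefit_cost_ratio, ("p", "c", "m", "r")),
    "time_to_stationary_diversity": (
        analytic.time_to_stationary_diversity, ("p", "tol")
    ),
}


@dataclass
class ExperimentConfig:
    """Validated experiment description."""

    model: str
    params: dict
    seed: int = 0
    reps: int = 1
    outdir: Path = Path("results")
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        unknown = set(self.params) - _ALLOWED_KEYS[self.model]
        if unknown:
            raise ValueError(
                f"unknown {self.model} config keys: {sorted(unknown)}; "
                f"allowed: {sorted(_ALLOWED_KEYS[self.model])}"
            )
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict) or "model" not in raw:
            raise ValueError(f"{path}: config must be a mapping with a 'model' key")
        top = {k: raw.pop(k) for k in ("model", "seed", "reps", "outdir", "log_level")
               if k in raw}
        return cls(params=raw.pop("params", raw), **top)


def write_table(df: pd.DataFrame, path: Path, config: ExperimentConfig) -> None:
    """TSV with a commented, deterministic metadata header."""
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# pcdhedge {__version__}\n"
        f"# model: {config.model}\n"
        f"# seed: {config.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _grid_frame(formula: str, grid: dict) -> pd.DataFrame:
    func, argnames = _FORMULAS[formula]
    for name in argnames:
        if name not in grid:
            raise ValueError(f"{formula} needs grid values for {argnames}")
    mesh = np.meshgrid(*[np.atleast_1d(grid[a]) for a in argnames], indexing="ij")
    rows = []
    for point in zip(*(m.ravel() for m in mesh)):
        kwargs = dict(zip(argnames, (float(v) for v in point)))
        if "t" in kwargs:
            kwargs["t"] = int(kwargs["t"])
        rows.append({**kwargs, "value": func(**kwargs)})
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Dispatch a config to its model and write the result table.

    Returns the table; also writes ``<outdir>/<model>.tsv`` plus an echo
    of the resolved config.
    """
    p = dict(config.params)
    if config.model == "analytic":
        df = _grid_frame(p["formula"], p["grid"])
        name = "analytic"
    elif config.model == "wellmixed":
        mode = p.get("mode", "run")
        if mode == "sweep":
            df = win_fraction_sweep(
                np.atleast_1d(p["p_grid"]), np.atleast_1d(p["c_grid"]),
                np.atleast_1d(p["r_grid"]), np.atleast_1d(p["d_grid"]),
                reps=config.reps, seed=config.seed,
                n_capacity=int(p.get("N", 10_000)),
                max_rounds=int(p.get("max_rounds", 10_000)),
            )
        else:
            cp = CompetitionParams(
                plus=StrainParams(p["p_plus"], p["c"], is_pcd_plus=True),
                minus=StrainParams(p.get("p_minus", p["p_plus"])),
                env=EnvironmentParams(
                    p["d"], int(p.get("N", 10_000)), assortment=p["r"]
                ),
            )
            rows = []
            for i, s in enumerate(np.random.SeedSequence(config.seed).spawn(config.reps)):
                res = run_competition(cp, int(p.get("max_rounds", 10_000)), seed=s)
                rows.append({"rep": i, "winner": res.winner,
                             "rounds": res.rounds_elapsed})
            df = pd.DataFrame(rows)
        name = "wellmixed"
    elif config.model == "lattice":
        lp = LatticeParams(
            switch_prob_plus=p.get("p", 0.1), switch_prob_minus=p.get("p", 0.1),
            pcd_prob=p.get("c", 0.05), disaster_prob=p.get("d", 0.05),
            rows=int(p.get("rows", 100)), cols=int(p.get("cols", 100)),
        )
        rows = []
        trajs = []
        for i, s in enumerate(np.random.SeedSequence(config.seed).spawn(config.reps)):
            res, traj = run_lattice_competition(
                p.get("target_r", 0.5), lp,
                max_rounds=int(p.get("max_rounds", 100_000)), seed=s,
            )
            trajs.append(traj)
            final_r = float(traj["mean_r"].iloc[-1]) if len(traj) else float("nan")
            rows.append({"rep": i, "winner": res.winner,
                         "rounds": res.rounds_elapsed, "final_mean_r": final_r})
        df = pd.DataFrame(rows)
        if trajs and config.reps == 1:
            write_table(trajs[0], config.outdir / "lattice_trajectory.tsv", config)
        stats = delta_r_statistics(trajs) if any(len(t) for t in trajs) else {}
        if stats:
            write_table(
                pd.DataFrame(
                    [{"class": k, **v} for k, v in stats.items()]
                ),
                config.outdir / "lattice_delta_r.tsv", config,
            )
        name = "lattice"
    else:  # abm
        mode = p.get("mode", "run")
        ap = AbmParams(
            disaster_prob=p.get("disaster_prob", 0.01),
            kill_fraction=p.get("kill_fraction", 0.99),
            switch_prob=p.get("switch_prob", 0.1),
            migration_prob=p.get("migration_prob", 0.005),
            pcd_prob=p.get("pcd_prob", 0.025),
            max_steps=int(p.get("max_steps", 20_000)),
        )
        dims = tuple(p.get("dims", (10, 10, 10)))
        if mode == "sweep":
            df = competition_sweep(
                np.atleast_1d(p["d_grid"]), np.atleast_1d(p["m_grid"]),
                reps=config.reps, params=ap, dims=dims,
                capacity=int(p.get("K", 10)),
                fill_fraction=p.get("fill_fraction", 1.0),
                seed=config.seed,
                record_every=int(p.get("record_every", 10)),
            )
        else:
            rows = []
            for i, s in enumerate(np.random.SeedSequence(config.seed).spawn(config.reps)):
                rng = np.random.default_rng(s)
                world = init_world(
                    dims, int(p.get("K", 10)), p.get("fill_fraction", 1.0),
                    p.get("mix", 0.5), rng,
                )
                metrics = run_abm(world, ap, rng,
                                  record_every=int(p.get("record_every", 1)))
                rows.append({
                    "rep": i, "outcome": metrics.outcome, "steps": metrics.steps,
                    "mean_log_pop": metrics.mean_log_pop, "cv_pop": metrics.cv_pop,
                })
            df = pd.DataFrame(rows)
        name = "abm"
    write_table(df, config.outdir / f"{name}.tsv", config)
    with open(config.outdir / f"{name}_config.yaml", "w") as fh:
        yaml.safe_dump(
            {"model": config.model, "seed": config.seed, "reps": config.reps,
             "params": config.params}, fh, sort_keys=True,
        )
    return df
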