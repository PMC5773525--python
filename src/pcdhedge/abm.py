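"""3D patch-structured agent-based model with emergent assortment.

Cells live in patches arranged on a 3D grid (default 10x10x10), each
patch holding at most K = 10 cells.  A time step is: global disaster
(with some probability, killing 99% of one phenotype), reproduction into
free patch slots, migration between face-adjacent patches, then PCD.
Disasters empty the world enough that clonal regrowth and blocked
migration rebuild genotypic assortment — the 3D analogue of the lattice
model's regrowth fronts.

Cell types are stored as per-patch counts over (A+, B+, A-, B-); all
per-cell randomness reduces to exchangeable draws (binomial and
multivariate-hypergeometric), which keeps the model faithful to its
per-cell description while staying vectorizable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

# type columns
A_PLUS, B_PLUS, A_MINUS, B_MINUS = 0, 1, 2, 3
PHENOTYPES = ("A", "B")


@dataclass(frozen=True)
class AbmParams:
    """Per-step probabilities of the agent-based model."""

    disaster_prob: float = 0.01
    kill_fraction: float = 0.99
    switch_prob: float = 0.1
    migration_prob: float = 0.005
    pcd_prob: float = 0.025
    max_steps: int = 20_000

    def __post_init__(self) -> None:
        for name in ("disaster_prob", "kill_fraction", "switch_prob",
                     "migration_prob", "pcd_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class World:
    """Patch grid with per-patch type counts and face adjacency."""

    dims: tuple
    capacity: int
    counts: np.ndarray  # (n_patches, 4) int64
    neighbors: list = field(repr=False, default_factory=list)

    @property
    def n_patches(self) -> int:
        return int(np.prod(self.dims))

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def type_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def check_capacity(self) -> None:
        if (self.totals() > self.capacity).any():
            raise AssertionError("patch capacity exceeded")


def _face_neighbors(dims) -> list:
    nx, ny, nz = dims
    index = np.arange(nx * ny * nz).reshape(dims)
    out = []
    for x, y, z in itertools.product(range(nx), range(ny), range(nz)):
        nbrs = []
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            i, j, k = x + dx, y + dy, z + dz
            if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                nbrs.append(index[i, j, k])
        out.append(np.array(nbrs, dtype=np.int64))
    return out


def init_world(
    dims=(10, 10, 10),
    capacity: int = 10,
    fill_fraction: float = 1.0,
    genotype_mix: float = 0.5,
    rng=None,
) -> World:
    """Random uniform placement of cells over patch slots.

    ``genotype_mix`` is the PCD+ fraction (0.5 for competitions, 1.0 or
    0.0 for monocultures); phenotypes are A or B with probability 0.5.
    """
    if not 0.0 < fill_fraction <= 1.0:
        raise ValueError("fill_fraction must be in (0, 1]")
    if not 0.0 <= genotype_mix <= 1.0:
        raise ValueError("genotype_mix must be in [0, 1]")
    rng = np.random.default_rng(rng)
    n_patches = int(np.prod(dims))
    n_slots = n_patches * capacity
    n_cells = round(fill_fraction * n_slots)
    if n_cells > n_slots:
        raise ValueError("requested cells exceed world capacity")
    slots = rng.choice(n_slots, size=n_cells, replace=False)
    patches = slots // capacity
    n_plus = round(genotype_mix * n_cells)
    genotype = np.zeros(n_cells, dtype=np.int64)
    genotype[:n_plus] = 1
    rng.shuffle(genotype)
    phenotype_b = rng.integers(2, size=n_cells)
    type_index = np.where(genotype == 1, 0, 2) + phenotype_b
    counts = np.zeros((n_patches, 4), dtype=np.int64)
    np.add.at(counts, (patches, type_index), 1)
    return World(tuple(dims), capacity, counts, _face_neighbors(dims))


def abm_step(world: World, params: AbmParams, rng) -> dict:
    """Advance the world one time step in place; returns a step log.

    Phase order: disaster, reproduction, migration, PCD.  Reproduction
    lets each cell produce at most one offspring into its own patch,
    cells drawn in random order until the patch is full (a uniform subset
    of size min(n, K - n)); offspring switch phenotype with
    ``switch_prob``.  Migration moves each cell with probability
    ``migration_prob`` to a uniformly chosen face-adjacent patch, blocked
    if the destination is full at that moment.
    """
    counts = world.counts
    cap = world.capacity
    log = {"disaster": False, "target": None}

    if rng.random() < params.disaster_prob:
        t = int(rng.integers(2))
        log["disaster"] = True
        log["target"] = PHENOTYPES[t]
        cols = [t, t + 2]
        hit = counts[:, cols]
        counts[:, cols] = rng.binomial(hit, 1.0 - params.kill_fraction)

    totals = counts.sum(axis=1)
    for i in np.nonzero((totals > 0) & (totals < cap))[0]:
        n = int(totals[i])
        births = min(n, cap - n)
        parents = rng.multivariate_hypergeometric(counts[i], births)
        offspring = parents.copy()
        if params.switch_prob > 0:
            for ty in range(4):
                if parents[ty]:
                    s = rng.binomial(parents[ty], params.switch_prob)
                    offspring[ty] -= s
                    offspring[ty ^ 1] += s
        counts[i] += offspring

    if params.migration_prob > 0:
        movers = rng.binomial(counts, params.migration_prob)
        if movers.any():
            src_patch, src_type = np.nonzero(movers)
            reps = movers[src_patch, src_type]
            src_patch = np.repeat(src_patch, reps)
            src_type = np.repeat(src_type, reps)
            order = rng.permutation(src_patch.size)
            totals = counts.sum(axis=1)
            for j in order:
                pi, ty = int(src_patch[j]), int(src_type[j])
                nbrs = world.neighbors[pi]
                dest = int(nbrs[rng.integers(nbrs.size)])
                if totals[dest] < cap:
                    counts[pi, ty] -= 1
                    counts[dest, ty] += 1
                    totals[pi] -= 1
                    totals[dest] += 1

    if params.pcd_prob > 0:
        deaths = rng.binomial(counts[:, :2], params.pcd_prob)
        counts[:, :2] -= deaths
    return log


def compute_metrics(world: World) -> dict:
    """Global counts, per-genotype phenotypic diversity, patch assortment.

    Diversity is the normalized Shannon entropy of a genotype's A/B split
    (1 at 50:50, 0 when monomorphic, NaN when the genotype is absent).
    Assortment r averages, over PCD+ cells with at least one patch-mate,
    the same-genotype fraction among their patch-mates; NaN when no PCD+
    cell qualifies.
    """
    by_type = world.type_counts()
    snapshot = {
        "n_a_plus": int(by_type[A_PLUS]),
        "n_b_plus": int(by_type[B_PLUS]),
        "n_a_minus": int(by_type[A_MINUS]),
        "n_b_minus": int(by_type[B_MINUS]),
    }

    def _diversity(a: int, b: int) -> float:
        n = a + b
        if n == 0:
            return float("nan")
        h = 0.0
        for k in (a, b):
            if k:
                f = k / n
                h -= f * np.log(f)
        return float(h / np.log(2))

    snapshot["diversity_plus"] = _diversity(by_type[A_PLUS], by_type[B_PLUS])
    snapshot["diversity_minus"] = _diversity(by_type[A_MINUS], by_type[B_MINUS])

    g_plus = world.counts[:, A_PLUS] + world.counts[:, B_PLUS]
    g_minus = world.counts[:, A_MINUS] + world.counts[:, B_MINUS]
    mates = g_plus + g_minus - 1
    ok = (g_plus > 0) & (mates > 0)
    if ok.any():
        # each of the g_plus cells in a patch sees (g_plus - 1) kin among mates
        per_patch = g_plus[ok] * (g_plus[ok] - 1) / mates[ok]
        snapshot["assortment"] = float(per_patch.sum() / g_plus[ok].sum())
    else:
        snapshot["assortment"] = float("nan")
    return snapshot


@dataclass
class AbmMetrics:
    """Per-step records and summary statistics of one ABM run."""

    records: pd.DataFrame
    outcome: str  # "pcd_plus" | "pcd_minus" | "extinct" | "timeout"
    steps: int

    def _totals(self) -> np.ndarray:
        r = self.records
        return (
            r["n_a_plus"] + r["n_b_plus"] + r["n_a_minus"] + r["n_b_minus"]
        ).to_numpy(dtype=float)

    @property
    def mean_log_pop(self) -> float:
        """Grand mean of log population size over recorded steps."""
        totals = self._totals()
        totals = totals[totals > 0]
        return float(np.log(totals).mean()) if totals.size else float("nan")

    @property
    def cv_pop(self) -> float:
        """Coefficient of variation of population size over time."""
        totals = self._totals()
        if totals.size < 2 or totals.mean() == 0:
            return float("nan")
        return float(totals.std(ddof=1) / totals.mean())


def run_abm(
    world: World,
    params: AbmParams,
    seed=None,
    record_every: int = 1,
) -> AbmMetrics:
    """Run until a genotype initially present goes extinct, or ``max_steps``.

    For a monoculture the rule reduces to total extinction.  Metrics are
    snapshotted every ``record_every`` steps (and at the final step).
    """
    rng = np.random.default_rng(seed)
    initial = world.type_counts()
    plus_present = initial[A_PLUS] + initial[B_PLUS] > 0
    minus_present = initial[A_MINUS] + initial[B_MINUS] > 0
    records = []
    outcome = "timeout"
    step = 0
    for step in range(1, params.max_steps + 1):
        log = abm_step(world, params, rng)
        if step % record_every == 0:
            snap = compute_metrics(world)
            snap["step"] = step
            snap["disaster"] = log["disaster"]
            records.append(snap)
        by_type = world.type_counts()
        n_plus = by_type[A_PLUS] + by_type[B_PLUS]
        n_minus = by_type[A_MINUS] + by_type[B_MINUS]
        if plus_present and minus_present:
            if n_plus == 0 and n_minus == 0:
                outcome = "extinct"
            elif n_plus == 0:
                outcome = "pcd_minus"
            elif n_minus == 0:
                outcome = "pcd_plus"
            else:
                continue
            break
        if n_plus + n_minus == 0:
            outcome = "extinct"
            break
    if not records or records[-1].get("step") != step:
        snap = compute_metrics(world)
        snap["step"] = step
        snap["disaster"] = False
        records.append(snap)
    return AbmMetrics(pd.DataFrame(records), outcome, step)


def competition_sweep(
    disaster_grid,
    migration_grid,
    reps: int = 100,
    params: Optional[AbmParams] = None,
    dims=(10, 10, 10),
    capacity: int = 10,
    fill_fraction: float = 1.0,
    seed=None,
    record_every: int = 10,
) -> pd.DataFrame:
    """PCD+ win fraction and mean assortment over a (disaster, migration) grid.

    Per combination: ``reps`` 50:50 competitions; reports the PCD+ win
    fraction among resolved runs, counts of unresolved (timeout) and
    all-extinct runs, the time-averaged assortment and mean steps to
    resolution.
    """
    base = params or AbmParams()
    combos = list(itertools.product(disaster_grid, migration_grid))
    seeds = np.random.SeedSequence(seed).spawn(len(combos))
    rows = []
    for (d, mig), combo_seed in zip(combos, seeds):
        p = AbmParams(
            disaster_prob=d,
            kill_fraction=base.kill_fraction,
            switch_prob=base.switch_prob,
            migration_prob=mig,
            pcd_prob=base.pcd_prob,
            max_steps=base.max_steps,
        )
        wins_plus = wins_minus = timeouts = extinct = 0
        r_values = []
        steps = []
        for rep_seed in combo_seed.spawn(reps):
            rng = np.random.default_rng(rep_seed)
            world = init_world(dims, capacity, fill_fraction, 0.5, rng)
            metrics = run_abm(world, p, rng, record_every=record_every)
            if metrics.outcome == "pcd_plus":
                wins_plus += 1
            elif metrics.outcome == "pcd_minus":
                wins_minus += 1
            elif metrics.outcome == "timeout":
                timeouts += 1
            else:
                extinct += 1
            r_mean = metrics.records["assortment"].mean()
            if np.isfinite(r_mean):
                r_values.append(float(r_mean))
            steps.append(metrics.steps)
        decided = wins_plus + wins_minus
        rows.append(
            {
                "disaster_prob": d,
                "migration_prob": mig,
                "wins_plus": wins_plus,
                "wins_minus": wins_minus,
                "timeouts": timeouts,
                "both_extinct": extinct,
                "win_fraction": wins_plus / decided if decided else np.nan,
                "mean_assortment": float(np.mean(r_values)) if r_values else np.nan,
                "mean_steps": float(np.mean(steps)),
            }
        )
    return pd.DataFrame(rows)
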