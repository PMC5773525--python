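"""Spatially-implicit stochastic competitions with fixed assortment r.

Discrete rounds alternate stochastic disasters (annihilating one
phenotype of both genotypes), regrowth to carrying capacity, and one
PCD/replacement step — the stochastic counterpart, term by term, of the
deterministic one-round map in :mod:`pcdhedge.analytic`.  A genotype wins
by driving the other extinct, or by holding the majority when the round
cap is reached.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._urn import draw_births
from .params import EnvironmentParams, StrainParams
from .population import PopulationState
from .results import (
    BOTH_EXTINCT,
    PCD_MINUS,
    PCD_PLUS,
    TIMEOUT_MINUS,
    TIMEOUT_PLUS,
    TIMEOUT_TIE,
    CompetitionResult,
    RoundLog,
)

PHENOTYPES = ("A", "B")


@dataclass(frozen=True)
class CompetitionParams:
    """Full parameterization of one well-mixed competition."""

    plus: StrainParams
    minus: StrainParams
    env: EnvironmentParams
    pcd_steps_per_round: int = 1

    def __post_init__(self) -> None:
        if not self.plus.is_pcd_plus:
            raise ValueError("'plus' strain must be PCD+")
        if self.minus.is_pcd_plus:
            raise ValueError("'minus' strain must be PCD-")
        if self.pcd_steps_per_round < 1:
            raise ValueError("pcd_steps_per_round must be >= 1")


def pcd_regrowth_round(
    state: PopulationState,
    plus: StrainParams,
    minus: StrainParams,
    env: EnvironmentParams,
    rng: np.random.Generator,
) -> PopulationState:
    """One stochastic round of PCD and same-total replacement.

    Each PCD+ cell dies independently with probability ``c``.  With
    probability ``r`` a dying cell is replaced by an own-genotype
    offspring of the same phenotype (switching with the PCD+ strain's
    ``p``); with probability ``1 - r`` it is replaced by a competitor
    offspring whose phenotype is drawn from the competitor's current
    phenotype frequencies and then switched with the competitor's ``p``.
    Total population is unchanged.  If the competitor is extinct, its
    share of replacements returns to the PCD+ genotype (drawn from the
    PCD+ phenotype frequencies), mirroring the deterministic convention.
    """
    if state.total == 0:
        raise ValueError("cannot run a PCD round on an empty population")
    c, r = plus.pcd_prob, env.assortment
    ap, bp = int(state.a_plus), int(state.b_plus)
    an, bn = int(state.a_minus), int(state.b_minus)

    d_a = rng.binomial(ap, c) if ap else 0
    d_b = rng.binomial(bp, c) if bp else 0
    ap -= d_a
    bp -= d_b

    own_a = rng.binomial(d_a, r) if d_a else 0
    own_b = rng.binomial(d_b, r) if d_b else 0
    sw_a = rng.binomial(own_a, plus.switch_prob) if own_a else 0
    sw_b = rng.binomial(own_b, plus.switch_prob) if own_b else 0
    ap += own_a - sw_a + sw_b
    bp += own_b - sw_b + sw_a

    n_comp = (d_a - own_a) + (d_b - own_b)
    if n_comp:
        g_minus = an + bn
        if g_minus > 0:
            p = minus.switch_prob
            prob_a = (an * (1 - p) + bn * p) / g_minus
            born_a = rng.binomial(n_comp, prob_a)
            an += born_a
            bn += n_comp - born_a
        else:
            # competitor extinct: spilled resources regrow the PCD+ strain
            g_plus = ap + bp
            p = plus.switch_prob
            prob_a = (ap * (1 - p) + bp * p) / g_plus if g_plus else 0.5
            born_a = rng.binomial(n_comp, prob_a)
            ap += born_a
            bp += n_comp - born_a
    return PopulationState(ap, bp, an, bn)


def apply_disaster(
    state: PopulationState,
    target: str,
    kill_fraction: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Kill a fraction of the targeted phenotype in both genotypes.

    ``kill_fraction = 1`` zeroes the targeted counts exactly; otherwise
    survivors are binomial with survival probability ``1 - kill_fraction``.
    """
    if target not in PHENOTYPES:
        raise ValueError(f"target must be one of {PHENOTYPES}, got {target!r}")
    ap, bp = int(state.a_plus), int(state.b_plus)
    an, bn = int(state.a_minus), int(state.b_minus)
    if kill_fraction == 1.0:
        if target == "A":
            ap = an = 0
        else:
            bp = bn = 0
    elif kill_fraction > 0.0:
        keep = 1.0 - kill_fraction
        if target == "A":
            ap = rng.binomial(ap, keep) if ap else 0
            an = rng.binomial(an, keep) if an else 0
        else:
            bp = rng.binomial(bp, keep) if bp else 0
            bn = rng.binomial(bn, keep) if bn else 0
    return PopulationState(ap, bp, an, bn)


def regrow_to_capacity(
    state: PopulationState,
    p_plus: float,
    p_minus: float,
    n_capacity: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Sequential births until the population is restored to capacity.

    Each birth's parent is drawn uniformly from the current, growing
    population; the offspring inherits the parent's genotype and
    phenotype, switching phenotype with that genotype's switch
    probability.  Raises on an all-extinct population — extinction is an
    outcome, never silently repopulated.
    """
    total = int(state.total)
    if total == 0:
        raise ValueError("cannot regrow an extinct population")
    if total > n_capacity:
        raise ValueError("population exceeds capacity")
    counts = np.array(
        [state.a_plus, state.b_plus, state.a_minus, state.b_minus], dtype=np.int64
    )
    draw_births(counts, n_capacity - total, p_plus, p_minus, rng)
    return PopulationState(*counts.tolist())


def _winner_at_cap(state: PopulationState) -> str:
    if state.g_plus > state.g_minus:
        return TIMEOUT_PLUS
    if state.g_minus > state.g_plus:
        return TIMEOUT_MINUS
    return TIMEOUT_TIE


def run_competition(
    params: CompetitionParams,
    max_rounds: int = 10_000,
    seed=None,
    initial_state: PopulationState | None = None,
    record_trajectory: bool = False,
) -> CompetitionResult:
    """Compete PCD+ against PCD- for up to ``max_rounds`` rounds.

    Each round: with probability ``d`` a disaster annihilates a uniformly
    chosen phenotype and the survivors regrow to capacity; then
    ``pcd_steps_per_round`` PCD/replacement steps run.  Terminates on
    genotype extinction, total extinction, or at the cap with the
    majority rule.
    """
    rng = np.random.default_rng(seed)
    env = params.env
    n_cap = env.carrying_capacity
    state = initial_state or PopulationState.quarters(n_cap)
    p_plus = params.plus.switch_prob
    p_minus = params.minus.switch_prob
    trajectory: list[RoundLog] = []

    winner = None
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        disaster = rng.random() < env.disaster_prob
        target = None
        if disaster:
            target = PHENOTYPES[rng.integers(2)]
            state = apply_disaster(state, target, env.kill_fraction, rng)
            if state.total == 0:
                winner = BOTH_EXTINCT
                break
            state = regrow_to_capacity(state, p_plus, p_minus, n_cap, rng)
        for _ in range(params.pcd_steps_per_round):
            state = pcd_regrowth_round(state, params.plus, params.minus, env, rng)
        if record_trajectory:
            trajectory.append(RoundLog(rounds, disaster, target, state))
        if state.g_plus == 0 and state.g_minus == 0:
            winner = BOTH_EXTINCT
            break
        if state.g_plus == 0:
            winner = PCD_MINUS
            break
        if state.g_minus == 0:
            winner = PCD_PLUS
            break
    if winner is None:
        winner = _winner_at_cap(state)
    return CompetitionResult(winner, rounds, trajectory, seed=None)


def _spawn_seeds(root_seed, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(root_seed).spawn(n)


def win_fraction_sweep(
    p_grid,
    c_grid,
    r_grid,
    d_grid,
    reps: int,
    seed,
    p_minus: float | None = None,
    n_capacity: int = 10_000,
    max_rounds: int = 10_000,
) -> pd.DataFrame:
    """PCD+ win fraction over a (p, c, r, d) parameter grid.

    For each combination runs ``reps`` independent competitions; the win
    fraction is PCD+ wins over competitions in which at least one strain
    survived (ties at the cap excluded likewise).  Each replicate's random
    stream derives from the root seed and the (combination, replicate)
    index, so extending the grid never perturbs existing rows.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    combos = list(itertools.product(p_grid, c_grid, r_grid, d_grid))
    seeds = _spawn_seeds(seed, len(combos))
    rows = []
    for (p, c, r, d), combo_seed in zip(combos, seeds):
        params = CompetitionParams(
            plus=StrainParams(p, c, is_pcd_plus=True),
            minus=StrainParams(p if p_minus is None else p_minus),
            env=EnvironmentParams(d, n_capacity, assortment=r),
        )
        tally = {
            "wins_plus": 0,
            "wins_minus": 0,
            "both_extinct": 0,
            "ties": 0,
        }
        for rep_seed in combo_seed.spawn(reps):
            result = run_competition(params, max_rounds=max_rounds, seed=rep_seed)
            if result.plus_won:
                tally["wins_plus"] += 1
            elif result.minus_won:
                tally["wins_minus"] += 1
            elif result.winner == BOTH_EXTINCT:
                tally["both_extinct"] += 1
            else:
                tally["ties"] += 1
        decided = tally["wins_plus"] + tally["wins_minus"]
        frac = tally["wins_plus"] / decided if decided else np.nan
        rows.append(
            {"p": p, "c": c, "r": r, "d": d, **tally, "win_fraction": frac}
        )
    return pd.DataFrame(rows)


def max_tolerated_pcd(
    d: float,
    r: float,
    p: float,
    c_grid,
    reps: int,
    seed,
    n_capacity: int = 10_000,
    max_rounds: int = 10_000,
) -> tuple[float, pd.DataFrame]:
    """Largest PCD rate in ``c_grid`` at which PCD+ still wins a majority.

    Returns (c_max, table); ``c_max`` is 0.0 when no tested rate is
    favored.  ``c_grid`` must be sorted ascending.
    """
    c_grid = list(c_grid)
    if any(b <= a for a, b in zip(c_grid, c_grid[1:])):
        raise ValueError("c_grid must be strictly increasing")
    table = win_fraction_sweep(
        [p], c_grid, [r], [d], reps, seed,
        n_capacity=n_capacity, max_rounds=max_rounds,
    )
    favored = table[table["win_fraction"] > 0.5]
    c_max = float(favored["c"].max()) if len(favored) else 0.0
    return c_max, table
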