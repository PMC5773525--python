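"""Closed-form cost/benefit theory of PCD-assisted bet hedging.

This layer holds the deterministic one-round map of the fixed-assortment
model and the closed-form expressions for the cost and benefit of
programmed cell death.  The central trade-off: between disasters a PCD+
genotype bleeds cells to its PCD- competitor at rate ``c * (1 - r)`` per
round (the cost), but the extra reproduction it triggers lets it
diversify between phenotypes through stochastic switching (the benefit).
Everything here is exact and serves as the oracle for the stochastic
modules.

Notation
--------
p : switch probability per reproduction
c : PCD probability per round (PCD+ strain only)
r : assortment — probability a PCD death is replaced by the same genotype
m : number of PCD+ cells at the start of a diversification window
N : carrying capacity
"""

from __future__ import annotations

import math

from .population import PopulationState

__all__ = [
    "deterministic_round",
    "cost_factor",
    "expected_switch_counts",
    "prob_exclusive_diversification",
    "optimal_switch_rate",
    "prob_pcd_extinction",
    "benefit_cost_ratio",
    "time_to_stationary_diversity",
]


def deterministic_round(
    state: PopulationState, c: float, r: float, p: float
) -> PopulationState:
    """Advance the real-valued four-type state one round of PCD and regrowth.

    Each PCD+ cell dies with probability ``c``.  A fraction ``r`` of the
    deaths is replaced by the PCD+ genotype itself (same phenotype, which
    then switches with probability ``p``); the remaining fraction ``1 - r``
    is replaced by the PCD- competitor, whose offspring phenotype follows
    the competitor's current phenotype frequencies and then switches with
    probability ``p``.  Total population is conserved exactly.

    When the competitor is extinct the resources it would have captured
    are returned to the PCD+ genotype in proportion to its own phenotype
    frequencies (only living cells can regrow), which is equivalent to a
    temporary ``r = 1``.

    Parameters
    ----------
    state
        Real-valued counts; all non-negative.
    c, r, p
        PCD, assortment and switch probabilities.

    Returns
    -------
    PopulationState
        The state one round later.
    """
    for name, value in (("c", c), ("r", r), ("p", p)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value!r}")

    ap, bp = state.a_plus, state.b_plus
    an, bn = state.a_minus, state.b_minus
    gp, gn = ap + bp, an + bn

    ap_next = ap - c * ap + c * r * (1 - p) * ap + p * r * c * bp
    bp_next = bp - c * bp + c * r * (1 - p) * bp + p * r * c * ap

    spilled = c * gp * (1 - r)  # resources not captured by the PCD+ genotype
    if gn > 0:
        fa, fb = an / gn, bn / gn
        an_next = an + spilled * (fa * (1 - p) + fb * p)
        bn_next = bn + spilled * (fb * (1 - p) + fa * p)
    else:
        an_next, bn_next = an, bn
        if gp > 0:
            fa, fb = ap / gp, bp / gp
            ap_next += spilled * (fa * (1 - p) + fb * p)
            bp_next += spilled * (fb * (1 - p) + fa * p)
    return PopulationState(ap_next, bp_next, an_next, bn_next)


def cost_factor(c: float, r: float, t: int) -> float:
    """Fractional decay of the PCD+ genotype after ``t`` rounds without disasters.

    Per round the PCD+ strain loses a fraction ``c`` of its cells and
    recaptures ``c * r`` of them, so after ``t`` rounds it has shrunk by
    ``(c * (r - 1) + 1) ** t``.  At perfect assortment (``r = 1``) the
    factor is 1 for any ``c`` and ``t``: PCD is then free.

    The factor does not involve the switch probability ``p``: the cost is
    borne by the genotype as a whole regardless of how it is partitioned
    between phenotypes.
    """
    if not 0.0 <= c <= 1.0 or not 0.0 <= r <= 1.0:
        raise ValueError("c and r must be probabilities")
    if t < 0:
        raise ValueError("t must be a non-negative integer")
    return (c * (r - 1.0) + 1.0) ** t


def expected_switch_counts(
    p: float, r: float, c: float, m: float
) -> tuple[float, float]:
    """Expected novel-phenotype cells created by one round of PCD/regrowth.

    Starting from ``m`` PCD+ cells of a single phenotype (the other
    phenotype having just been annihilated by a disaster), one round of
    PCD kills ``c * m`` of them in expectation.  Replacement births that
    switch phenotype create the missing phenotype: ``p * r * c * m`` in
    the PCD+ genotype and ``p * (1 - r) * c * m`` in the PCD- genotype.
    The split between the genotypes is governed solely by ``r``.

    Returns
    -------
    (float, float)
        Expected new-phenotype counts for (PCD+, PCD-); they sum to
        ``p * c * m``.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    return p * r * c * m, p * (1 - r) * c * m


def prob_exclusive_diversification(p: float, c: float, m: float, r: float) -> float:
    """Probability the PCD+ strain diversifies while the PCD- strain does not.

    With ``c * m`` expected replacement births split ``r : (1 - r)``
    between the genotypes, the PCD- strain gains no switched offspring
    with probability ``(1 - p) ** (c m (1 - r))`` while the PCD+ strain
    gains at least one with probability ``1 - (1 - p) ** (c m r)``; the
    product is::

        (1 - p) ** (c m (1 - r)) - (1 - p) ** (c m)

    Real-valued exponents are used as-is (the expression is an
    expectation-level approximation, not an integer-trial law).  Computed
    via ``log1p``/``expm1`` so that values of order 1e-7 at p ~ 1e-6 keep
    full relative precision.
    """
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 0.0
    log_q = math.log1p(-p)  # log(1 - p) < 0
    # (1-p)^{cm(1-r)} * (1 - (1-p)^{cmr})
    return math.exp(c * m * (1 - r) * log_q) * -math.expm1(c * m * r * log_q)


def optimal_switch_rate(c: float, m: float, r: float) -> float:
    """Switch probability maximizing :func:`prob_exclusive_diversification`.

    Setting the derivative in ``p`` to zero gives
    ``p* = 1 - (1 - r) ** (1 / (c m r))``.  For weak assortment
    (``r << 1``) the optimum corresponds to roughly one expected switched
    birth, ``p* * c * m ~ 1``.  The ``r = 1`` limit is ``p* = 1``.
    """
    if c * m * r <= 0:
        raise ValueError("c * m * r must be positive")
    if r >= 1.0:
        return 1.0
    return 1.0 - (1.0 - r) ** (1.0 / (c * m * r))


def prob_pcd_extinction(c: float, m: float, r: float) -> float:
    """Probability that PCD alone wipes out ``m`` PCD+ cells in one round.

    Requires every one of the ``m`` cells to die (probability ``c`` each)
    and be replaced by the competitor (probability ``1 - r`` each):
    ``(c (1 - r)) ** m``.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    return (c ** m) * ((1.0 - r) ** m)


def benefit_cost_ratio(p: float, c: float, m: float, r: float) -> float:
    """Odds that one PCD round is beneficial (exclusive diversification)
    rather than catastrophic (extinction by PCD).

    Evaluates::

        (1 - p)^{cm} ((1 - p)^{-cmr} - 1) / (c (1 - r))^m

    in log space — the denominator underflows to 0 in double precision
    already at modest ``m`` — and is algebraically identical to
    :func:`prob_exclusive_diversification` / :func:`prob_pcd_extinction`.

    Returns
    -------
    float
        The ratio; ``math.inf`` when the extinction probability is exactly
        zero (``c = 0`` or ``r = 1``), 0.0 when ``p`` is 0 or 1.
    """
    if c == 0.0 or r == 1.0:
        return math.inf
    if p == 0.0 or p == 1.0:
        return 0.0
    log_q = math.log1p(-p)
    # log numerator: cm*log(1-p) + log((1-p)^{-cmr} - 1), the latter via expm1
    log_num = c * m * log_q + math.log(math.expm1(-c * m * r * log_q))
    log_den = m * (math.log(c) + math.log1p(-r))
    return math.exp(log_num - log_den)


def time_to_stationary_diversity(p: float, tol: float = 0.005) -> int:
    """Generations for switching alone to equilibrate an initially uniform population.

    Iterates the expected minority-phenotype frequency
    ``x(t+1) = x(t) (1 - p) + (1 - x(t)) p`` from ``x(0) = 0`` and returns
    the first generation at which ``0.5 - x(t) <= tol``.  Equals
    ``ceil(ln(2 tol) / ln(1 - 2p))`` for ``p < 0.5``.  At typical microbial
    switch rates (p ~ 1e-3) this exceeds a thousand generations, which is
    the slowness that PCD-driven turnover alleviates.

    Parameters
    ----------
    p
        Switch probability per generation, in (0, 0.5].
    tol
        Distance from the 0.5 stationary point counted as "maximally
        diverse".  Default 0.005 (1% of the stationary value).
    """
    if not 0.0 < p <= 0.5:
        raise ValueError("p must be in (0, 0.5]")
    if not 0.0 < tol < 0.5:
        raise ValueError("tol must be in (0, 0.5); tol >= 0.5 holds at t = 0")
    x = 0.0
    t = 0
    # closed-form bound guards against an unbounded loop at tiny p
    if p < 0.5:
        bound = math.ceil(math.log(2 * tol) / math.log1p(-2 * p)) + 2
    else:
        bound = 2
    while 0.5 - x > tol:
        x = x * (1 - p) + (1 - x) * p
        t += 1
        if t > bound:  # pragma: no cover - closed form makes this unreachable
            raise RuntimeError("recursion failed to reach stationarity")
    return t
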