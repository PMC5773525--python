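"""Parameter containers shared by all three model layers.

Two microbial genotypes compete: a PCD+ strain that undergoes programmed
cell death at per-round probability ``c`` and a PCD- strain that does not.
Both diversify between two disaster-relevant phenotypes (A and B) by
stochastic phenotype switching at reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class StrainParams:
    """One genotype's heritable probabilities.

    Parameters
    ----------
    switch_prob
        Probability ``p`` that a reproduction event yields the alternate
        phenotype.
    pcd_prob
        Per-round probability ``c`` of programmed cell death.  Must be 0
        for a PCD- strain.
    is_pcd_plus
        Whether this strain carries the PCD machinery.
    """

    switch_prob: float
    pcd_prob: float = 0.0
    is_pcd_plus: bool = False

    def __post_init__(self) -> None:
        _check_prob("switch_prob", self.switch_prob)
        _check_prob("pcd_prob", self.pcd_prob)
        if not self.is_pcd_plus and self.pcd_prob != 0.0:
            raise ValueError("a PCD- strain must have pcd_prob == 0")


@dataclass(frozen=True)
class EnvironmentParams:
    """Shared environment: disasters, capacity and (fixed) assortment.

    ``assortment`` is the probability ``r`` that a cell dying from PCD is
    replaced by growth of its own genotype; it is only meaningful for the
    spatially-implicit model (the lattice and patch models measure it).
    ``kill_fraction`` is the fraction of the targeted phenotype removed by
    a disaster: 1.0 (annihilation) in the well-mixed and lattice models,
    0.99 in the patch-based agent model.
    """

    disaster_prob: float
    carrying_capacity: int = 10_000
    assortment: float = 0.5
    kill_fraction: float = 1.0

    def __post_init__(self) -> None:
        _check_prob("disaster_prob", self.disaster_prob)
        _check_prob("assortment", self.assortment)
        _check_prob("kill_fraction", self.kill_fraction)
        if self.carrying_capacity < 2:
            raise ValueError("carrying_capacity must be at least 2")
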