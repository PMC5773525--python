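"""Four-type population state for the spatially-implicit models.

Counts are indexed (A+, B+, A-, B-): two genotypes (PCD+ / PCD-), each
expressing two phenotypes (A / B).  Counts are integers in the stochastic
simulations and reals in the deterministic one-round map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PopulationState:
    """Counts of the four cell types.

    Attributes
    ----------
    a_plus, b_plus
        A- and B-phenotype counts of the PCD+ genotype.
    a_minus, b_minus
        A- and B-phenotype counts of the PCD- genotype.
    """

    a_plus: float
    b_plus: float
    a_minus: float
    b_minus: float

    def __post_init__(self) -> None:
        for name in ("a_plus", "b_plus", "a_minus", "b_minus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def g_plus(self) -> float:
        """Total PCD+ genotype count."""
        return self.a_plus + self.b_plus

    @property
    def g_minus(self) -> float:
        """Total PCD- genotype count."""
        return self.a_minus + self.b_minus

    @property
    def total(self) -> float:
        return self.g_plus + self.g_minus

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a_plus, self.b_plus, self.a_minus, self.b_minus], dtype=float
        )

    @classmethod
    def from_array(cls, arr) -> "PopulationState":
        a_plus, b_plus, a_minus, b_minus = arr
        return cls(a_plus, b_plus, a_minus, b_minus)

    @classmethod
    def quarters(cls, n: int) -> "PopulationState":
        """Equal split of capacity ``n`` across the four types."""
        q = n // 4
        return cls(q, q, q, q)
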