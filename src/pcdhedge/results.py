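"""Outcome bookkeeping shared by the well-mixed and lattice competitions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .population import PopulationState

# Winner labels.  Extinction outcomes are decided when a genotype total
# hits zero; timeout outcomes apply the majority rule at the round cap.
PCD_PLUS = "pcd_plus"
PCD_MINUS = "pcd_minus"
BOTH_EXTINCT = "both_extinct"
TIMEOUT_PLUS = "timeout_majority_pcd_plus"
TIMEOUT_MINUS = "timeout_majority_pcd_minus"
TIMEOUT_TIE = "timeout_tie"

WINNERS = (PCD_PLUS, PCD_MINUS, BOTH_EXTINCT, TIMEOUT_PLUS, TIMEOUT_MINUS, TIMEOUT_TIE)

#: outcomes counted as a PCD+ win in win-fraction statistics
PLUS_WINS = (PCD_PLUS, TIMEOUT_PLUS)
#: outcomes counted as a PCD- win
MINUS_WINS = (PCD_MINUS, TIMEOUT_MINUS)
#: outcomes excluded from win fractions entirely
EXCLUDED = (BOTH_EXTINCT, TIMEOUT_TIE)


@dataclass(frozen=True)
class RoundLog:
    """One round of a competition trajectory."""

    round_index: int
    disaster_occurred: bool
    disaster_target: Optional[str]  # "A" | "B", only when a disaster struck
    state: PopulationState

    def __post_init__(self) -> None:
        if self.disaster_occurred != (self.disaster_target is not None):
            raise ValueError("disaster_target must be recorded iff a disaster occurred")


@dataclass
class CompetitionResult:
    """Winner, duration and (optionally) the full per-round trajectory."""

    winner: str
    rounds_elapsed: int
    trajectory: list = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.winner not in WINNERS:
            raise ValueError(f"unknown winner label {self.winner!r}")

    @property
    def plus_won(self) -> bool:
        return self.winner in PLUS_WINS

    @property
    def minus_won(self) -> bool:
        return self.winner in MINUS_WINS

    @property
    def excluded(self) -> bool:
        return self.winner in EXCLUDED
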