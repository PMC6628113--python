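"""Shared record types for completed threshold measurements."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

from .errors import DomainError

__all__ = ["TrialRecord", "ThresholdRun"]

PEN_MIN, PEN_MAX = 1, 16


@dataclass(frozen=True)
class TrialRecord:
    """One presented triplet and its outcome.

    ``phase`` is "A" or "B" for the staircase and "-" for QUEST;
    ``proposed_level`` is the engine's real-valued proposal before rounding
    and clamping (QUEST only, NaN otherwise); ``target_position`` is the
    position (1-3) of the odor pen within the triplet.
    """

    trial_index: int
    presented_pen: int
    correct: bool
    phase: str = "-"
    proposed_level: float = float("nan")
    target_position: int = 0
    participant_id: str = ""
    session: str = ""
    procedure: str = ""

    def __post_init__(self) -> None:
        if not PEN_MIN <= self.presented_pen <= PEN_MAX:
            raise DomainError(
                f"presented_pen must be in [{PEN_MIN}, {PEN_MAX}],"
                f" got {self.presented_pen}"
            )
        if self.trial_index < 1:
            raise DomainError("trial_index is 1-based")


@dataclass(frozen=True)
class ThresholdRun:
    """One completed threshold measurement.

    ``raw_threshold`` may fall outside [1, 16] for QUEST (the posterior mean
    lives on a wider grid) and is NaN for staircase runs aborted by the trial
    cap before any reversal.  ``cleaned_threshold`` is None until the
    measurement has been passed through :func:`olfthresh.agreement.clean_run`.
    """

    procedure: str  # "staircase" | "quest"
    trials: tuple[TrialRecord, ...]
    raw_threshold: float
    pen1_ever_correct: bool
    hit_pen17: bool = False
    aborted: bool = False
    cleaned_threshold: float | None = None
    seed: int | None = None
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def n_trials_phase(self, phase: str) -> int:
        return sum(1 for t in self.trials if t.phase == phase)

    def with_cleaned(self, value: float) -> "ThresholdRun":
        return replace(self, cleaned_threshold=value)
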