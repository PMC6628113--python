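"""The standard Sniffin' Sticks one-up/two-down staircase.

The procedure has two phases.  Phase A finds the *starting concentration*:
beginning at pen 16 (or 15, balanced across participants), the pen is made
two steps stronger after every incorrect response; after a correct response
the same pen is repeated, and a second consecutive correct response fixes it
as the starting concentration.  Phase B is the threshold staircase proper:
one step stronger (pen - 1) after each incorrect response, one step weaker
(pen + 1) after two consecutive correct responses at the same pen.  A
*reversal* is logged at the pen where the walk changes direction (before the
move); the run ends at the seventh reversal and the raw threshold is the mean
of the last four reversal pens.

Boundary handling mirrors the study protocol: a demanded pen 0 is replaced by
pen 1 (presented repeatedly if need be; the data-cleaning step later assigns
T=1 to runs where pen 1 was never identified), while a demanded pen 17
terminates the run with the sentinel threshold 16.  The asymptotic
percent-correct target of the one-up/two-down rule is sqrt(1/2) = 70.71%,
although with the fixed one-pen step the realized convergence level sits a
few points lower (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigError, OlfthreshError, StateError
from .runs import PEN_MAX, PEN_MIN, ThresholdRun, TrialRecord

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "phase_a_step",
    "phase_b_step",
    "staircase_finalize",
    "staircase_run",
    "target_position",
]

_UP = -1   # toward stronger odor: pen number decreases
_DOWN = 1  # toward weaker odor: pen number increases


@dataclass(frozen=True)
class StaircaseConfig:
    start_pen: int = 16
    phase_a_step: int = 2
    phase_b_step: int = 1
    n_reversals: int = 7
    n_average: int = 4
    trial_cap: int = 200  # guards against never-correct responders at pen 1

    def __post_init__(self) -> None:
        if self.start_pen not in (15, 16):
            raise ConfigError("start_pen must be 15 or 16")
        if self.n_average > self.n_reversals:
            raise ConfigError("n_average cannot exceed n_reversals")
        if min(self.phase_a_step, self.phase_b_step, self.n_reversals,
               self.n_average, self.trial_cap) < 1:
            raise ConfigError("steps, counts and cap must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of a staircase in progress."""

    config: StaircaseConfig
    phase: str = "A"  # "A" | "B" | "done"
    current_pen: int = 16
    consecutive_correct: int = 0
    intended_direction: int | None = None  # -1 stronger, +1 weaker, None yet
    reversal_pens: tuple[int, ...] = ()
    n_trials: int = 0
    pen1_ever_correct: bool = False
    hit_pen17: bool = False

    @property
    def terminated(self) -> bool:
        return self.phase == "done"


def _note_pen1(state: StaircaseState, correct: bool) -> dict:
    if state.current_pen == PEN_MIN and correct:
        return {"pen1_ever_correct": True}
    return {}


def phase_a_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the starting-concentration search by one response."""
    if state.phase != "A":
        raise StateError("phase_a_step called outside phase A")
    upd = _note_pen1(state, correct)
    if correct:
        if state.consecutive_correct + 1 >= 2:
            # starting concentration found: phase B begins fresh at this pen
            return replace(state, phase="B", consecutive_correct=0,
                           n_trials=state.n_trials + 1, **upd)
        return replace(state, consecutive_correct=1,
                       n_trials=state.n_trials + 1, **upd)
    pen = max(PEN_MIN, state.current_pen - state.config.phase_a_step)
    return replace(state, current_pen=pen, consecutive_correct=0,
                   n_trials=state.n_trials + 1, **upd)


def phase_b_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the one-up/two-down staircase by one response."""
    if state.phase != "B":
        raise StateError("phase_b_step called outside phase B")
    cfg = state.config
    upd = _note_pen1(state, correct)

    if correct and state.consecutive_correct + 1 < 2:
        return replace(state, consecutive_correct=1,
                       n_trials=state.n_trials + 1, **upd)

    direction = _DOWN if correct else _UP
    reversals = state.reversal_pens
    if state.intended_direction is not None and direction != state.intended_direction:
        reversals = reversals + (state.current_pen,)

    if len(reversals) >= cfg.n_reversals:
        return replace(state, phase="done", reversal_pens=reversals,
                       consecutive_correct=0, intended_direction=direction,
                       n_trials=state.n_trials + 1, **upd)

    demanded = state.current_pen + direction * cfg.phase_b_step
    if demanded > PEN_MAX:
        # a hypothetical pen 17: terminate with the sentinel threshold
        return replace(state, phase="done", hit_pen17=True,
                       reversal_pens=reversals, consecutive_correct=0,
                       intended_direction=direction,
                       n_trials=state.n_trials + 1, **upd)
    pen = max(PEN_MIN, demanded)
    return replace(state, current_pen=pen, consecutive_correct=0,
                   intended_direction=direction, reversal_pens=reversals,
                   n_trials=state.n_trials + 1, **upd)


def staircase_finalize(state: StaircaseState) -> float:
    """Raw threshold: mean of the last ``n_average`` reversal pens.

    A run that ended on the pen-17 demand gets the sentinel value 16.
    """
    if not state.terminated:
        raise StateError("staircase has not terminated")
    if state.hit_pen17:
        return float(PEN_MAX)
    if not state.reversal_pens:
        return float("nan")
    tail = state.reversal_pens[-state.config.n_average:]
    return float(np.mean(tail))


def target_position(trial_index: int) -> int:
    """Position (1-3) of the odor pen within the triplet for the staircase.

    The schedule cycles 1, 2, 3, 1, 2, 3, ... over 1-based trial indices.
    (QUEST draws the position uniformly at random instead.)
    """
    if trial_index < 1:
        raise StateError("trial_index is 1-based")
    return (trial_index - 1) % 3 + 1


def staircase_run(
    config: StaircaseConfig,
    responder: Callable[[int], bool],
    seed: int | None = None,
    participant_id: str = "",
    session: str = "",
) -> ThresholdRun:
    """Run phase A then phase B to termination against a response callback.

    Deterministic given the responder (the triplet position schedule is fixed,
    so ``seed`` is recorded but never consumed).  The global ``trial_cap``
    aborts runs of responders that never answer correctly at pen 1.
    """
    state = StaircaseState(config=config, current_pen=config.start_pen)
    trials: list[TrialRecord] = []
    aborted = False
    try:
        while not state.terminated:
            if state.n_trials >= config.trial_cap:
                aborted = True
                break
            pen = state.current_pen
            phase = state.phase
            correct = bool(responder(pen))
            trials.append(
                TrialRecord(
                    trial_index=len(trials) + 1,
                    presented_pen=pen,
                    correct=correct,
                    phase=phase,
                    target_position=target_position(len(trials) + 1),
                    participant_id=participant_id,
                    session=session,
                    procedure="staircase",
                )
            )
            step = phase_a_step if phase == "A" else phase_b_step
            state = step(state, correct)
    except OlfthreshError:
        raise
    except Exception as exc:
        exc.partial_trials = tuple(trials)  # type: ignore[attr-defined]
        raise

    if aborted:
        raw = (
            float(np.mean(state.reversal_pens[-config.n_average:]))
            if state.reversal_pens else float("nan")
        )
    else:
        raw = staircase_finalize(state)
    return ThresholdRun(
        procedure="staircase",
        trials=tuple(trials),
        raw_threshold=raw,
        pen1_ever_correct=state.pen1_ever_correct,
        hit_pen17=state.hit_pen17,
        aborted=aborted,
        seed=seed,
        config=config.to_dict(),
    )
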