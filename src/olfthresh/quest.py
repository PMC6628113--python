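"""Bayesian adaptive (QUEST) threshold estimation on the discrete pen set.

The engine keeps a posterior over candidate thresholds on a fine grid.  The
candidate thresholds are anchored at the procedure's target probability
(80% correct by default), so "threshold" here literally means the pen level a
participant identifies correctly 80% of the time.  Each trial:

1. a real-valued level is proposed from the posterior (mode by default, the
   placement originally recommended for QUEST; mean and median are options),
2. the proposal is rounded to the nearest pen (ties toward the stronger,
   lower-numbered pen) and clamped into [1, 16],
3. if the same pen was presented on the two previous trials and both
   responses were correct, the next pen is one step weaker instead; if both
   were incorrect, one step stronger (re-clamped),
4. the posterior is updated with the Bernoulli likelihood of the *actually
   presented* pen and the observed response.

The run ends after a fixed number of trials (20) and the reported raw
threshold is the posterior mean, which may fall outside [1, 16]; the
data-cleaning step clamps it afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import psychometric as psy
from .errors import ConfigError, OlfthreshError, StateError
from .runs import PEN_MAX, PEN_MIN, ThresholdRun, TrialRecord

__all__ = [
    "PsychometricShape",
    "QuestConfig",
    "QuestState",
    "quest_init",
    "quest_propose",
    "quest_update",
    "quest_estimate",
    "quest_run",
]


@dataclass(frozen=True)
class PsychometricShape:
    """Assumed psychometric shape (all parameters except the threshold)."""

    beta: float = 3.5
    guess: float = 1.0 / 3.0
    lapse: float = 0.01

    def with_threshold(self, threshold: float, anchor_p: float | None) -> psy.WeibullParams:
        return psy.WeibullParams(
            threshold=threshold, beta=self.beta, guess=self.guess,
            lapse=self.lapse, anchor_p=anchor_p,
        )


@dataclass(frozen=True)
class QuestConfig:
    """Configuration of one adaptive run.

    Defaults follow the study protocol: prior normal(start_pen=7, sd=20) in
    pen units, grid step 0.01, grid spanning start_pen +/- 1.5 prior SDs
    (wide enough to represent the sub-pen-1 estimates that occur in
    practice), 20 trials, 80%-correct target.
    """

    assumed_pf: PsychometricShape = field(default_factory=PsychometricShape)
    target_p: float = 0.80
    start_pen: float = 7.0
    prior_sd: float = 20.0
    grid_step: float = 0.01
    grid_lo: float = -23.0
    grid_hi: float = 37.0
    n_trials: int = 20
    placement: str = "mode"  # "mode" | "mean" | "median"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        if not (self.grid_lo < PEN_MIN and self.grid_hi > PEN_MAX):
            raise ConfigError("grid must bracket the pen range [1, 16]")
        if self.prior_sd <= 0:
            raise ConfigError("prior_sd must be > 0")
        if self.placement not in ("mode", "mean", "median"):
            raise ConfigError(f"unknown placement rule {self.placement!r}")
        n_points = int(math.floor((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        if n_points < 2:
            raise ConfigError("grid must contain at least 2 points")

    def make_grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class QuestState:
    """Grid, log-posterior and trial history of one run (immutable)."""

    config: QuestConfig
    grid: np.ndarray
    log_posterior: np.ndarray
    history: tuple[tuple[float, int, bool], ...] = ()
    # history rows: (proposed_level, presented_pen, correct)

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)


def _normalize(logp: np.ndarray) -> np.ndarray:
    m = logp.max()
    w = np.exp(logp - m)
    return logp - (m + math.log(w.sum()))


def quest_init(config: QuestConfig) -> QuestState:
    """Start a run: posterior equals the normal prior evaluated on the grid."""
    grid = config.make_grid()
    if grid.size < 2:
        raise ConfigError("grid must contain at least 2 points")
    logp = -0.5 * ((grid - config.start_pen) / config.prior_sd) ** 2
    return QuestState(config=config, grid=grid, log_posterior=_normalize(logp))


def _likelihood(state: QuestState, pen: int) -> np.ndarray:
    cfg = state.config
    shape = cfg.assumed_pf
    d = psy.threshold_offset(cfg.target_p, shape.beta, shape.guess, shape.lapse)
    # candidate threshold t is anchored at target_p, so the psi midpoint is t+d
    return psy._psi(pen, state.grid + d, shape.beta, shape.guess, shape.lapse)


def quest_propose(state: QuestState) -> int:
    """Pen (1-16) to present next; see the module docstring for the rules."""
    if len(state.history) >= state.config.n_trials:
        raise StateError("run already complete")
    prop = proposed_level(state)
    pen = int(math.ceil(prop - 0.5))  # nearest pen, ties toward stronger
    pen = min(PEN_MAX, max(PEN_MIN, pen))
    h = state.history
    if len(h) >= 2 and h[-1][1] == h[-2][1]:
        if h[-1][2] and h[-2][2]:
            pen = min(PEN_MAX, h[-1][1] + 1)
        elif not h[-1][2] and not h[-2][2]:
            pen = max(PEN_MIN, h[-1][1] - 1)
    return pen


def proposed_level(state: QuestState) -> float:
    """The raw (real-valued) placement level before rounding and clamping."""
    post = state.posterior
    rule = state.config.placement
    if rule == "mean":
        return float(post @ state.grid)
    if rule == "median":
        return float(state.grid[np.searchsorted(np.cumsum(post), 0.5)])
    return float(state.grid[int(np.argmax(post))])


def quest_update(state: QuestState, presented_pen: int, correct: bool) -> QuestState:
    """Bayes update with the presented pen and response; returns a new state."""
    if not PEN_MIN <= presented_pen <= PEN_MAX:
        raise StateError(f"presented_pen must be in [{PEN_MIN}, {PEN_MAX}]")
    lik = _likelihood(state, presented_pen)
    lik = lik if correct else 1.0 - lik
    with np.errstate(divide="ignore"):
        logp = state.log_posterior + np.log(lik)
    if not np.isfinite(logp).any():
        raise StateError("posterior mass vanished (degenerate likelihood)")
    prop = proposed_level(state)
    return QuestState(
        config=state.config,
        grid=state.grid,
        log_posterior=_normalize(logp),
        history=state.history + ((prop, int(presented_pen), bool(correct)),),
    )


def quest_estimate(state: QuestState) -> float:
    """Posterior-mean threshold in pen units (valid mid-run as well)."""
    return float(state.posterior @ state.grid)


def quest_run(
    config: QuestConfig,
    responder: Callable[[int], bool],
    seed: int | None = None,
    participant_id: str = "",
    session: str = "",
) -> ThresholdRun:
    """Execute a full run against a response callback.

    ``seed`` drives only the random odor-pen position within each triplet
    (the simulated responder carries its own generator); identical seed and
    responder reproduce the run bit for bit.
    """
    rng = np.random.default_rng(seed)
    state = quest_init(config)
    trials: list[TrialRecord] = []
    pen1_ever_correct = False
    try:
        for i in range(config.n_trials):
            pen = quest_propose(state)
            prop = proposed_level(state)
            correct = bool(responder(pen))
            if pen == PEN_MIN and correct:
                pen1_ever_correct = True
            trials.append(
                TrialRecord(
                    trial_index=i + 1,
                    presented_pen=pen,
                    correct=correct,
                    phase="-",
                    proposed_level=prop,
                    target_position=int(rng.integers(1, 4)),
                    participant_id=participant_id,
                    session=session,
                    procedure="quest",
                )
            )
            state = quest_update(state, pen, correct)
    except OlfthreshError:
        raise
    except Exception as exc:
        # responder failure: abort, preserving the partial trial log
        exc.partial_trials = tuple(trials)  # type: ignore[attr-defined]
        raise
    return ThresholdRun(
        procedure="quest",
        trials=tuple(trials),
        raw_threshold=quest_estimate(state),
        pen1_ever_correct=pen1_ever_correct,
        hit_pen17=False,
        seed=seed,
        config=config.to_dict(),
    )
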