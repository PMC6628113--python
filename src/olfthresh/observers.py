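"""Simulated 3-AFC responders and a synthetic test-retest cohort generator.

The cohort generator stands in for a study sample: each participant gets a
true threshold drawn on the pen axis, responds to both procedures in a Test
and a Retest session through a Weibull observer, and the retest true
threshold is shifted by a systematic sensitivity gain plus session-to-session
drift.  Defaults mirror the study's printed summaries (threshold mean ~7,
between-participant SD ~3, ~1 pen-unit retest gain) and the assumed
psychometric shape (slope 3.5/pen, guess 1/3, lapse 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from . import agreement
from .errors import ConfigError
from .psychometric import WeibullParams, p_correct
from .quest import QuestConfig, quest_run
from .runs import PEN_MAX, PEN_MIN
from .staircase import StaircaseConfig, staircase_run

__all__ = [
    "ObserverSpec",
    "CohortSpec",
    "observer_respond",
    "make_responder",
    "generate_cohort",
    "COHORT_COLUMNS",
]


@dataclass(frozen=True)
class ObserverSpec:
    """A simulated responder: a Weibull observer or a pure 1/3 guesser."""

    kind: str = "weibull"  # "weibull" | "guesser"
    pf: WeibullParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("weibull", "guesser"):
            raise ConfigError(f"unknown observer kind {self.kind!r}")
        if self.kind == "weibull" and self.pf is None:
            raise ConfigError("weibull observer requires a psychometric function")


def observer_respond(pen: int, spec: ObserverSpec, rng: np.random.Generator) -> bool:
    """One Bernoulli response; consumes exactly one uniform draw."""
    u = rng.random()
    if spec.kind == "guesser":
        return u < 1.0 / 3.0
    return u < p_correct(pen, spec.pf)


def make_responder(spec: ObserverSpec, rng: np.random.Generator) -> Callable[[int], bool]:
    """Bind an observer and a generator into a pen -> correct callback."""
    return lambda pen: observer_respond(pen, spec, rng)


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of a synthetic test-retest sample.

    ``retest_shift`` is the systematic sensitivity gain at retest in pen
    units (positive = higher pens detected at retest) and ``within_sd`` the
    SD of the additional session-to-session drift of the true threshold.
    Drawn thresholds are clipped to the physical pen range [1, 16].
    """

    n_participants: int = 36
    true_threshold_mean: float = 7.0
    true_threshold_sd: float = 3.0
    within_sd: float = 2.0
    retest_shift: float = 1.0
    observer_beta: float = 3.5
    observer_lapse: float = 0.01
    seed: int = 0
    quest_config: QuestConfig = field(default_factory=QuestConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if min(self.true_threshold_sd, self.within_sd) < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.observer_beta <= 0 or not 0 <= self.observer_lapse < 0.5:
            raise ConfigError("invalid observer psychometric shape")

    def to_dict(self) -> dict:
        return asdict(self)


COHORT_COLUMNS = [
    "participant_id",
    "session",
    "procedure",
    "raw_threshold",
    "cleaned_threshold",
    "n_trials_phase_b",
    "pen1_ever_correct",
]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a full participant x session x procedure threshold table.

    For each participant a true Test threshold is drawn from
    normal(true_threshold_mean, true_threshold_sd); the Retest truth adds
    ``retest_shift`` plus normal(0, within_sd) drift; both are clipped to
    [1, 16].  Each session runs the staircase (start pen alternating 16/15
    across participants, as in the study) and QUEST against the participant's
    Weibull observer.  Returns one row per run with raw and cleaned
    thresholds, the phase-B trial count (total trials for QUEST) and the
    pen-1 identification flag.
    """
    root = np.random.SeedSequence(spec.seed)
    rows: list[dict] = []
    for i, child in enumerate(root.spawn(spec.n_participants)):
        kids = child.spawn(5)
        truth_rng = np.random.default_rng(kids[0])
        t_test = float(np.clip(
            truth_rng.normal(spec.true_threshold_mean, spec.true_threshold_sd),
            PEN_MIN, PEN_MAX))
        t_retest = float(np.clip(
            t_test + spec.retest_shift + truth_rng.normal(0.0, spec.within_sd),
            PEN_MIN, PEN_MAX))
        start_pen = 16 if i % 2 == 0 else 15
        kid_iter = iter(kids[1:])
        for session, truth in (("test", t_test), ("retest", t_retest)):
            pf = WeibullParams(threshold=truth, beta=spec.observer_beta,
                               guess=1.0 / 3.0, lapse=spec.observer_lapse)
            obs = ObserverSpec(kind="weibull", pf=pf)
            for procedure in ("staircase", "quest"):
                run_seed = int(next(kid_iter).generate_state(1)[0] % (2 ** 31))
                rng = np.random.default_rng(run_seed)
                responder = make_responder(obs, rng)
                if procedure == "staircase":
                    run = staircase_run(
                        StaircaseConfig(start_pen=start_pen), responder,
                        seed=run_seed, participant_id=f"p{i+1:03d}", session=session)
                    n_b = run.n_trials_phase("B")
                else:
                    run = quest_run(
                        spec.quest_config, responder,
                        seed=run_seed, participant_id=f"p{i+1:03d}", session=session)
                    n_b = run.n_trials
                run = agreement.clean_run(run)
                rows.append({
                    "participant_id": f"p{i+1:03d}",
                    "session": session,
                    "procedure": procedure,
                    "raw_threshold": run.raw_threshold,
                    "cleaned_threshold": run.cleaned_threshold,
                    "n_trials_phase_b": n_b,
                    "pen1_ever_correct": run.pen1_ever_correct,
                })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
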