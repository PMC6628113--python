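"""CSV trial logs, cohort tables and the deposited-data adapter.

Everything is plain UTF-8 CSV with '.' decimal separators: the study scale
is tiny and transparency beats compactness.  The deposited-data loader is an
adapter: it maps whatever per-run records a local copy of the study archive
contains onto the cohort schema, and fails with a descriptive schema error
when the layout is not recognized (it never downloads anything).
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError
from .observers import COHORT_COLUMNS
from .runs import ThresholdRun, TrialRecord

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "write_trial_log",
    "read_trial_log",
    "write_cohort",
    "read_cohort",
    "write_run_summary",
    "load_deposited",
]

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "session",
    "procedure",
    "trial_index",
    "phase",
    "proposed_level",
    "presented_pen",
    "target_position",
    "correct",
]


def write_trial_log(path: str | Path, records: Iterable[TrialRecord]) -> None:
    """Write trial records as CSV with a fixed header."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRIAL_LOG_COLUMNS)
        for r in records:
            w.writerow([
                r.participant_id, r.session, r.procedure, r.trial_index,
                r.phase,
                "" if math.isnan(r.proposed_level) else repr(r.proposed_level),
                r.presented_pen, r.target_position, int(r.correct),
            ])


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read a trial-log CSV back into records (inverse of write_trial_log)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file")
        if header != TRIAL_LOG_COLUMNS:
            raise SchemaError(
                f"{path}: unexpected header {header!r}; expected {TRIAL_LOG_COLUMNS!r}")
        out = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(TRIAL_LOG_COLUMNS):
                raise SchemaError(f"{path}: malformed row at line {lineno}")
            try:
                out.append(TrialRecord(
                    participant_id=row[0], session=row[1], procedure=row[2],
                    trial_index=int(row[3]), phase=row[4],
                    proposed_level=float(row[5]) if row[5] else float("nan"),
                    presented_pen=int(row[6]), target_position=int(row[7]),
                    correct=bool(int(row[8])),
                ))
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: malformed row at line {lineno}: {exc}")
    return out


def write_cohort(path: str | Path, dataset: pd.DataFrame) -> None:
    dataset.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: not a cohort table; missing columns {missing},"
            f" found {list(df.columns)}")
    return df


def write_run_summary(path: str | Path, run: ThresholdRun) -> None:
    """JSON echo of one completed run: config, seed, thresholds, flags."""
    payload = {
        "procedure": run.procedure,
        "seed": run.seed,
        "config": run.config,
        "raw_threshold": run.raw_threshold,
        "cleaned_threshold": run.cleaned_threshold,
        "pen1_ever_correct": run.pen1_ever_correct,
        "pen1_presented": any(t.presented_pen == 1 for t in run.trials),
        "hit_pen17": run.hit_pen17,
        "aborted": run.aborted,
        "n_trials": run.n_trials,
        "n_trials_phase_b": run.n_trials_phase("B") if run.procedure == "staircase"
        else run.n_trials,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable),
                          encoding="utf-8")


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return str(obj)


# ---------------------------------------------------------------------------
# deposited-data adapter

_COLUMN_ALIASES = {
    "participant_id": ["participant_id", "participant", "subject", "subj", "id"],
    "session": ["session", "visit"],
    "procedure": ["procedure", "method", "algorithm", "task"],
    "threshold": ["cleaned_threshold", "threshold", "thresh", "t", "estimate"],
}

_SESSION_MAP = {"test": "test", "1": "test", "t1": "test",
                "retest": "retest", "2": "retest", "t2": "retest"}
_PROCEDURE_MAP = {"staircase": "staircase", "stair": "staircase",
                  "quest": "quest"}


def load_deposited(path: str | Path) -> pd.DataFrame:
    """Map a local copy of the deposited study records onto the cohort schema.

    Accepts a CSV file (or a directory containing exactly one CSV) with one
    row per threshold measurement.  Column names are matched
    case-insensitively against common aliases; anything unrecognized raises a
    :class:`SchemaError` listing the columns that were found so the mapping
    can be extended.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no deposited data at {path}")
    if path.is_dir():
        candidates = sorted(path.glob("**/*.csv"))
        if len(candidates) != 1:
            raise SchemaError(
                f"{path}: expected exactly one CSV in the archive, found"
                f" {[str(c) for c in candidates]}")
        path = candidates[0]
    df = pd.read_csv(path)
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for target, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                resolved[target] = lower[a]
                break
    missing = [t for t in _COLUMN_ALIASES if t not in resolved]
    if missing:
        raise SchemaError(
            f"{path}: unrecognized layout; could not resolve {missing}."
            f" Columns found: {list(df.columns)}")
    out = pd.DataFrame({
        "participant_id": df[resolved["participant_id"]].astype(str),
        "session": df[resolved["session"]].astype(str).str.lower()
        .map(_SESSION_MAP),
        "procedure": df[resolved["procedure"]].astype(str).str.lower()
        .map(_PROCEDURE_MAP),
        "cleaned_threshold": pd.to_numeric(df[resolved["threshold"]],
                                           errors="coerce"),
    })
    if out["session"].isna().any() or out["procedure"].isna().any():
        raise SchemaError(
            f"{path}: unmapped session/procedure labels;"
            f" sessions={sorted(df[resolved['session']].astype(str).unique())},"
            f" procedures={sorted(df[resolved['procedure']].astype(str).unique())}")
    out["raw_threshold"] = out["cleaned_threshold"]
    out["n_trials_phase_b"] = pd.NA
    out["pen1_ever_correct"] = pd.NA
    return out[COHORT_COLUMNS]
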