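"""Data cleaning, reliability and agreement statistics for threshold runs.

Covers the study's analysis pipeline: extreme-pen cleaning rules, the TDI
composite, Wilcoxon / Spearman / OLS test-retest reliability, the
repeatability coefficient, Bland-Altman limits of agreement with exact-paired
confidence intervals (the noncentral-t tolerance-limit formulation), and the
variance-corrected limits used when two methods are compared through session
means.

Sign conventions match the study's tables: within a procedure differences are
Test - Retest, between procedures Staircase - QUEST.  Sample SDs use the
n - 1 denominator throughout, and cleaning is applied before every statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    StateError,
)
from .runs import PEN_MAX, PEN_MIN, ThresholdRun

__all__ = [
    "AgreementResult",
    "CorrectedLoa",
    "ReliabilityReport",
    "clean_threshold",
    "clean_run",
    "tdi_score",
    "repeatability",
    "loa_exact_ci",
    "corrected_loa",
    "reliability_report",
    "estimate_duration",
    "bland_altman_plot",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
SECONDS_PER_TRIAL = 28.5  # makes 20 trials come out at exactly 9.5 minutes


# ---------------------------------------------------------------------------
# cleaning and composite score

def clean_threshold(run: ThresholdRun) -> float:
    """Cleaned threshold in [1, 16] per the study's rules.

    Staircase: runs in which pen 1 was presented but never identified get
    T=1; runs that demanded the hypothetical pen 17 get T=16.  QUEST: the
    raw posterior mean is clamped into [1, 16].
    """
    if run.procedure == "staircase":
        if not run.trials and math.isnan(run.raw_threshold):
            raise StateError("cannot clean an empty, unterminated run")
        if run.hit_pen17:
            return float(PEN_MAX)
        pen1_presented = any(t.presented_pen == PEN_MIN for t in run.trials)
        if pen1_presented and not run.pen1_ever_correct:
            return float(PEN_MIN)
        if math.isnan(run.raw_threshold):
            # aborted before any reversal without touching pen 1: no estimate
            raise StateError("staircase run has no reversals to average")
        return float(min(PEN_MAX, max(PEN_MIN, run.raw_threshold)))
    if run.procedure == "quest":
        return float(min(PEN_MAX, max(PEN_MIN, run.raw_threshold)))
    raise StateError(f"unknown procedure {run.procedure!r}")


def clean_run(run: ThresholdRun) -> ThresholdRun:
    """Return a copy of the run with ``cleaned_threshold`` filled (idempotent)."""
    return replace(run, cleaned_threshold=clean_threshold(run))


def tdi_score(t: float, d: float, i: float) -> float:
    """Composite TDI score: threshold + discrimination + identification."""
    if not PEN_MIN <= t <= PEN_MAX:
        raise DomainError(f"threshold must be in [1, 16], got {t}")
    for name, v in (("discrimination", d), ("identification", i)):
        if not 0 <= v <= 16:
            raise DomainError(f"{name} score must be in [0, 16], got {v}")
    return float(t) + float(d) + float(i)


def estimate_duration(n_trials: float) -> float:
    """Testing duration in minutes at 28.5 s per triplet trial."""
    if n_trials < 0:
        raise DomainError("trial count cannot be negative")
    return n_trials * SECONDS_PER_TRIAL / 60.0


# ---------------------------------------------------------------------------
# Bland-Altman machinery

@dataclass(frozen=True)
class AgreementResult:
    """Mean difference, repeatability coefficient and limits of agreement."""

    n: int
    mean_diff: float
    sd_diff: float
    rc: float
    loa_low: float
    loa_high: float
    ci_low: tuple[float, float] | None = None   # CI for loa_low
    ci_high: tuple[float, float] | None = None  # CI for loa_high
    ci_mean: tuple[float, float] | None = None  # CI for mean_diff

    def to_dict(self) -> dict:
        return asdict(self)


def loa_exact_ci(
    mean_diff: float,
    sd_diff: float,
    n: int,
    coverage: float = 0.95,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Exact-paired confidence intervals for both 95% limits of agreement.

    Uses the noncentral-t characterization of one-sided tolerance limits:
    d_bar + (t'_{q}(n-1, 1.96*sqrt(n))/sqrt(n)) * s covers the upper limit
    with confidence q, which yields equal-tailed exact intervals for
    d_bar +/- 1.96 s.  Returns ``(ci_for_lower_limit, ci_for_upper_limit)``.
    """
    if n < 3:
        raise InsufficientDataError("need at least 3 paired differences")
    if not sd_diff > 0:
        raise DegenerateDataError("sd of differences is zero; limits have no CI")
    alpha = 1.0 - coverage
    nc = Z95 * math.sqrt(n)
    k_lo = stats.nct.ppf(alpha / 2.0, df=n - 1, nc=nc) / math.sqrt(n)
    k_hi = stats.nct.ppf(1.0 - alpha / 2.0, df=n - 1, nc=nc) / math.sqrt(n)
    upper = (mean_diff + k_lo * sd_diff, mean_diff + k_hi * sd_diff)
    lower = (mean_diff - k_hi * sd_diff, mean_diff - k_lo * sd_diff)
    return lower, upper


def repeatability(
    pairs: Iterable[tuple[float, float]] | np.ndarray,
    coverage: float = 0.95,
) -> AgreementResult:
    """Repeatability coefficient and limits of agreement for paired data.

    Differences are ``first - second`` (e.g. Test - Retest).  RC = 1.96 x SD
    of the differences; the limits are d_bar +/- 1.96 x SD with exact-paired
    CIs attached when the data admit them (zero-variance data still yield
    point limits, with the CIs left as None).
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be an (n, 2) array-like")
    n = arr.shape[0]
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    d = arr[:, 0] - arr[:, 1]
    if not np.all(np.isfinite(d)):
        raise DomainError("differences must be finite")
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    rc = Z95 * sd_diff
    loa_low, loa_high = mean_diff - rc, mean_diff + rc
    ci_low = ci_high = ci_mean = None
    if sd_diff > 0:
        ci_low, ci_high = loa_exact_ci(mean_diff, sd_diff, n, coverage)
        half = stats.t.ppf(1 - (1 - coverage) / 2, n - 1) * sd_diff / math.sqrt(n)
        ci_mean = (mean_diff - half, mean_diff + half)
    return AgreementResult(
        n=n, mean_diff=mean_diff, sd_diff=sd_diff, rc=rc,
        loa_low=loa_low, loa_high=loa_high,
        ci_low=ci_low, ci_high=ci_high, ci_mean=ci_mean,
    )


@dataclass(frozen=True)
class CorrectedLoa:
    """Variance-corrected limits of agreement for a two-method comparison.

    ``sigma_d_sq`` = s_dbar^2 + 0.5 s_xw^2 + 0.5 s_yw^2 restores the
    within-participant variance that averaging over sessions removes.
    """

    n: int
    mean_diff: float
    s_dbar_sq: float
    s_xw_sq: float
    s_yw_sq: float
    sigma_d_sq: float
    loa_low: float
    loa_high: float
    ci_low: tuple[float, float] | None = None
    ci_high: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def corrected_loa(
    dataset: pd.DataFrame,
    method_x: str = "staircase",
    method_y: str = "quest",
    value_col: str = "cleaned_threshold",
    coverage: float = 0.95,
) -> CorrectedLoa:
    """Corrected limits of agreement between two methods measured twice each.

    Expects a cohort table with columns participant_id, session
    (test/retest), procedure and a value column, complete for every
    participant.  Differences are method_x - method_y of the session means.
    CIs use the delta-method variance of the corrected limits (each variance
    component contributes 2 s^4 / df with df = n-1 for the session-mean
    differences and df = n for the within-method components).
    """
    wide = dataset.pivot_table(
        index="participant_id", columns=["procedure", "session"],
        values=value_col, aggfunc="first")
    needed = [(m, s) for m in (method_x, method_y) for s in ("test", "retest")]
    missing = [c for c in needed if c not in wide.columns]
    if missing or wide.loc[:, needed].isna().any().any():
        raise InsufficientDataError(
            f"every participant needs both sessions for both methods; missing {missing}"
        )
    n = wide.shape[0]
    if n < 2:
        raise InsufficientDataError("need at least 2 complete participants")
    x = wide[method_x]
    y = wide[method_y]
    d_bar = (x.mean(axis=1) - y.mean(axis=1)).to_numpy()
    mean_diff = float(d_bar.mean())
    s_dbar_sq = float(d_bar.var(ddof=1))
    s_xw_sq = float(((x["test"] - x["retest"]) ** 2).sum() / (2 * n))
    s_yw_sq = float(((y["test"] - y["retest"]) ** 2).sum() / (2 * n))
    sigma_d_sq = s_dbar_sq + 0.5 * s_xw_sq + 0.5 * s_yw_sq
    sigma_d = math.sqrt(sigma_d_sq)
    lo = mean_diff - Z95 * sigma_d
    hi = mean_diff + Z95 * sigma_d
    ci_lo = ci_hi = None
    if sigma_d_sq > 0 and n >= 3:
        var_sig2 = (2 * s_dbar_sq ** 2 / (n - 1)
                    + 0.25 * 2 * s_xw_sq ** 2 / n
                    + 0.25 * 2 * s_yw_sq ** 2 / n)
        var_sig = var_sig2 / (4 * sigma_d_sq)
        var_limit = s_dbar_sq / n + Z95 ** 2 * var_sig
        half = stats.t.ppf(1 - (1 - coverage) / 2, n - 1) * math.sqrt(var_limit)
        ci_lo = (lo - half, lo + half)
        ci_hi = (hi - half, hi + half)
    return CorrectedLoa(
        n=n, mean_diff=mean_diff, s_dbar_sq=s_dbar_sq,
        s_xw_sq=s_xw_sq, s_yw_sq=s_yw_sq, sigma_d_sq=sigma_d_sq,
        loa_low=lo, loa_high=hi, ci_low=ci_lo, ci_high=ci_hi,
    )


# ---------------------------------------------------------------------------
# reliability report

@dataclass(frozen=True)
class ReliabilityReport:
    """Paired-comparison summary: location test, rank correlation, OLS fit."""

    n: int
    label: str
    wilcoxon_w: float
    wilcoxon_p: float
    spearman_rho: float
    spearman_p: float
    ols_slope: float
    ols_intercept: float
    resid_shapiro_w: float
    resid_shapiro_p: float
    mean_first: float
    sd_first: float
    mean_second: float
    sd_second: float
    agreement: AgreementResult
    interval_rho: float | None = None
    interval_p: float | None = None

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _paired_report(
    first: np.ndarray,
    second: np.ndarray,
    label: str,
    intervals: np.ndarray | None = None,
) -> ReliabilityReport:
    import statsmodels.api as sm

    n = first.size
    d = first - second
    if np.unique(first).size < 2 or np.unique(second).size < 2:
        raise DegenerateDataError("constant input to rank statistics")
    if np.allclose(d, 0.0):
        # perfect agreement: the signed-rank statistic is undefined
        w_stat, w_p = float("nan"), 1.0
    else:
        w = stats.wilcoxon(first, second)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    rho = stats.spearmanr(first, second)
    ols = sm.OLS(second, sm.add_constant(first)).fit()
    resid = np.asarray(ols.resid)
    if np.ptp(resid) < 1e-12:
        sw_stat, sw_p = float("nan"), 1.0  # exact fit: residuals carry no shape
    else:
        sw = stats.shapiro(resid)
        sw_stat, sw_p = float(sw.statistic), float(sw.pvalue)
    agr = repeatability(np.column_stack([first, second]))
    irho = ip = None
    if intervals is not None:
        r = stats.spearmanr(intervals, d)
        irho, ip = float(r.statistic), float(r.pvalue)
    return ReliabilityReport(
        n=n, label=label,
        wilcoxon_w=w_stat, wilcoxon_p=w_p,
        spearman_rho=float(rho.statistic), spearman_p=float(rho.pvalue),
        ols_slope=float(ols.params[1]), ols_intercept=float(ols.params[0]),
        resid_shapiro_w=sw_stat, resid_shapiro_p=sw_p,
        mean_first=float(first.mean()), sd_first=float(first.std(ddof=1)),
        mean_second=float(second.mean()), sd_second=float(second.std(ddof=1)),
        agreement=agr, interval_rho=irho, interval_p=ip,
    )


def reliability_report(
    dataset: pd.DataFrame,
    mode: str = "testretest",
    procedure: str | None = None,
    value_col: str = "cleaned_threshold",
    intervals: pd.Series | None = None,
) -> ReliabilityReport:
    """Assemble the paired reliability analysis from a cohort table.

    ``mode="testretest"`` pairs Test vs Retest within ``procedure``
    (differences Test - Retest); ``mode="compare"`` pairs the per-participant
    session means of the staircase vs QUEST (differences Staircase - QUEST).
    ``intervals`` (days between sessions, indexed by participant) adds the
    optional interval-vs-difference rank correlation.  Cleaning must already
    be reflected in ``value_col``; statistics are delegated to scipy and
    statsmodels.
    """
    if mode == "testretest":
        if procedure is None:
            raise DomainError("testretest mode requires a procedure")
        sub = dataset[dataset["procedure"] == procedure]
        wide = sub.pivot_table(index="participant_id", columns="session",
                               values=value_col, aggfunc="first")
        if "test" not in wide.columns or "retest" not in wide.columns or \
                wide[["test", "retest"]].isna().any().any():
            raise InsufficientDataError("incomplete test/retest pairs")
        first, second = wide["test"].to_numpy(), wide["retest"].to_numpy()
        label = f"{procedure}: test vs retest"
    elif mode == "compare":
        wide = dataset.pivot_table(index="participant_id",
                                   columns=["procedure", "session"],
                                   values=value_col, aggfunc="first")
        try:
            first = wide["staircase"].mean(axis=1).to_numpy()
            second = wide["quest"].mean(axis=1).to_numpy()
        except KeyError as exc:
            raise InsufficientDataError(f"missing procedure column: {exc}")
        if np.isnan(first).any() or np.isnan(second).any():
            raise InsufficientDataError("incomplete session means")
        label = "session means: staircase vs quest"
    else:
        raise DomainError(f"unknown mode {mode!r}")
    if first.size < 3:
        raise InsufficientDataError("need at least 3 participants")
    iv = None
    if intervals is not None:
        idx = wide.index
        iv = intervals.reindex(idx).to_numpy(dtype=float)
        if np.isnan(iv).any():
            raise InsufficientDataError("intervals missing for some participants")
    return _paired_report(first, second, label, intervals=iv)


def bland_altman_plot(
    first: Sequence[float],
    second: Sequence[float],
    ax=None,
    label: str = "",
):
    """Scatter of differences vs means with d_bar, limits and shaded CIs."""
    import matplotlib.pyplot as plt

    first = np.asarray(first, float)
    second = np.asarray(second, float)
    res = repeatability(np.column_stack([first, second]))
    if ax is None:
        _, ax = plt.subplots()
    mean = (first + second) / 2.0
    diff = first - second
    ax.scatter(mean, diff, s=18, zorder=3)
    ax.axhline(res.mean_diff, color="k", lw=1)
    for lim, ci in ((res.loa_low, res.ci_low), (res.loa_high, res.ci_high)):
        ax.axhline(lim, color="k", lw=1, ls="--")
        if ci is not None:
            ax.axhspan(ci[0], ci[1], color="0.85", zorder=1)
    if res.ci_mean is not None:
        ax.axhspan(res.ci_mean[0], res.ci_mean[1], color="0.85", zorder=1)
    ax.set_xlabel("mean of measurements (pen units)")
    ax.set_ylabel("difference (pen units)")
    if label:
        ax.set_title(label)
    return ax
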