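import math

import numpy as np
import pandas as pd
import pytest

import matplotlib

matplotlib.use("Agg")

from olfthresh import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    ThresholdRun,
    TrialRecord,
    bland_altman_plot,
    clean_run,
    clean_threshold,
    corrected_loa,
    estimate_duration,
    loa_exact_ci,
    reliability_report,
    repeatability,
    tdi_score,
)

Z = 1.959963984540054


def fake_run(procedure, raw, pens=(), pen1_ever_correct=False, hit_pen17=False):
    trials = tuple(
        TrialRecord(trial_index=i + 1, presented_pen=p, correct=False,
                    phase="B" if procedure == "staircase" else "-")
        for i, p in enumerate(pens)
    )
    return ThresholdRun(procedure=procedure, trials=trials, raw_threshold=raw,
                        pen1_ever_correct=pen1_ever_correct,
                        hit_pen17=hit_pen17)


class TestCleaning:
    def test_untouched_staircase_value_passes_through(self):
        run = fake_run("staircase", 3.25, pens=(4, 3, 4))
        assert clean_threshold(run) == 3.25

    def test_staircase_with_unidentified_pen1_set_to_floor(self):
        run = fake_run("staircase", 2.0, pens=(2, 1, 1, 2))
        assert clean_threshold(run) == 1.0

    def test_staircase_with_identified_pen1_keeps_value(self):
        run = fake_run("staircase", 2.0, pens=(2, 1, 2), pen1_ever_correct=True)
        assert clean_threshold(run) == 2.0

    def test_pen17_sentinel(self):
        run = fake_run("staircase", 16.0, pens=(16, 16), hit_pen17=True)
        assert clean_threshold(run) == 16.0

    @pytest.mark.parametrize("raw, expected", [(0.42, 1.0), (-3.0, 1.0),
                                               (17.2, 16.0), (7.3, 7.3)])
    def test_quest_estimates_clamped(self, raw, expected):
        assert clean_threshold(fake_run("quest", raw, pens=(7,))) == expected

    def test_cleaning_is_idempotent(self):
        run = fake_run("staircase", 2.0, pens=(2, 1, 1))
        once = clean_run(run)
        twice = clean_run(once)
        assert once.cleaned_threshold == twice.cleaned_threshold == 1.0


class TestTdi:
    @pytest.mark.parametrize("args, expected",
                             [((7.5, 13, 13), 33.5), ((1, 0, 0), 1.0),
                              ((16, 16, 16), 48.0)])
    def test_composite_sum(self, args, expected):
        assert tdi_score(*args) == expected

    @pytest.mark.parametrize("args", [(0.5, 8, 8), (17, 8, 8), (8, -1, 8),
                                      (8, 8, 17)])
    def test_out_of_range_rejected(self, args):
        with pytest.raises(DomainError):
            tdi_score(*args)


class TestRepeatability:
    def test_zero_differences(self):
        res = repeatability([(5, 5), (7, 7), (9, 9)])
        assert res.mean_diff == 0.0
        assert res.rc == 0.0
        assert res.ci_low is None

    def test_alternating_differences(self):
        # diffs (2, -2, 2, -2): sd with n-1 denominator is sqrt(16/3)
        res = repeatability([(4, 2), (2, 4), (6, 4), (4, 6)])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(math.sqrt(16 / 3), rel=1e-12)
        assert res.rc == pytest.approx(Z * math.sqrt(16 / 3), rel=1e-12)
        assert res.rc == pytest.approx(4.5264, abs=2e-4)

    def test_rc_is_half_the_loa_width(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pairs = rng.normal(8, 2, size=(20, 2))
            res = repeatability(pairs)
            assert res.rc == pytest.approx((res.loa_high - res.loa_low) / 2,
                                           rel=1e-12)
            assert res.loa_low == pytest.approx(res.mean_diff - Z * res.sd_diff)
            assert res.loa_high == pytest.approx(res.mean_diff + Z * res.sd_diff)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            repeatability([(1, 2), (3, 4)])


class TestExactCi:
    def test_ci_brackets_its_limit(self):
        lower, upper = loa_exact_ci(0.5, 2.0, 36)
        assert lower[0] < 0.5 - Z * 2.0 < lower[1]
        assert upper[0] < 0.5 + Z * 2.0 < upper[1]

    @pytest.mark.parametrize("n", [30, 100, 400])
    def test_agrees_with_normal_approximation_for_large_n(self, n):
        # oracle: CI half-width ~ 1.96 * s * sqrt(3/n)
        _, upper = loa_exact_ci(0.0, 1.0, n)
        half = (upper[1] - upper[0]) / 2
        approx = Z * math.sqrt(3.0 / n)
        assert half == pytest.approx(approx, rel=0.10)

    def test_width_grows_as_n_shrinks(self):
        widths = []
        for n in (40, 20, 10, 5):
            _, upper = loa_exact_ci(0.0, 1.0, n)
            widths.append(upper[1] - upper[0])
        assert widths == sorted(widths)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            loa_exact_ci(0.0, 0.0, 10)
        with pytest.raises(InsufficientDataError):
            loa_exact_ci(0.0, 1.0, 2)


def two_method_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "session",
                                       "procedure", "cleaned_threshold"])


class TestCorrectedLoa:
    def worked_example(self):
        rows = []
        for pid, sc, qu in [("a", (6, 8), (5, 7)), ("b", (7, 9), (6, 8))]:
            for sess, v in zip(("test", "retest"), sc):
                rows.append((pid, sess, "staircase", v))
            for sess, v in zip(("test", "retest"), qu):
                rows.append((pid, sess, "quest", v))
        return two_method_frame(rows)

    def test_worked_example_components_and_limits(self):
        res = corrected_loa(self.worked_example())
        assert res.mean_diff == pytest.approx(1.0)
        assert res.s_dbar_sq == pytest.approx(0.0)
        assert res.s_xw_sq == pytest.approx(2.0)
        assert res.s_yw_sq == pytest.approx(2.0)
        assert res.sigma_d_sq == pytest.approx(2.0)
        assert res.loa_low == pytest.approx(-1.772, abs=1e-3)
        assert res.loa_high == pytest.approx(3.772, abs=1e-3)

    def test_variance_identity(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(12):
            for proc in ("staircase", "quest"):
                for sess in ("test", "retest"):
                    rows.append((f"p{i}", sess, proc, rng.normal(8, 2)))
        res = corrected_loa(two_method_frame(rows))
        assert res.sigma_d_sq == pytest.approx(
            res.s_dbar_sq + 0.5 * res.s_xw_sq + 0.5 * res.s_yw_sq, rel=1e-12)

    def test_zero_within_variance_reduces_to_session_mean_limits(self):
        rows = []
        for i, (x, y) in enumerate([(6, 5), (8, 6), (7, 7), (9, 6)]):
            for sess in ("test", "retest"):
                rows.append((f"p{i}", sess, "staircase", x))
                rows.append((f"p{i}", sess, "quest", y))
        df = two_method_frame(rows)
        res = corrected_loa(df)
        assert res.s_xw_sq == res.s_yw_sq == 0.0
        assert res.sigma_d_sq == pytest.approx(res.s_dbar_sq)

    def test_corrected_never_narrower_than_session_mean_limits(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(15):
            base = rng.normal(8, 2)
            for proc, off in (("staircase", 0.0), ("quest", -1.0)):
                for sess in ("test", "retest"):
                    rows.append((f"p{i}", sess, proc,
                                 base + off + rng.normal(0, 1.5)))
        df = two_method_frame(rows)
        res = corrected_loa(df)
        naive = Z * math.sqrt(res.s_dbar_sq)
        assert (res.loa_high - res.loa_low) / 2 >= naive

    def test_missing_cells_rejected(self):
        df = self.worked_example().iloc[:-1]
        with pytest.raises(InsufficientDataError):
            corrected_loa(df)


def cohort_frame(test_vals, retest_vals, procedure="quest"):
    rows = []
    for i, (t, r) in enumerate(zip(test_vals, retest_vals)):
        rows.append((f"p{i:02d}", "test", procedure, t))
        rows.append((f"p{i:02d}", "retest", procedure, r))
    return pd.DataFrame(rows, columns=["participant_id", "session",
                                       "procedure", "cleaned_threshold"])


class TestReliabilityReport:
    def test_identical_vectors_give_perfect_rho_and_zero_bias(self):
        vals = [4.0, 6.0, 8.0, 10.0, 12.0]
        rep = reliability_report(cohort_frame(vals, vals), procedure="quest")
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.agreement.mean_diff == 0.0
        assert math.isnan(rep.wilcoxon_w)  # signed-rank undefined on zero diffs
        assert rep.ols_slope == pytest.approx(1.0)

    def test_noisy_pairs_assemble_all_statistics(self):
        rng = np.random.default_rng(4)
        test = rng.normal(8, 3, 30)
        retest = test + rng.normal(0.5, 1.0, 30)
        rep = reliability_report(cohort_frame(test, retest), procedure="quest")
        assert -1 <= rep.spearman_rho <= 1
        assert rep.wilcoxon_p <= 1
        assert rep.agreement.n == 30
        assert rep.mean_first == pytest.approx(test.mean())
        # differences are Test - Retest
        assert rep.agreement.mean_diff == pytest.approx(
            float(np.mean(test - retest)))

    def test_interval_correlation_attached(self):
        rng = np.random.default_rng(5)
        test = rng.normal(8, 3, 20)
        retest = test + rng.normal(0, 1, 20)
        frame = cohort_frame(test, retest)
        intervals = pd.Series(rng.uniform(1, 9, 20),
                              index=[f"p{i:02d}" for i in range(20)])
        rep = reliability_report(frame, procedure="quest", intervals=intervals)
        assert rep.interval_rho is not None and -1 <= rep.interval_rho <= 1

    def test_constant_vector_rejected(self):
        frame = cohort_frame([5, 5, 5, 5], [6, 7, 8, 9])
        with pytest.raises(DegenerateDataError):
            reliability_report(frame, procedure="quest")

    def test_compare_mode_uses_session_means(self):
        rows = []
        for i, (sc, qu) in enumerate([((6, 8), (5, 7)), ((7, 9), (6, 8)),
                                      ((5, 5), (4, 6)), ((9, 7), (8, 7))]):
            for sess, v in zip(("test", "retest"), sc):
                rows.append((f"p{i}", sess, "staircase", v))
            for sess, v in zip(("test", "retest"), qu):
                rows.append((f"p{i}", sess, "quest", v))
        df = pd.DataFrame(rows, columns=["participant_id", "session",
                                         "procedure", "cleaned_threshold"])
        rep = reliability_report(df, mode="compare")
        # staircase minus quest session means: (7-6, 8-7, 5-5, 8-7.5)
        assert rep.agreement.mean_diff == pytest.approx(
            np.mean([1.0, 1.0, 0.0, 0.5]))

    def test_insufficient_participants(self):
        with pytest.raises(InsufficientDataError):
            reliability_report(cohort_frame([5], [6]), procedure="quest")


class TestDuration:
    @pytest.mark.parametrize("n, minutes", [(20, 9.5), (0, 0.0), (23.6, 11.21)])
    def test_trial_count_to_minutes(self, n, minutes):
        assert estimate_duration(n) == pytest.approx(minutes)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            estimate_duration(-1)


def test_bland_altman_plot_renders():
    rng = np.random.default_rng(6)
    first = rng.normal(8, 2, 25)
    second = first + rng.normal(0, 1, 25)
    ax = bland_altman_plot(first, second, label="demo")
    assert len(ax.lines) >= 3  # mean line plus two limit lines
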