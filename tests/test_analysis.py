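import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from inrkit import (
    SampleSizeResult,
    StatTest,
    compare_categorical,
    compare_continuous,
    cumulative_event_curves,
    event_summary,
    inr_distribution,
    sample_size_two_proportions,
)
from inrkit.analysis import percent


class TestContinuousGate:
    def test_normal_samples_take_t_test(self):
        rng = np.random.default_rng(0)
        c = compare_continuous(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert c.test is StatTest.T_TEST
        assert "mean" in c.summaries["group1"]

    def test_skewed_sample_takes_mann_whitney(self):
        rng = np.random.default_rng(0)
        c = compare_continuous(rng.exponential(1.0, 200), rng.normal(0, 1, 200))
        assert c.test is StatTest.MANN_WHITNEY
        assert "median" in c.summaries["group1"]

    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 100)
        c = compare_continuous(x, x.copy())
        assert c.p_value > 0.9

    def test_tiny_samples_refused(self):
        c = compare_continuous([1.0, 2.0], [1.0, 2.0, 3.0])
        assert c.test is StatTest.NONE
        assert c.p_value is None

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous([], [1.0, 2.0, 3.0])


def fisher_enumeration_p(table):
    """Independent Fisher oracle: enumerate all tables with the observed
    margins and sum the hypergeometric probabilities of tables at most as
    probable as the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyp(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = hyp(a)
    return sum(p for x in range(lo, hi + 1) if (p := hyp(x)) <= p_obs * (1 + 1e-9))


class TestCategoricalGate:
    def test_low_expected_count_takes_fisher(self):
        c = compare_categorical([[2, 10], [1, 12]])
        assert c.test is StatTest.FISHER_EXACT

    def test_large_table_takes_chi_square(self):
        c = compare_categorical([[100, 200], [150, 150]])
        assert c.test is StatTest.CHI_SQUARE

    def test_zero_cell_takes_fisher(self):
        c = compare_categorical([[24, 3101], [0, 2959]])
        assert c.test is StatTest.FISHER_EXACT
        assert c.p_value < 0.001

    def test_zero_margin_is_degenerate(self):
        c = compare_categorical([[0, 10], [0, 12]])
        assert c.test is StatTest.NONE
        assert c.p_value is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[1, -2], [3, 4]])

    def test_fisher_agrees_with_enumeration_oracle(self):
        """The Fisher path matches an exhaustive-enumeration oracle on small
        tables (N <= 40)."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(300):
            cells = rng.integers(0, 11, size=4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            (a, b), (c, d) = table
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            res = compare_categorical(table)
            if res.test is not StatTest.FISHER_EXACT:
                continue
            assert res.p_value == pytest.approx(fisher_enumeration_p(table), abs=1e-9)
            checked += 1
        assert checked > 50


class TestINRDistribution:
    def make_cohort_frames(self):
        registry = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "arm": ["non_web", "web"],
                "indications": ["atrial_fibrillation", "atrial_fibrillation"],
                "enroll_day": [0, 0],
                "exit_day": [180, 180],
            }
        )
        inr_log = pd.DataFrame(
            {
                "patient_id": ["a", "a", "a", "b", "b"],
                "inr": [1.7, 2.5, 3.6, 2.5, 4.8],
            }
        )
        return registry, inr_log

    def test_counts_and_percents(self):
        registry, inr_log = self.make_cohort_frames()
        table = inr_distribution(inr_log, registry)
        assert table.counts.loc["EXTREME_SUB", "non_web"] == 1
        assert table.counts.loc["THERAPEUTIC", "non_web"] == 1
        assert table.counts.loc["SUPRA", "non_web"] == 1
        assert table.counts.loc["EXTREME_SUPRA", "web"] == 1
        # per-arm percents recompute from counts
        assert table.percents.loc["THERAPEUTIC", "web"] == 50.0
        assert table.counts["non_web"].sum() == 3

    def test_single_record_is_100_percent(self):
        registry, _ = self.make_cohort_frames()
        inr_log = pd.DataFrame({"patient_id": ["a"], "inr": [2.5]})
        table = inr_distribution(inr_log, registry)
        assert table.percents.loc["THERAPEUTIC", "non_web"] == 100.0

    def test_empty_log_all_zero_no_tests(self):
        registry, _ = self.make_cohort_frames()
        table = inr_distribution(pd.DataFrame({"patient_id": [], "inr": []}), registry)
        assert int(table.counts.to_numpy().sum()) == 0
        assert all(t.p_value is None for t in table.row_tests.values())

    def test_unresolvable_patient_excluded_and_counted(self):
        registry, inr_log = self.make_cohort_frames()
        inr_log.loc[len(inr_log)] = {"patient_id": "ghost", "inr": 2.0}
        table = inr_distribution(inr_log, registry)
        assert table.n_excluded == 1


class TestEventSummary:
    def make_frames(self):
        registry = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(10)],
                "arm": ["non_web"] * 5 + ["web"] * 5,
                "indications": ["vte"] * 10,
                "enroll_day": [0] * 10,
                "exit_day": [180] * 10,
            }
        )
        events = pd.DataFrame(
            {
                "patient_id": ["p0", "p0", "p1", "p5"],
                "event_type": ["minor_bleed"] * 4,
                "day": [10, 40, 20, 30],
            }
        )
        return registry, events

    def test_first_event_per_patient_counts_once(self):
        registry, events = self.make_frames()
        out = event_summary(events, registry)
        c = out["minor_bleed"]
        assert c.summaries["non_web"]["count"] == 2  # p0 counted once
        assert c.summaries["web"]["count"] == 1
        assert c.summaries["non_web"]["total"] == 5

    def test_unknown_patient_raises_with_ids(self):
        registry, events = self.make_frames()
        events.loc[len(events)] = {"patient_id": "zz", "event_type": "minor_bleed", "day": 3}
        with pytest.raises(ValueError, match="zz"):
            event_summary(events, registry)

    def test_zero_events_gives_degenerate_rows(self):
        registry, _ = self.make_frames()
        out = event_summary(pd.DataFrame(columns=["patient_id", "event_type", "day"]), registry)
        assert out["severe_bleed"].summaries["web"]["count"] == 0
        assert out["severe_bleed"].test is StatTest.NONE  # zero event margin


class TestEventCurves:
    def make_registry(self, n_per_arm=10, follow=180):
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(2 * n_per_arm)],
                "arm": ["non_web"] * n_per_arm + ["web"] * n_per_arm,
                "indications": ["vte"] * 2 * n_per_arm,
                "enroll_day": [0] * 2 * n_per_arm,
                "exit_day": [follow] * 2 * n_per_arm,
            }
        )

    def test_event_free_cohort_has_flat_curves(self):
        registry = self.make_registry()
        ec = cumulative_event_curves(
            pd.DataFrame(columns=["patient_id", "event_type", "day"]), registry, "minor_bleed"
        )
        assert ec.p_value is None
        for arm_curve in ec.curves.values():
            assert (arm_curve["survival"] == 1.0).all()

    def test_single_event_steps_by_one_over_n(self):
        registry = self.make_registry(n_per_arm=10)
        events = pd.DataFrame(
            {"patient_id": ["p0"], "event_type": ["minor_bleed"], "day": [50]}
        )
        ec = cumulative_event_curves(events, registry, "minor_bleed")
        curve = ec.curves["non_web"]
        after = curve.loc[curve["time"] >= 50, "survival"].iloc[0]
        assert after == pytest.approx(1.0 - 1.0 / 10.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        """With every patient experiencing the event, the KM estimate equals
        the hand-computed empirical survival function (independent oracle)."""
        rng = np.random.default_rng(5)
        days = rng.integers(1, 170, size=12)
        registry = self.make_registry(n_per_arm=12)
        events = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(12)],
                "event_type": ["minor_bleed"] * 12,
                "day": days,
            }
        )
        ec = cumulative_event_curves(events, registry, "minor_bleed")
        curve = ec.curves["non_web"].set_index("time")["survival"]
        for t in np.unique(days):
            empirical = np.mean(days > t)
            assert curve.loc[float(t)] == pytest.approx(empirical)

    def test_earlier_denser_events_separate_curves(self):
        """An arm with earlier, more frequent events yields a smaller log-rank
        p than a label-shuffled comparison of the same data."""
        rng = np.random.default_rng(6)
        registry = self.make_registry(n_per_arm=40)
        nonweb_events = [f"p{i}" for i in range(24)]
        web_events = [f"p{40+i}" for i in range(8)]
        events = pd.DataFrame(
            {
                "patient_id": nonweb_events + web_events,
                "event_type": "minor_bleed",
                "day": np.concatenate(
                    [rng.integers(1, 60, 24), rng.integers(90, 170, 8)]
                ),
            }
        )
        ec = cumulative_event_curves(events, registry, "minor_bleed")
        shuffled = registry.copy()
        shuffled["arm"] = rng.permutation(shuffled["arm"].to_numpy())
        ec_null = cumulative_event_curves(events, shuffled, "minor_bleed")
        assert ec.p_value < 0.05
        assert ec.p_value < ec_null.p_value


class TestSampleSize:
    def test_attrition_chain(self):
        r = SampleSizeResult.from_evaluable(206, attrition=0.20)
        assert r.n_enrolled_per_group == 258
        assert r.n_total == 516

    def test_zero_attrition_identity(self):
        r = SampleSizeResult.from_evaluable(206, attrition=0.0)
        assert r.n_enrolled_per_group == 206

    def test_pooled_closed_form(self):
        """The pooled two-proportion formula, cross-checked against a direct
        recomputation of the closed form."""
        from scipy.stats import norm

        p1, p2, alpha, power = 0.731, 0.66, 0.05, 0.80
        z_a, z_b = norm.ppf(1 - alpha / 2), norm.ppf(power)
        pbar = (p1 + p2) / 2
        n_expected = math.ceil(
            (
                (z_a * math.sqrt(2 * pbar * (1 - pbar))
                 + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2)))
                / (p1 - p2)
            )
            ** 2
        )
        r = sample_size_two_proportions(p1, p2, alpha, power)
        assert r.n_evaluable_per_group == n_expected
        assert r.n_total == 2 * r.n_enrolled_per_group

    def test_superiority_framing_enforced(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.6, 0.7)
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.7, 0.7)


def test_percent_rounds_half_up_at_one_decimal():
    assert percent(165, 260) == 63.5
    assert percent(17, 259) == 6.6
    assert percent(1, 3) == 33.3
    assert percent(0, 0) == 0.0
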