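"""Outcome labeling, ROC/AUC, threshold selection, KM, and Cox."""

from fractions import Fraction

import numpy as np
import pytest

from nucleomorph.core_io import CaseRecord
from nucleomorph.prognostics import (
    confusion_metrics,
    cox_hr,
    kaplan_meier,
    label_outcomes,
    roc_auc,
    select_threshold,
    threshold_grid,
)


def make_case(cid, cause, t, followup=None):
    return CaseRecord(
        case_id=cid,
        roi_measurements=[{"area_sd": 8.0}],
        survival_time_months=t,
        cause=cause,
        followup_months=followup,
    )


def concordant_pair_auc(scores, labels):
    """Mann-Whitney AUC by explicit pair counting with tie correction."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLabelOutcomes:
    def test_unrelated_death_negative_for_roc_censored_for_km(self):
        cases = [
            make_case("a", "unrelated_death", 8.5),
            make_case("b", "tumor_related_death", 4.3),
        ]
        out = label_outcomes(cases, "tumor_related_death_anytime")
        assert out.labels.tolist() == [0, 1]
        assert out.events.tolist() == [0, 1]  # censored at 8.5 vs event at 4.3
        assert out.times.tolist() == [8.5, 4.3]

    def test_survivor_censored_at_followup(self):
        out = label_outcomes([make_case("a", "alive_or_lost", 0.0, followup=24.0)])
        assert out.times.tolist() == [24.0]
        assert out.events.tolist() == [0]

    def test_tumor_specific_12mo_excludes_late_deaths(self):
        cases = [
            make_case("a", "tumor_related_death", 24.0),
            make_case("b", "tumor_related_death", 6.0),
        ]
        out = label_outcomes(cases, "tumor_specific_12mo")
        assert out.labels.tolist() == [0, 1]

    def test_overall_12mo_counts_any_death(self):
        out = label_outcomes([make_case("a", "unrelated_death", 6.0)], "overall_12mo")
        assert out.labels.tolist() == [1]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            label_outcomes([make_case("a", "alive_or_lost", 20.0)], "nope")


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 8, 9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_hand_counted_example(self):
        # pos {3,5}, neg {1,4}: concordant pairs 3 of 4
        auc, _ = roc_auc([3, 5, 1, 4], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_shuffled_labels_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_concordant_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(concordant_pair_auc(scores, labels), rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.lognormal(1, 0.5, size=60)
        labels = (scores + rng.normal(0, 1, 60) > 3).astype(int)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.log(scores), labels)
        assert a1 == pytest.approx(a2)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self, rng):
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 60)]
        labels = np.r_[np.ones(40, int), np.zeros(60, int)]
        auc1, ci1 = roc_auc(scores, labels, n_boot=500, seed=7)
        auc2, ci2 = roc_auc(scores, labels, n_boot=500, seed=7)
        assert ci1 == ci2
        assert ci1[0] <= auc1 <= ci1[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestThresholdGrid:
    def test_unit_range(self):
        grid = threshold_grid([0.0, 1.0])
        assert len(grid) == 201
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert grid[1] == pytest.approx(0.005)

    def test_step_is_half_percent_of_range(self):
        grid = threshold_grid([10.0, 30.0])
        assert np.diff(grid) == pytest.approx(0.1)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            threshold_grid([5.0, 5.0])


class TestSelectThreshold:
    def test_separated_classes_full_sensitivity(self):
        scores = [10.0] * 4 + [1.0] * 6
        labels = [1] * 4 + [0] * 6
        r = select_threshold(scores, labels, Fraction(1))
        assert r.cutoff == pytest.approx(10.0)
        assert r.rates.sensitivity == 1.0
        assert r.rates.specificity == 1.0

    def test_highest_cutoff_matching_target_verified_exhaustively(self):
        # 13 positives at 5..17, target 10/13
        pos = list(range(5, 18))
        neg = [4.0, 6.0, 8.0]
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * 13 + [0] * 3)
        r = select_threshold(scores, labels, (10, 13))
        grid = threshold_grid(scores)
        hits = [
            c for c in grid
            if (scores[labels == 1] >= c).sum() == 10
        ]
        assert r.cutoff == pytest.approx(max(hits))
        assert r.tp == 10 and r.fn == 3

    def test_unachievable_target_lists_achievable(self):
        scores = [5.0, 5.0, 1.0]
        labels = [1, 1, 0]
        with pytest.raises(ValueError, match="achievable"):
            select_threshold(scores, labels, (1, 2))

    def test_returned_cutoff_at_least_matching_grid_point(self, rng):
        scores = rng.lognormal(2, 0.4, size=40)
        labels = (scores > np.median(scores)).astype(int)
        grid = threshold_grid(scores)
        c = grid[60]
        tp = int((scores[labels == 1] >= c).sum())
        r = select_threshold(scores, labels, (tp, int(labels.sum())))
        assert r.cutoff >= c - 1e-12


class TestConfusionMetrics:
    def test_study_sensitivity_10_of_13(self):
        rates = confusion_metrics(tp=10, fp=0, fn=3, tn=0)
        assert rates.sensitivity == pytest.approx(10 / 13)
        assert round(100 * rates.sensitivity, 1) == 76.9

    def test_study_precision_and_false_omission(self):
        # 83 negatives at specificity 89.2% -> tn 74, fp 9
        rates = confusion_metrics(tp=10, fp=9, fn=3, tn=74)
        assert round(100 * rates.precision, 1) == 52.6
        assert round(100 * rates.false_omission_rate, 1) == 3.9
        assert round(100 * rates.specificity, 1) == 89.2

    def test_undefined_precision_is_missing(self):
        rates = confusion_metrics(tp=0, fp=0, fn=2, tn=5)
        assert rates.precision is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        t, s, median = kaplan_meier([5, 8, 12], [0, 0, 0])
        assert np.all(s == 1.0)
        assert median is None

    def test_two_events_no_censoring_product_limit_by_hand(self):
        t, s, median = kaplan_meier([1.0, 2.0], [1, 1])
        s_at = dict(zip(t, s))
        assert s_at[1.0] == pytest.approx(0.5)
        assert s_at[2.0] == pytest.approx(0.0)
        assert median == 1.0

    def test_censoring_after_last_event_changes_nothing(self):
        # extending a censored follow-up beyond the last event leaves the
        # curve identical at every event time
        t1, s1, _ = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 0])
        t2, s2, _ = kaplan_meier([1.0, 2.0, 30.0], [1, 1, 0])
        for x in [1.0, 2.0]:
            i1 = np.searchsorted(t1, x, side="right") - 1
            i2 = np.searchsorted(t2, x, side="right") - 1
            assert s1[i1] == pytest.approx(s2[i2])

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, size=200)
        t, s, _ = kaplan_meier(times, np.ones(200, int))
        for q in [2.0, 5.0, 10.0, 20.0]:
            empirical = (times > q).mean()
            idx = np.searchsorted(t, q, side="right") - 1
            assert s[idx] == pytest.approx(empirical, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestCoxHR:
    def test_exchangeable_groups_hr_near_one(self, rng):
        times = rng.exponential(10, size=400)
        group = rng.integers(0, 2, size=400)
        fit = cox_hr(group, times, np.ones(400, int))
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_recovers_true_hr_2_at_n_2000(self):
        rng = np.random.default_rng(0)
        n = 2000
        group = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        lam = np.where(group == 1, 2.0, 1.0) * 0.1
        times = rng.exponential(1.0 / lam)
        fit = cox_hr(group, times, np.ones(n, int))
        assert fit.hazard_ratio == pytest.approx(2.0, abs=0.15)
        # log-HR within 3 Wald SEs of the generating value
        se = (np.log(fit.ci_high) - np.log(fit.hazard_ratio)) / 1.96
        assert abs(np.log(fit.hazard_ratio) - np.log(2.0)) < 3 * se

    def test_no_events_in_one_group_flagged_unstable(self):
        group = [0, 0, 0, 1, 1, 1]
        times = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        events = [1, 1, 0, 0, 0, 0]
        fit = cox_hr(group, times, events)
        assert fit.unstable

    def test_km_curves_attached_per_group(self, rng):
        group = np.r_[np.zeros(20, int), np.ones(20, int)]
        times = rng.exponential(5, size=40)
        fit = cox_hr(group, times, np.ones(40, int))
        assert set(fit.km_times) == {0, 1}
        assert all(np.all(np.diff(s) <= 0) for s in fit.km_survival.values())
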