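"""Statistical procedures against independent hand/enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sddetwin.stats import (
    detect_complete_separation,
    kaplan_meier,
    km_by_delay_tertiles,
    log_rank,
    mann_whitney_u,
    roc_auc,
    tertile_split,
)


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p of the rank-sum over all splits."""
    combined = sorted(a + b)
    n_a = len(a)
    observed = sum(sorted(combined).index(x) + 1 for x in sorted(a))
    stats = [sum(idx + 1 for idx in comb)
             for comb in itertools.combinations(range(len(combined)), n_a)]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(observed - mean) for s in stats)
    return extreme / len(stats)


def pairwise_auc(scores, labels):
    """Enumeration oracle: P(pos > neg) + 0.5 P(tie) over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMannWhitney:
    def test_disjoint_groups_exact_p(self):
        comp = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert comp.statistic == 0.0
        assert comp.p_value == pytest.approx(
            exact_rank_sum_p([1, 2, 3], [4, 5, 6]))
        assert comp.p_value == pytest.approx(0.1)

    def test_identical_tied_groups_midpoint_u(self):
        comp = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert comp.statistic == pytest.approx(2.0)  # n_a*n_b/2

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_u_statistics_sum_identity(self, a, b):
        u_a = mann_whitney_u(a, b).statistic
        u_b = mann_whitney_u(b, a).statistic
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(12345)
        rejections = sum(
            mann_whitney_u(rng.normal(size=12), rng.normal(size=12)).p_value < 0.05
            for _ in range(500))
        assert 0.02 <= rejections / 500 <= 0.09


class TestRocAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([1, 2, 3, 4], [1, 1, 0, 0], 0.0),
        ([1, 1, 2], [0, 1, 1], 0.75),          # tie counts one half
    ])
    def test_known_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels))

    @given(st.lists(st.tuples(st.floats(-10, 10), st.integers(0, 1)),
                    min_size=4, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_label_inversion_complements(self, data):
        scores = [s for s, _ in data]
        labels = [l for _, l in data]
        if len(set(labels)) < 2:
            return
        inverted = [1 - l for l in labels]
        assert roc_auc(scores, labels) + roc_auc(scores, inverted) == \
            pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestSeparationDiagnostic:
    def test_disjoint_ranges_complete(self):
        d = detect_complete_separation([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert d.separated and d.overlap_fraction == 0.0

    def test_interleaved_not_separated(self):
        scores = list(range(20))
        labels = [i % 2 for i in range(20)]
        assert not detect_complete_separation(scores, labels).separated

    def test_single_straggler_in_hundred_is_near_complete(self):
        scores = np.arange(100.0)
        labels = np.zeros(100, dtype=int)
        labels[80:] = 1
        labels[[79, 80]] = labels[[80, 79]]  # one inversion at the boundary
        d = detect_complete_separation(scores, labels)
        assert d.separated and d.n_overlap < 5


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = kaplan_meier([3.0, 5.0, 7.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_two_subject_product_limit(self):
        km = kaplan_meier([1.0, 2.0], [1, 1])
        assert km.survival_at(1.0) == pytest.approx(0.5)
        assert km.survival_at(2.0) == pytest.approx(0.0)
        np.testing.assert_array_equal(km.at_risk, [2, 1])
        np.testing.assert_array_equal(km.events, [1, 1])

    def test_three_subject_with_censoring(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(10.0, size=40)
        km = kaplan_meier(times, np.ones(40, dtype=int))
        for t in np.quantile(times, [0.2, 0.5, 0.9]):
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0], [1])


class TestLogRank:
    def test_identical_groups_zero_chi_square(self):
        g = ([1.0, 2.0, 3.0], [1, 0, 1])
        comp = log_rank([g, g])
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_observed_vs_expected(self):
        # events only in group A at t=1,2; B censored at the same times.
        # O_A - E_A = 1, Var = 0.25 + 0.25: chi2 = 1 / 0.5 = 2.
        comp = log_rank([([1.0, 2.0], [1, 1]), ([1.0, 2.0], [0, 0])])
        assert comp.statistic == pytest.approx(2.0)

    def test_p_matches_chi_square_survival(self):
        from scipy.stats import chi2
        comp = log_rank([([1.0, 2.0], [1, 1]), ([1.0, 2.0], [0, 0])])
        assert comp.p_value == pytest.approx(chi2.sf(comp.statistic, df=1))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            log_rank([([1.0], [0]), ([2.0], [0])])


class TestTertiles:
    def test_nine_value_split(self):
        assignment = tertile_split(list(range(1, 10)))
        np.testing.assert_array_equal(assignment, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_degenerate_identical_values_warns(self):
        with pytest.warns(UserWarning):
            assignment = tertile_split([2.0] * 5)
        assert np.all(assignment == 1)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant(self, values):
        values = np.array(values)
        perm = np.random.default_rng(0).permutation(len(values))
        direct = tertile_split(values)
        assert np.array_equal(direct[perm], tertile_split(values[perm]))


class TestDelayTertileCurves:
    def test_default_cohort_event_fraction_rises(self, default_cohort):
        curves, comparison, tert = km_by_delay_tertiles(default_cohort)
        ev = np.array([m.event_cv for m in default_cohort.metrics])
        fractions = [ev[tert == g].mean() for g in (1, 2, 3)]
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert comparison.p_value < 0.05
        assert len(curves) == 3

    def test_zero_event_cohort_flat_curves(self, default_cohort):
        import dataclasses
        no_events = dataclasses.replace(
            default_cohort,
            metrics=tuple(dataclasses.replace(m, event_cv=0)
                          for m in default_cohort.metrics))
        curves, comparison, _ = km_by_delay_tertiles(no_events)
        assert comparison is None
        for c in curves:
            assert np.all(c.survival == 1.0)
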