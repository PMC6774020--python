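import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as lifelines_logrank

from ctdna_tmi.survival import (
    NOT_REACHED,
    CutoffError,
    batch_two_sample_test,
    bh_adjust,
    gehan_wilcoxon_test,
    km_estimate,
    logrank_test,
    median_survival,
    roc_auc,
    subgroup_evaluation,
    two_sample_test,
    ward_cutoff_scan,
)


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate([10, 20, 30], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(25) == 1.0
        assert median_survival(curve) == NOT_REACHED

    def test_hand_product_limit(self):
        # censored at 5, events at 10 and 15: S(10)=1/2, S(15)=0, median 10
        curve = km_estimate([5, 10, 15], [False, True, True])
        assert curve.survival_at(10) == pytest.approx(0.5)
        assert curve.survival_at(15) == pytest.approx(0.0)
        assert median_survival(curve) == 10

    def test_single_event_steps_to_zero(self):
        curve = km_estimate([7], [True])
        assert curve.survival_at(6.9) == 1.0
        assert curve.survival_at(7) == 0.0

    def test_median_at_exact_half_takes_earliest_crossing(self):
        # two events: S hits exactly 0.5 at the first -> median = first time
        curve = km_estimate([4, 9], [True, True])
        assert median_survival(curve) == 4

    @given(
        st.lists(st.floats(1, 500), min_size=1, max_size=30),
    )
    @settings(max_examples=40, deadline=None)
    def test_equals_empirical_survival_without_censoring(self, times):
        times = np.asarray(times)
        curve = km_estimate(times, np.ones(times.size, bool))
        for t in times:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))


# moderate-effect toy set: chi-square p within 0.02 of the exhaustive
# permutation p for both weightings (4 vs 4, all 70 assignments)
TOY_TIMES = np.array([69.0, 21.0, 3.0, 6.0, 2.0, 12.0, 2.0, 18.0])
TOY_EVENTS = np.array([True, True, True, True, False, True, True, False])


class TestTwoSampleTests:
    def test_identical_groups_give_zero_statistic(self):
        t = [10, 20, 30]
        e = [True, True, False]
        for fn in (logrank_test, gehan_wilcoxon_test):
            res = fn(t, e, t, e)
            assert res.statistic == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        ta, ea = [5, 10, 40, 60], [True, True, False, True]
        tb, eb = [8, 22, 35], [True, False, True]
        for fn in (logrank_test, gehan_wilcoxon_test):
            assert fn(ta, ea, tb, eb).p_value == pytest.approx(
                fn(tb, eb, ta, ea).p_value
            )

    @pytest.mark.parametrize("fn,weighting", [
        (logrank_test, "logrank"),
        (gehan_wilcoxon_test, "gehan_wilcoxon"),
    ])
    def test_within_002_of_exhaustive_permutation(self, fn, weighting):
        n, k = len(TOY_TIMES), 4
        stats = {}
        for comb in itertools.combinations(range(n), k):
            mask = np.zeros(n, bool)
            mask[list(comb)] = True
            s, _ = batch_two_sample_test(
                TOY_TIMES, TOY_EVENTS, mask[None, :], weighting=weighting
            )
            stats[comb] = s[0]
        observed = stats[tuple(range(k))]
        perm_p = np.mean([v >= observed - 1e-12 for v in stats.values()])
        res = fn(TOY_TIMES[:k], TOY_EVENTS[:k], TOY_TIMES[k:], TOY_EVENTS[k:])
        assert abs(res.p_value - perm_p) <= 0.02

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(100, 30), rng.exponential(60, 30)
        ea, eb = rng.random(30) < 0.8, rng.random(30) < 0.8
        mine = logrank_test(ta, ea, tb, eb)
        ref = lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)
        mine_w = gehan_wilcoxon_test(ta, ea, tb, eb)
        ref_w = lifelines_logrank(
            ta, tb, event_observed_A=ea, event_observed_B=eb,
            weightings="wilcoxon",
        )
        assert mine_w.statistic == pytest.approx(ref_w.test_statistic, abs=1e-9)
        assert mine_w.p_value == pytest.approx(ref_w.p_value, abs=1e-9)

    def test_logrank_equals_gehan_when_all_events_at_one_time(self):
        ta, tb = [10, 10], [10, 10, 10]
        ea, eb = [True, True], [True, False, True]
        lr = logrank_test(ta, ea, tb, eb)
        gw = gehan_wilcoxon_test(ta, ea, tb, eb)
        assert lr.statistic == pytest.approx(gw.statistic)

    def test_zero_event_group_is_finite(self):
        res = logrank_test([50, 60], [False, False], [5, 8, 12], [True] * 3)
        assert math.isfinite(res.statistic)
        assert 0 <= res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1, 2], [True, True])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_matches_bruteforce_stepup_and_is_monotone(self, ps):
        adj = bh_adjust(ps)
        # independent step-up oracle
        p = np.asarray(ps, float)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            expected[idx] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= p - 1e-12)
        # re-adjusting adjusted values never lowers them
        assert np.all(bh_adjust(adj) >= adj - 1e-12)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11], [True, True, True, False, False])
        assert res.auc == 1.0
        assert res.ci_low <= res.auc <= res.ci_high

    def test_all_tied_scores(self):
        res = roc_auc([5, 5, 5, 5], [True, False, True, False])
        assert res.auc == pytest.approx(0.5)
        assert res.null_p == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])

    @given(
        st.lists(st.integers(0, 8), min_size=4, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_equals_pair_counting(self, scores, label_seed):
        rng = np.random.default_rng(label_seed)
        benefit = rng.random(len(scores)) < 0.5
        if benefit.all() or (~benefit).any() is False or (~benefit).sum() == 0:
            benefit[0], benefit[-1] = True, False
        res = roc_auc(scores, benefit)
        s = np.asarray(scores, float)
        pos, neg = s[~benefit], s[benefit]
        pairs = [(0.5 if x == y else float(x > y)) for x in pos for y in neg]
        assert res.auc == pytest.approx(np.mean(pairs), abs=1e-12)


def _brute_force_scan(values, time, event, min_group, test):
    values = np.asarray(values, float)
    distinct = np.unique(values)
    best = None
    profile = []
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cand = (lo + hi) / 2
        low = values < cand
        if low.sum() < min_group or (~low).sum() < min_group:
            continue
        res = two_sample_test(
            np.asarray(time)[low], np.asarray(event)[low],
            np.asarray(time)[~low], np.asarray(event)[~low], test
        )
        profile.append((cand, res.p_value))
        if best is None or res.p_value < best[1]:
            best = (cand, res.p_value)
    return best, profile


class TestWardScan:
    def test_single_admissible_candidate(self):
        values = [1, 1, 1, 2, 2, 2]
        time = [100, 90, 80, 20, 25, 30]
        event = [True] * 6
        res = ward_cutoff_scan(values, time, event, min_group=3)
        assert res.cutoff == pytest.approx(1.5)
        assert len(res.p_profile) == 1

    def test_equals_bruteforce_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(10, 40))
            values = rng.integers(0, 12, n).astype(float)
            time = rng.exponential(100, n) + 1
            event = rng.random(n) < 0.8
            if np.unique(values).size < 2:
                continue
            for test in ("gehan", "logrank"):
                try:
                    res = ward_cutoff_scan(values, time, event, min_group=3,
                                           test=test)
                except CutoffError:
                    best, _ = _brute_force_scan(values, time, event, 3, test)
                    assert best is None
                    continue
                best, profile = _brute_force_scan(values, time, event, 3, test)
                assert res.cutoff == pytest.approx(best[0])
                assert res.chosen_p == pytest.approx(best[1], abs=1e-12)
                assert len(res.p_profile) == len(profile)
                assert res.chosen_p == pytest.approx(
                    min(p for _, p in res.p_profile), abs=1e-15
                )

    def test_all_equal_values_rejected(self):
        with pytest.raises(CutoffError):
            ward_cutoff_scan([3] * 10, np.arange(1, 11), [True] * 10)

    def test_no_admissible_split_rejected(self):
        with pytest.raises(CutoffError):
            ward_cutoff_scan([1, 2, 2, 2, 2, 2], np.arange(1, 7), [True] * 6,
                             min_group=3)


class TestSubgroupEvaluation:
    def test_full_cohort_subgroup_matches_direct_calls(self, default_cohort):
        import pandas as pd

        clinical = default_cohort.clinical.iloc[:40]
        rng = np.random.default_rng(0)
        responder = pd.Series(rng.random(len(clinical)) < 0.5,
                              index=clinical.index)
        scores = pd.Series(rng.integers(0, 30, len(clinical)).astype(float),
                           index=clinical.index)
        benefit = pd.Series(rng.random(len(clinical)) < 0.5,
                            index=clinical.index, dtype=object)
        out = subgroup_evaluation(
            clinical, responder, scores, benefit, benefit,
            subgroups={"all": lambda c: c["metastases"] >= 0},
        )["all"]
        direct_km = two_sample_test(
            clinical.loc[responder, "pfs_days"],
            clinical.loc[responder, "pfs_event"],
            clinical.loc[~responder, "pfs_days"],
            clinical.loc[~responder, "pfs_event"],
            "gehan",
        )
        direct_roc = roc_auc(scores.to_numpy(), benefit.astype(bool).to_numpy())
        assert out.status == "ok"
        assert out.km_pfs_p == pytest.approx(direct_km.p_value)
        assert out.auc_pfs == pytest.approx(direct_roc.auc)

    def test_one_sided_predictor_class_not_evaluable(self, default_cohort):
        import pandas as pd

        clinical = default_cohort.clinical.iloc[:20]
        responder = pd.Series(True, index=clinical.index)
        scores = pd.Series(1.0, index=clinical.index)
        labels = pd.Series(True, index=clinical.index, dtype=object)
        out = subgroup_evaluation(
            clinical, responder, scores, labels, labels,
            subgroups={"all": lambda c: c["metastases"] >= 0},
        )["all"]
        assert out.status == "not_evaluable"
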