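"""Cumulative patient scores, cohort filters, the hand-rolled log-rank test
against lifelines and a permutation oracle, cutpoint optimality, and
stratification behaviour under planted and null hazards."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as lifelines_logrank

from crcs.survival import (
    BLACsConfig,
    PatientProfile,
    ThresholdConstraints,
    blacs_score,
    chi2_scan,
    cohort_filters,
    km_curve,
    logrank_test,
    optimal_threshold,
    stratify_and_test,
)
from crcs.simulate import SurvivalSimConfig, simulate_survival_cohort


class TestBlacsScore:
    def test_closed_forms(self):
        assert blacs_score([0.0, 0.0], 4) == 0.0
        assert blacs_score([1.0, 1.0, 1.0], 4) == 15.0
        assert blacs_score([0.5, 1.0], 4) == pytest.approx(9.0)

    def test_bounds_and_order_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.random(20)
        v = blacs_score(s, 4)
        assert 0.0 <= v <= 15.0
        assert blacs_score(s[::-1], 4) == pytest.approx(v)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10),
        st.integers(min_value=0, max_value=9),
    )
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_any_single_score(self, scores, which):
        which %= len(scores)
        if scores[which] > 0.999:
            scores[which] = 0.5
        bumped = list(scores)
        bumped[which] = min(1.0, scores[which] + 1e-3)
        assert blacs_score(bumped, 4) > blacs_score(scores, 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            blacs_score([], 4)


def patient(pid, ct, n_mut, time, event):
    return PatientProfile(pid, ct, [0.5] * n_mut, time, event)


class TestCohortFilters:
    def test_sparse_patients_then_sparse_types(self):
        cfg = BLACsConfig(min_mutations=5, min_patients_per_type=3)
        patients = (
            [patient(f"a{i}", "X", 5, 10, 1) for i in range(3)]
            + [patient("drop", "X", 4, 10, 1)]
            + [patient(f"b{i}", "Y", 6, 10, 1) for i in range(2)]
        )
        kept = cohort_filters(patients, cfg)
        assert set(kept) == {"X"}
        assert len(kept["X"]) == 3

    def test_empty_input(self):
        assert cohort_filters([], BLACsConfig()) == {}


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_accumulated_oracle(self):
        """A dies at t=1,2; B dies at t=3,4; no censoring.  O-E and the
        hypergeometric variance accumulated by hand."""
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        # t=1: n=4, n1=2, d=1 -> e=0.5, v=(1)(2/4)(2/4)(3/3)=0.25
        # t=2: n=3, n1=1, d=1 -> e=1/3, v=(1/3)(2/3)(2/2)=2/9
        # t=3: n=2, n1=0, d=1 -> e=0,   v=0... n1=0 so terms vanish
        # t=4: n=1 -> variance term 0
        o_minus_e = (1 - 0.5) + (1 - 1 / 3) + 0 + 0
        var = 0.25 + 2 / 9
        assert chi2 == pytest.approx(o_minus_e**2 / var)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(10, 25), rng.exponential(15, 30)
        ea = (rng.random(25) < 0.7).astype(int)
        eb = (rng.random(30) < 0.7).astype(int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = lifelines_logrank(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_permutation_reference(self):
        """Chi-square p agrees with a permutation reference within
        Monte-Carlo error on a small uncensored sample."""
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 20)
        events = np.ones(20, dtype=int)
        in_a = np.zeros(20, dtype=bool)
        in_a[:9] = True
        chi2, p = logrank_test(times[in_a], events[in_a], times[~in_a], events[~in_a])
        n_perm, hits = 2000, 0
        for _ in range(n_perm):
            perm = rng.permutation(20)
            pa = perm[:9]
            pb = perm[9:]
            c, _ = logrank_test(times[pa], events[pa], times[pb], events[pb])
            hits += c >= chi2 - 1e-12
        assert p == pytest.approx(hits / n_perm, abs=0.04)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestOptimalThreshold:
    CONS = ThresholdConstraints(min_fraction=0.1, min_group=2)

    def test_sharp_split_recovered(self):
        scores = np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        times = np.where(scores <= 2, 20.0, 2.0) + np.tile([0.0, 0.1, 0.2], 4)
        events = np.ones_like(times, dtype=int)
        thr = optimal_threshold(scores, times, events, self.CONS)
        assert 2.0 < thr < 3.0

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold([1.0] * 10, np.arange(10.0), np.ones(10), self.CONS)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        times = rng.exponential(5, 30)
        events = (rng.random(30) < 0.8).astype(int)
        thr = optimal_threshold(scores, times, events, self.CONS)
        perm = rng.permutation(30)
        thr2 = optimal_threshold(scores[perm], times[perm], events[perm], self.CONS)
        assert thr == pytest.approx(thr2)

    def test_returned_cutpoint_maximizes_scan(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        times = rng.exponential(5, 40)
        events = (rng.random(40) < 0.7).astype(int)
        cuts, chi2s = chi2_scan(scores, times, events, self.CONS)
        thr = optimal_threshold(scores, times, events, self.CONS)
        best = chi2s[np.searchsorted(cuts, thr)]
        assert best >= chi2s.max() - 1e-12


def test_km_equals_empirical_survival_without_censoring():
    times = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
    curve = km_curve(times, np.ones(5, dtype=int))
    for t, s in zip(curve["time"], curve["survival"]):
        assert s == pytest.approx(np.mean(times > t))


class TestStratifyAndTest:
    def test_planted_hazard_recovered(self):
        cohort = simulate_survival_cohort(
            SurvivalSimConfig(n_patients=150, gamma=0.5, seed=0)
        )
        cfg = BLACsConfig(min_patients_per_type=100, n_permutations=100, seed=0)
        kept = cohort_filters(cohort, cfg)
        (res,) = stratify_and_test([p for ps in kept.values() for p in ps], cfg).values()
        assert res.adjusted_p_value < 0.1
        # high-risk group dies faster
        med_high = np.median(res.km_curves["high"]["time"])
        med_low = np.median(res.km_curves["low"]["time"])
        assert med_high < med_low

    def test_null_calibration_of_adjusted_p(self):
        """With gamma = 0 the selection-adjusted p rejects at roughly the
        nominal rate despite the maximised cutpoint."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            cohort = simulate_survival_cohort(
                SurvivalSimConfig(n_patients=120, gamma=0.0, seed=200 + seed)
            )
            cfg = BLACsConfig(n_permutations=60, seed=seed)
            (res,) = stratify_and_test(cohort, cfg).values()
            hits += res.adjusted_p_value < 0.1
        se = np.sqrt(0.1 * 0.9 / n_rep)
        assert hits / n_rep <= 0.1 + 3 * se

    def test_single_cancer_type_single_cohort(self):
        cohort = simulate_survival_cohort(SurvivalSimConfig(n_patients=60, seed=3))
        cfg = BLACsConfig(n_permutations=0, seed=3)
        out = stratify_and_test(cohort, cfg)
        assert list(out) == ["SYN"]
        res = out["SYN"]
        assert set(res.risk_group) == {"high", "low"}
        assert (res.scores >= res.threshold).sum() == (res.risk_group == "high").sum()
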