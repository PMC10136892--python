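"""Kaplan-Meier, log-rank, Cox PH and the dichotomized PFS analysis."""

import numpy as np
import pandas as pd
import pytest

from radpet.errors import DegenerateSplitError, NoEventsError
from radpet.survival import (cox_fit, dichotomized_pfs_analysis, km_estimate,
                             logrank_test, survival_at)
from radpet.synthetic import SyntheticConfig, draw_outcomes

from oracles import bf_km


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        curve = km_estimate([5, 10, 15], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(curve.at_risk) == [3, 2, 1]

    def test_censored_subject_leaves_risk_set(self):
        # times (5, 10+, 15): S(5) = 2/3, then 15 is the last subject at risk
        curve = km_estimate([5, 10, 15], [1, 0, 1])
        assert survival_at(curve, 5) == pytest.approx(2 / 3)
        assert survival_at(curve, 15) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([3, 6, 9], [0, 0, 0])
        for t in (0, 5, 20):
            assert survival_at(curve, t) == 1.0

    def test_matches_hand_product_limit_with_censoring(self, rng):
        times = rng.integers(1, 20, 40).astype(float)
        events = rng.integers(0, 2, 40).astype(bool)
        if not events.any():
            events[0] = True
        curve = km_estimate(times, events)
        ref_t, ref_s = bf_km(times, events)
        assert curve.event_times == pytest.approx(ref_t)
        assert curve.survival == pytest.approx(ref_s)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(5, 60)
        curve = km_estimate(times, np.ones(60, bool))
        for t in (1.0, 3.0, 8.0):
            assert survival_at(curve, t) == pytest.approx(np.mean(times > t))

    def test_step_function_conventions(self):
        curve = km_estimate([2, 4, 6, 8], [1, 1, 1, 1])
        assert survival_at(curve, 1.0) == 1.0          # before first event
        assert survival_at(curve, 4.0) == pytest.approx(0.5)  # post-jump
        assert survival_at(curve, 100.0) == 0.0        # beyond last time

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_group_label_swap_invariance(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(9, 30)
        ea, eb = np.ones(30, bool), np.ones(30, bool)
        chi_ab, _ = logrank_test(ta, ea, tb, eb)
        chi_ba, _ = logrank_test(tb, eb, ta, ea)
        assert chi_ab == pytest.approx(chi_ba)

    def test_detects_strong_separation(self, rng):
        hits = 0
        for _ in range(20):
            ta = rng.exponential(1.0, 50)
            tb = rng.exponential(4.0, 50)
            _, p = logrank_test(ta, np.ones(50, bool), tb, np.ones(50, bool))
            hits += p < 0.05
        assert hits >= 18

    def test_no_events_rejected(self):
        with pytest.raises(NoEventsError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCoxFit:
    def test_recovers_protective_hazard_ratio(self, rng):
        n, beta = 300, np.log(0.2)
        x = rng.integers(0, 2, n).astype(float)
        t = -np.log(rng.random(n)) / np.exp(beta * x)
        fit = cox_fit(t, np.ones(n, bool), x)
        assert 0.13 <= fit.hr <= 0.30
        assert fit.ci_low <= fit.hr <= fit.ci_high
        assert fit.converged

    def test_replication_invariance(self, rng):
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.where(x > 0, 2.0, 1.0))
        e = np.ones(n, bool)
        single = cox_fit(t, e, x)
        doubled = cox_fit(np.tile(t, 2), np.tile(e, 2), np.tile(x, 2))
        # replication introduces ties; Efron's correction perturbs the
        # estimate slightly (exact invariance holds only under Breslow)
        assert doubled.beta == pytest.approx(single.beta, abs=0.05)

    def test_sign_matches_logrank_direction(self, rng):
        x = rng.integers(0, 2, 80).astype(float)
        t = rng.exponential(np.where(x > 0, 3.0, 1.0))  # x=1 protective
        fit = cox_fit(t, np.ones(80, bool), x)
        assert fit.beta < 0 and fit.hr < 1

    def test_stratified_fit_runs(self, rng):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        strata = rng.choice(["a", "b"], n)
        t = rng.exponential(np.where(x > 0, 2.0, 1.0))
        fit = cox_fit(t, np.ones(n, bool), x, strata=strata)
        assert np.isfinite(fit.beta)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0])

    def test_needs_events(self):
        with pytest.raises(NoEventsError):
            cox_fit([1, 2, 3], [0, 0, 0], [0.0, 1.0, 0.0])


def _synthetic_cohort(n=300, seed=0):
    config = SyntheticConfig(gamma_skew=0.9, gamma_median=0.0)
    rng = np.random.default_rng(seed)
    skews = rng.uniform(*config.lesion_skew_range, n)
    rows = [draw_outcomes(config, s, 8.0, rng, f"P{i:04d}")
            for i, s in enumerate(skews)]
    cohort = pd.DataFrame(rows)
    features = pd.Series(skews, index=cohort["patient_id"])
    return cohort, features


class TestDichotomizedAnalysis:
    def test_low_skew_group_is_protective(self):
        cohort, skew = _synthetic_cohort()
        run = dichotomized_pfs_analysis(cohort, skew, float(skew.median()),
                                        exposure_side="le")
        assert run.cox.hr < 1.0
        assert run.p_logrank < 0.05
        assert run.n_exposed + run.n_other == len(cohort)

    def test_threshold_at_minimum_rejected(self):
        cohort, skew = _synthetic_cohort(n=100)
        with pytest.raises(DegenerateSplitError):
            dichotomized_pfs_analysis(cohort, skew, float(skew.min()) - 1.0)

    def test_subgroup_matches_manual_restriction(self):
        cohort, skew = _synthetic_cohort()
        level = "TPS>=50"
        sub = dichotomized_pfs_analysis(cohort, skew, float(skew.median()),
                                        subgroup=level)
        manual_cohort = cohort[cohort["tps_group"] == level]
        manual = dichotomized_pfs_analysis(
            manual_cohort, skew[manual_cohort["patient_id"]],
            float(skew.median()))
        assert sub.cox.hr == pytest.approx(manual.cox.hr)
        assert sub.chi2 == pytest.approx(manual.chi2)

    def test_six_month_survival_readout(self):
        cohort, skew = _synthetic_cohort()
        run = dichotomized_pfs_analysis(cohort, skew, float(skew.median()))
        s_low = survival_at(run.km_exposed, 6.0)
        s_high = survival_at(run.km_other, 6.0)
        assert 0.0 <= s_high < s_low <= 1.0
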