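import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from benefitscore.errors import DataError, DegenerateInputError
from benefitscore.simulate import simulate_survival
from benefitscore.survival import (
    cox_fit,
    dichotomize,
    find_optimal_cutpoint,
    km_estimate,
    logrank_test,
    maxstat_adjusted_p,
)

from oracles import cutpoint_bruteforce, km_survival_bruteforce


class TestKaplanMeier:
    def test_hand_worked_product_limit(self, survival_frame):
        # deaths at 1 and 2, censoring at 3: S(1) = 2/3, S(3) = (2/3)(1/2) = 1/3
        curve = km_estimate(survival_frame([(1, 1), (2, 1), (3, 0)]))
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(1 / 3)

    def test_censored_subject_leaves_risk_set_without_drop(self, survival_frame):
        curve = km_estimate(survival_frame([(1, 1), (2, 0), (3, 1)]))
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(2) == pytest.approx(2 / 3)  # no drop at censoring
        assert curve.survival_at(3) == pytest.approx(0.0)  # last at-risk subject dies

    def test_all_censored_stays_at_one(self, survival_frame):
        curve = km_estimate(survival_frame([(1, 0), (2, 0), (5, 0)]))
        assert curve.event_times.size == 0
        assert curve.survival_at(5) == 1.0

    def test_single_event_drops_to_zero(self, survival_frame):
        curve = km_estimate(survival_frame([(5, 1)]))
        assert curve.survival_at(5) == 0.0

    def test_empty_input_rejected(self, survival_frame):
        with pytest.raises(DegenerateInputError):
            km_estimate(survival_frame([]))

    def test_matches_bruteforce_on_random_data(self, rng):
        time = rng.exponential(10, size=40).round(1) + 0.1
        event = rng.random(40) < 0.7
        frame = pd.DataFrame({"time": time, "event": event})
        curve = km_estimate(frame)
        for t in [2.0, 5.0, 10.0, 20.0]:
            assert curve.survival_at(t) == pytest.approx(
                km_survival_bruteforce(time, event, t), abs=1e-12
            )

    def test_identical_groups_pool_to_same_curve(self, survival_frame):
        pairs = [(1, 1), (2, 0), (4, 1), (7, 1), (9, 0)]
        one = km_estimate(survival_frame(pairs))
        pooled = km_estimate(survival_frame(pairs + pairs))
        np.testing.assert_allclose(one.survival_prob, pooled.survival_prob)


class TestLogRank:
    def test_hand_worked_chi_square(self, survival_frame):
        a = survival_frame([(1, 1), (3, 1)])
        b = survival_frame([(2, 1), (4, 0)])
        res = logrank_test(a, b)
        # O_A = 2, E_A = 4/3, V = 13/18
        assert res.chi_square == pytest.approx(0.61538, abs=1e-4)

    def test_identical_groups_give_zero(self, survival_frame):
        g = survival_frame([(1, 1), (4, 1), (6, 0)])
        assert logrank_test(g, g.copy()).chi_square == pytest.approx(0.0, abs=1e-12)

    def test_no_events_rejected(self, survival_frame):
        with pytest.raises(DegenerateInputError):
            logrank_test(survival_frame([(1, 0)]), survival_frame([(2, 0)]))

    def test_agrees_with_lifelines(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 60))
            time = rng.exponential(12, size=n) + 0.01
            event = rng.random(n) < 0.8
            split = n // 2
            a = pd.DataFrame({"time": time[:split], "event": event[:split]})
            b = pd.DataFrame({"time": time[split:], "event": event[split:]})
            ours = logrank_test(a, b)
            ref = ll_logrank(a["time"], b["time"], a["event"], b["event"])
            assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-6)
            assert ours.p_value == pytest.approx(ref.p_value, rel=1e-6)


class TestDichotomize:
    def test_boundary_is_low(self):
        groups = dichotomize({"a": 5.0, "b": 5.1}, threshold=5.0)
        assert groups == {"a": "low", "b": "high"}

    def test_empty_map(self):
        assert dichotomize({}, 1.0) == {}


class TestCutpoint:
    def _random_instance(self, rng, n):
        marker = rng.lognormal(1.0, 0.8, size=n)
        # survival loosely tied to the marker so maxima are non-trivial
        hazard = 0.05 * np.exp(-0.3 * (marker > np.median(marker)))
        time = rng.exponential(1 / hazard) + 0.01
        cens = rng.uniform(5, 50, size=n)
        frame = pd.DataFrame(
            {
                "sample_id": [f"P{i}" for i in range(n)],
                "time": np.minimum(time, cens),
                "event": time <= cens,
            }
        )
        return dict(zip(frame["sample_id"], marker)), frame

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            marker, frame = self._random_instance(rng, n)
            cp = find_optimal_cutpoint(marker, frame, minprop=0.1)
            values = np.array([marker[s] for s in frame["sample_id"]])
            thr, chi2 = cutpoint_bruteforce(
                values, frame["time"], frame["event"], minprop=0.1
            )
            assert cp.threshold == pytest.approx(thr)
            assert cp.chi_square == pytest.approx(chi2, rel=1e-9)

    def test_clear_separation_recovers_gap_threshold(self, survival_frame):
        # marker >= 10 -> long survivors; others die early
        frame = survival_frame(
            [(1, 1), (2, 1), (3, 1), (30, 0), (40, 1), (50, 0)]
        )
        marker = dict(zip(frame["sample_id"], [1, 2, 3, 10, 11, 12]))
        cp = find_optimal_cutpoint(marker, frame, minprop=0.5)
        assert 3 < cp.threshold < 10
        assert cp.n_high == cp.n_low == 3

    def test_minprop_half_forces_even_split(self, survival_frame):
        frame = survival_frame([(1, 1), (2, 1), (3, 1), (9, 1), (11, 1), (12, 1)])
        marker = dict(zip(frame["sample_id"], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        cp = find_optimal_cutpoint(marker, frame, minprop=0.5)
        assert cp.n_high == cp.n_low == 3
        assert cp.threshold == pytest.approx(3.5)

    def test_constant_marker_rejected(self, survival_frame):
        frame = survival_frame([(1, 1), (2, 1), (3, 0)])
        with pytest.raises(DegenerateInputError):
            find_optimal_cutpoint({s: 1.0 for s in frame["sample_id"]}, frame)

    def test_invariant_under_monotone_marker_transform(self, rng):
        marker, frame = self._random_instance(rng, 50)
        cp_raw = find_optimal_cutpoint(marker, frame)
        cp_log = find_optimal_cutpoint({s: np.log(v) for s, v in marker.items()}, frame)
        assert cp_raw.statistic == pytest.approx(cp_log.statistic, rel=1e-9)
        assert cp_raw.group_assignment == cp_log.group_assignment

    def test_adjusted_p_exceeds_naive(self, rng):
        marker, frame = self._random_instance(rng, 60)
        cp = find_optimal_cutpoint(marker, frame)
        assert cp.adjusted_p >= cp.naive_logrank_p
        assert maxstat_adjusted_p(0.0, 0.1) == 1.0


class TestCox:
    def test_recovers_simulated_hazard_ratio(self, rng):
        is_high = np.arange(500) < 250
        surv = simulate_survival(is_high, 0.05, np.log(2.0), (10, 80), rng)
        frame = surv.assign(
            sample_id=[f"P{i}" for i in range(500)],
            group=np.where(is_high, "high", "low"),
        )
        fit = cox_fit(frame, ["group"], reference_levels={"group": "high"})
        assert fit.converged
        hr = fit.table.loc[0, "hr"]
        assert 1.7 < hr < 2.35

    def test_constant_covariate_dropped_and_flagged(self, rng):
        is_high = np.arange(60) < 30
        surv = simulate_survival(is_high, 0.05, 0.7, (10, 80), rng)
        frame = surv.assign(
            sample_id=[f"P{i}" for i in range(60)],
            group=np.where(is_high, "high", "low"),
            site="one-center",
        )
        fit = cox_fit(frame, ["site", "group"])
        assert "site" in fit.dropped
        assert fit.converged

    def test_only_constant_covariates_reports_nonconvergence(self, rng):
        surv = simulate_survival(np.ones(20, bool), 0.05, 0.0, (10, 80), rng)
        frame = surv.assign(sample_id=[f"P{i}" for i in range(20)], site="x")
        fit = cox_fit(frame, ["site"])
        assert not fit.converged and "constant" in fit.diagnostics

    def test_wald_agrees_with_logrank_asymptotically(self, rng):
        is_high = np.arange(200) < 100
        surv = simulate_survival(is_high, 0.06, np.log(1.8), (5, 60), rng)
        frame = surv.assign(
            sample_id=[f"P{i}" for i in range(200)],
            group=np.where(is_high, "high", "low"),
        )
        fit = cox_fit(frame, ["group"], reference_levels={"group": "high"})
        wald_chi2 = (fit.table.loc[0, "coef"] / (np.log(fit.table.loc[0, "ci_high"] / fit.table.loc[0, "hr"]) / 1.959964)) ** 2
        lr = logrank_test(frame[is_high], frame[~is_high])
        assert wald_chi2 == pytest.approx(lr.chi_square, rel=0.15)

    def test_missing_covariate_column_rejected(self, survival_frame):
        frame = survival_frame([(1, 1), (2, 1), (3, 0), (4, 1)])
        with pytest.raises(DataError, match="age"):
            cox_fit(frame, ["age"])
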