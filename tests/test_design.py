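"""Closed-form planning layer: sample sizes, thresholds, z-tests, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from thresholdcross import (
    DesignParams,
    HistoricalCohort,
    InfeasibleDesignError,
    RuleTag,
    ThresholdRule,
    TrialResult,
    compute_threshold,
    exact_rejection_probability,
    one_sample_z_test,
    parallel_group_sample_size,
    planned_trial_size,
    round_to_hundred,
    single_arm_sample_size,
    two_sample_z_test,
)

NAIVE = ThresholdRule(RuleTag.NAIVE_MEAN)
CI = ThresholdRule(RuleTag.CI_UPPER)


class TestSampleSizes:
    def test_two_arm_reference_design(self, params):
        """Delta=0.2 at 2.5%/80% needs 393 per group, 'about 400'/800 total."""
        n = parallel_group_sample_size(params)
        assert n == 393
        assert round_to_hundred(n) == 400
        assert round_to_hundred(2 * n) == 800

    def test_two_arm_matches_statsmodels(self, params):
        """Independent cross-check against statsmodels' normal power solver."""
        smp = pytest.importorskip("statsmodels.stats.power")
        n_float = smp.NormalIndPower().solve_power(
            effect_size=params.delta, alpha=params.alpha, power=params.power,
            ratio=1.0, alternative="larger")
        assert parallel_group_sample_size(params) == math.ceil(n_float)

    def test_single_arm_naive_size(self):
        """One-sample design at the full effect needs 197, 'about 200'."""
        n = single_arm_sample_size(0.2)
        assert n == 197
        assert round_to_hundred(n) == 200

    def test_huge_effect_needs_one_patient(self):
        assert parallel_group_sample_size(DesignParams(delta=4.0)) == 1

    def test_zero_effective_delta_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            single_arm_sample_size(0.0)

    @given(delta=st.floats(0.05, 2.0), power=st.floats(0.5, 0.99),
           alpha=st.floats(0.005, 0.2))
    @settings(max_examples=50, derandomize=True)
    def test_size_monotonicity_and_ceiling(self, delta, power, alpha):
        """Sizes shrink with effect, grow with power and with stricter alpha,
        and never fall below the real-valued formula."""
        p = DesignParams(delta=delta, alpha=alpha, power=power)
        n = parallel_group_sample_size(p)
        z = norm.ppf(1 - alpha) + norm.ppf(power)
        assert n >= 2 * z**2 / delta**2 - 1e-9
        assert parallel_group_sample_size(
            DesignParams(delta=delta * 1.5, alpha=alpha, power=power)) <= n
        assert parallel_group_sample_size(
            DesignParams(delta=delta, alpha=alpha,
                         power=min(power + 0.005, 0.995))) >= n
        assert parallel_group_sample_size(
            DesignParams(delta=delta, alpha=alpha * 0.5, power=power)) >= n


class TestThresholds:
    def test_naive_mean_is_identity(self, params):
        h = HistoricalCohort("h", 50, mean=0.0)
        assert compute_threshold(h, NAIVE, params).t == 0.0

    def test_ci_upper_offsets(self, params):
        """CI upper bound at n_h=1000 sits z_{0.975}/sqrt(1000) above the
        mean; the +0.2 delta variant adds 0.04 on top."""
        h = HistoricalCohort("h", 1000, mean=0.0)
        t = compute_threshold(h, CI, params).t
        assert t == pytest.approx(0.06198, abs=5e-6)
        plus = ThresholdRule(RuleTag.CI_UPPER_PLUS, c=0.2)
        assert compute_threshold(h, plus, params).t == pytest.approx(
            0.10198, abs=5e-6)

    def test_c_zero_reduces_plus_to_ci_upper(self, params):
        h = HistoricalCohort("h", 200, mean=0.3)
        plus0 = ThresholdRule(RuleTag.CI_UPPER_PLUS, c=0.0)
        assert compute_threshold(h, plus0, params).t == \
            compute_threshold(h, CI, params).t

    @given(n_h=st.integers(1, 10_000), mean=st.floats(-2, 2))
    @settings(max_examples=50, derandomize=True)
    def test_ci_threshold_never_below_mean(self, n_h, mean):
        h = HistoricalCohort("h", n_h, mean=mean)
        assert compute_threshold(h, CI, DesignParams(0.2)).t >= mean

    def test_cohort_summary_value_consistency(self):
        with pytest.raises(ValueError):
            HistoricalCohort("h", 3, mean=5.0, values=(0.0, 1.0, 2.0))
        c = HistoricalCohort.from_values("h", [0.0, 1.0, 2.0])
        assert c.n_h == 3 and c.mean == 1.0 and c.sd == 1.0


class TestPlannedTrialSize:
    def test_ci_adjusted_size_at_1000_controls(self, params):
        """The half-width-adjusted single-arm design needs 413 ('about 400',
        half the two-arm total) with 1000 historical controls."""
        n = planned_trial_size(CI, 1000, params)
        assert n == 413
        assert round_to_hundred(n) == 400

    def test_small_historical_sample_is_infeasible(self, params):
        # half-width 1.96/sqrt(96) just exceeds delta=0.2
        with pytest.raises(InfeasibleDesignError):
            planned_trial_size(CI, 96, params)

    def test_monotone_in_nh_with_naive_limit(self, params):
        sizes = [planned_trial_size(CI, n_h, params)
                 for n_h in (150, 300, 1000, 5000, 10**8)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == single_arm_sample_size(params.delta)


class TestZTests:
    def test_one_sample_boundary_does_not_reject(self, params):
        res = one_sample_z_test(TrialResult(n=50, mean=0.3), 0.3,
                                alpha=params.alpha)
        assert res.z == 0.0 and not res.reject

    def test_one_sample_critical_mean(self, params):
        crit_mean = norm.ppf(0.975) / math.sqrt(197)
        assert one_sample_z_test(TrialResult(197, crit_mean + 1e-6), 0.0).reject
        assert not one_sample_z_test(TrialResult(197, crit_mean), 0.0).reject
        res = one_sample_z_test(TrialResult(197, 0.10), 0.0)
        assert res.z == pytest.approx(1.4036, abs=1e-4)
        assert not res.reject

    def test_two_sample_at_planned_size(self):
        e = TrialResult(393, 0.2)
        c = TrialResult(393, 0.0)
        res = two_sample_z_test(e, c)
        assert res.z == pytest.approx(2.8035, abs=1e-4)
        assert res.reject
        small = two_sample_z_test(TrialResult(393, 0.05), c)
        assert small.z == pytest.approx(0.7009, abs=1e-4)
        assert not small.reject


class TestExactRejectionProbability:
    def test_infinite_historical_data_recovers_alpha(self, params):
        p = exact_rejection_probability(NAIVE, math.inf, 197, params)
        assert p == pytest.approx(params.alpha, abs=1e-12)

    @pytest.mark.parametrize("rule,n_h,true_delta,drift,expected", [
        (NAIVE, 100, 0.0, 0.0, 0.1277),
        (CI, 100, 0.0, 0.0, 0.00313),
        (NAIVE, 1000, 0.0, 0.05, 0.1251),
    ])
    def test_frozen_oracle_values(self, params, rule, n_h, true_delta,
                                  drift, expected):
        """Hand-derived normal-tail values for the marginal rejection
        probability at n=197."""
        p = exact_rejection_probability(rule, n_h, 197, params,
                                        true_delta, drift)
        assert p == pytest.approx(expected, abs=5e-4)

    def test_ci_rule_controls_type_one_error(self, params):
        """Without drift the CI-upper threshold keeps the null rejection
        probability at or below alpha over a whole (n, n_h) grid."""
        for n_h in (10, 50, 150, 1000, 10_000):
            for n in (20, 197, 413, 2000):
                p = exact_rejection_probability(CI, n_h, n, params)
                assert p <= params.alpha + 1e-12

    def test_monotone_in_effect_drift_and_c(self, params):
        base = exact_rejection_probability(NAIVE, 200, 197, params)
        assert exact_rejection_probability(NAIVE, 200, 197, params,
                                           true_delta=0.1) > base
        assert exact_rejection_probability(NAIVE, 200, 197, params,
                                           drift=0.05) > base
        probs_c = [exact_rejection_probability(
            ThresholdRule(RuleTag.CI_UPPER_PLUS, c=c), 200, 197, params,
            true_delta=0.2) for c in (0.0, 0.1, 0.2, 0.3)]
        assert probs_c == sorted(probs_c, reverse=True)

    def test_naive_inflation_decreasing_in_nh(self, params):
        probs = [exact_rejection_probability(NAIVE, n_h, 197, params)
                 for n_h in (50, 100, 500, 5000)]
        assert probs == sorted(probs, reverse=True)
        assert all(p > params.alpha for p in probs)

    def test_two_arm_power_at_planned_size_meets_target(self, params):
        """Closed form: 1 - Phi(z_alpha - delta sqrt(n/2)) >= 0.80 at n=393."""
        n = parallel_group_sample_size(params)
        power = norm.sf(norm.ppf(1 - params.alpha)
                        - params.delta * math.sqrt(n / 2))
        assert power >= params.power
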