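"""ICERs, dominance taxonomy, bootstrap uncertainty and acceptability curves."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from cpcea import bootstrap_cea, ceac, compute_icer, incremental_estimates, percentile_ui, replicate_icers
from cpcea.cea import (
    DOMINANT,
    DOMINATED,
    TRADEOFF_NE,
    TRADEOFF_SW,
    UNDEFINED,
    BootstrapReplicates,
    classify,
    display_round,
    effective_effect,
)
from cpcea.errors import ValidationError

HIGH, LOW = "higher_is_better", "lower_is_better"


class TestComputeIcer:
    def test_pain_domain_with_orientation_reversal(self):
        out = compute_icer(2527.0, -9.24, LOW)
        assert out.effective_delta_E == pytest.approx(9.24)
        assert out.classification == TRADEOFF_NE
        assert display_round(out.icer) == 273

    def test_family_health_and_access_icers(self):
        assert display_round(compute_icer(2527.0, 2.36, HIGH).icer) == 1071
        assert display_round(compute_icer(2528.0, 1.46, HIGH).icer) == 1732

    def test_costlier_and_worse_is_dominated(self):
        out = compute_icer(2527.0, -2.63, HIGH)
        assert out.classification == DOMINATED
        assert out.icer is None
        assert out.label == "Dominated"

    def test_cheaper_and_better_is_dominant(self):
        assert compute_icer(-100.0, 1.0, HIGH).classification == DOMINANT

    def test_zero_cost_with_benefit_gives_zero_icer(self):
        out = compute_icer(0.0, 3.0, HIGH)
        assert out.classification == TRADEOFF_NE and out.icer == 0.0

    def test_zero_benefit_with_cost_is_undefined_not_infinite(self):
        out = compute_icer(500.0, 0.0, HIGH)
        assert out.classification == UNDEFINED and out.icer is None

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValidationError):
            compute_icer(np.inf, 1.0, HIGH)

    @given(
        st.floats(min_value=-1e5, max_value=1e5),
        st.floats(min_value=-100, max_value=100),
        st.sampled_from([HIGH, LOW]),
    )
    def test_plane_partition_and_ratio_identity(self, d_c, d_e, orientation):
        assume(d_c != 0 and d_e != 0)
        out = compute_icer(d_c, d_e, orientation)
        eff = out.effective_delta_E
        expected = {
            (True, True): TRADEOFF_NE,
            (True, False): DOMINANT,
            (False, True): DOMINATED,
            (False, False): TRADEOFF_SW,
        }[(eff > 0, d_c > 0)]
        assert out.classification == expected
        # dominance iff definitions
        assert (out.classification == DOMINATED) == (d_c > 0 and eff < 0)
        assert (out.classification == DOMINANT) == (d_c < 0 and eff > 0)
        if out.icer is not None:
            assert out.icer * eff == pytest.approx(d_c, rel=1e-12)

    def test_orientation_flip_negates_effective_effect(self):
        assert effective_effect(-9.24, LOW) == pytest.approx(9.24)
        assert effective_effect(-9.24, HIGH) == pytest.approx(-9.24)


class TestIncrementalEstimates:
    def test_equal_arms_give_zero_increments(self):
        assert incremental_estimates([3.0, 5.0], [5.0, 3.0], [1.0], [1.0], HIGH) == (0.0, 0.0, 0.0)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValidationError):
            incremental_estimates([], [1.0], [1.0], [1.0], HIGH)

    def test_means_differenced_intervention_minus_control(self):
        d_c, d_e, eff = incremental_estimates([10.0, 20.0], [5.0], [2.0, 4.0], [1.0], LOW)
        assert d_c == 10.0 and d_e == 2.0 and eff == -2.0


class TestBootstrap:
    def test_degenerate_arms_give_zero_width_ui(self):
        reps = bootstrap_cea([10.0] * 4, [4.0] * 3, [2.0] * 4, [1.0] * 3, HIGH, b=500, seed=1)
        assert np.all(reps.delta_C == 6.0) and np.all(reps.delta_E == 1.0)
        ratios, _ = replicate_icers(reps)
        assert percentile_ui(ratios) == (6.0, 6.0)

    def test_single_replicate_collapses_ui(self):
        reps = bootstrap_cea([10.0, 12.0], [4.0, 6.0], [2.0, 3.0], [1.0, 2.0], HIGH, b=1, seed=2)
        assert reps.b == 1
        lo, hi = percentile_ui(reps.delta_C)
        assert lo == hi == reps.delta_C[0]

    def test_reproducible_given_seed(self):
        args = ([1.0, 5.0, 9.0], [2.0, 4.0], [1.0, 2.0, 3.0], [0.5, 1.5], HIGH)
        a = bootstrap_cea(*args, b=100, seed=42)
        b = bootstrap_cea(*args, b=100, seed=42)
        np.testing.assert_array_equal(a.delta_C, b.delta_C)
        np.testing.assert_array_equal(a.delta_E, b.delta_E)

    def test_monte_carlo_matches_exhaustive_enumeration_on_tiny_arms(self):
        # n=3/3: all 3^3 x 3^3 equally likely ordered within-arm resamples
        ci, cc = np.array([100.0, 250.0, 400.0]), np.array([50.0, 60.0, 130.0])
        ei, ec = np.array([1.0, 2.0, 6.0]), np.array([0.5, 1.0, 3.0])
        exhaustive = []
        for ii in itertools.product(range(3), repeat=3):
            for jj in itertools.product(range(3), repeat=3):
                exhaustive.append(ci[list(ii)].mean() - cc[list(jj)].mean())
        exhaustive = np.array(exhaustive)
        reps = bootstrap_cea(ci, cc, ei, ec, HIGH, b=100_000, seed=9)
        mc_se = reps.delta_C.std(ddof=1) / np.sqrt(reps.b)
        assert abs(reps.delta_C.mean() - exhaustive.mean()) < 3 * mc_se

    def test_stacking_over_imputations_multiplies_replicates(self):
        eff_sets = [[1.0, 2.0], [1.5, 2.5], [2.0, 3.0]]
        reps = bootstrap_cea(
            [10.0, 20.0], [5.0, 7.0], eff_sets, [[0.5, 1.0]] * 3, HIGH, b=50, seed=3
        )
        assert reps.b == 150 and reps.stacked_over_imputations

    def test_misaligned_arrays_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_cea([1.0, 2.0], [3.0], [1.0], [1.0], HIGH, b=5, seed=0)


class TestPercentileUi:
    def test_matches_order_statistics_oracle_on_1_to_100(self):
        values = np.arange(1.0, 101.0)
        lo, hi = percentile_ui(values, 0.95)
        # brute-force linear-interpolation quantile oracle
        def oracle(q):
            h = 99 * q
            k = int(np.floor(h))
            v = np.sort(values)
            return v[k] + (h - k) * (v[min(k + 1, 99)] - v[k])
        assert lo == pytest.approx(oracle(0.025))
        assert hi == pytest.approx(oracle(0.975))

    def test_constant_replicates_give_point_interval(self):
        assert percentile_ui([7.0] * 50) == (7.0, 7.0)

    def test_symmetric_replicates_give_symmetric_bounds(self):
        v = np.concatenate([np.arange(-50, 0), np.arange(1, 51)])
        lo, hi = percentile_ui(v, 0.9)
        assert lo == pytest.approx(-hi)

    def test_undefined_ratios_excluded_with_count(self):
        reps = BootstrapReplicates(
            delta_C=np.array([10.0, 20.0, 30.0]),
            delta_E=np.array([1.0, 0.0, 2.0]),
            orientation=HIGH,
            seed=0,
        )
        ratios, excluded = replicate_icers(reps)
        assert excluded == 1 and reps.excluded_undefined == 1
        np.testing.assert_allclose(ratios, [10.0, 15.0])


def _reps(delta_C, delta_E, orientation=HIGH):
    return BootstrapReplicates(
        delta_C=np.asarray(delta_C, float), delta_E=np.asarray(delta_E, float),
        orientation=orientation, seed=0,
    )


class TestCeac:
    def test_direct_nmb_count(self):
        # replicates {(100, 1), (300, 1)} at lambda=200: NMB {100, -100} -> 0.5
        curve = ceac(_reps([100.0, 300.0], [1.0, 1.0]), [200.0])
        assert curve["probability"].iloc[0] == 0.5

    def test_lambda_zero_is_probability_of_cost_saving(self):
        curve = ceac(_reps([100.0, 300.0], [1.0, 1.0]), [0.0])
        assert curve["probability"].iloc[0] == 0.0
        curve = ceac(_reps([-1.0, 300.0, -2.0, 5.0], [1.0] * 4), [0.0])
        assert curve["probability"].iloc[0] == 0.5

    def test_certain_cost_effectiveness_reaches_one(self):
        curve = ceac(_reps([100.0, 300.0], [1.0, 2.0]), [1000.0])
        assert curve["probability"].iloc[0] == 1.0

    @given(
        st.lists(st.floats(min_value=-5000, max_value=5000), min_size=1, max_size=60),
        st.lists(
            st.one_of(
                st.just(0.0),
                st.floats(min_value=0.01, max_value=10),
                st.floats(min_value=-10, max_value=-0.01),
            ),
            min_size=1,
            max_size=60,
        ),
        st.sampled_from([HIGH, LOW]),
    )
    def test_boundary_identities_on_any_replicate_set(self, d_c, d_e, orientation):
        n = min(len(d_c), len(d_e))
        reps = _reps(d_c[:n], d_e[:n], orientation)
        eff = reps.effective_delta_E
        at_zero = ceac(reps, [0.0])["probability"].iloc[0]
        assert at_zero == np.mean(reps.delta_C < 0)
        at_inf = ceac(reps, [1e12])["probability"].iloc[0]
        # zero-benefit replicates keep NMB = -delta_C at every lambda
        expected_limit = np.mean((eff > 0) | ((eff == 0) & (reps.delta_C < 0)))
        assert at_inf == expected_limit

    def test_grid_sorted_and_probabilities_bounded(self, rng):
        reps = _reps(rng.normal(2500, 600, 500), rng.normal(1, 3, 500))
        curve = ceac(reps, rng.uniform(0, 5000, 40))
        assert curve["wtp_lambda"].is_monotonic_increasing
        assert curve["probability"].between(0, 1).all()

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValidationError):
            ceac(_reps([1.0], [1.0]), [-5.0])


class TestScaleEquivariance:
    def test_costs_scaling_propagates_to_icer_ui_and_ceac(self):
        rng = np.random.default_rng(5)
        ci, cc = rng.lognormal(8, 0.4, 12), rng.lognormal(7.5, 0.4, 9)
        ei, ec = rng.normal(3, 2, 12), rng.normal(1, 2, 9)
        c = 2.5
        base = bootstrap_cea(ci, cc, ei, ec, HIGH, b=2000, seed=77)
        scaled = bootstrap_cea(c * ci, c * cc, ei, ec, HIGH, b=2000, seed=77)
        r0, _ = replicate_icers(base)
        r1, _ = replicate_icers(scaled)
        np.testing.assert_allclose(r1, c * r0, rtol=1e-12)
        lo0, hi0 = percentile_ui(r0)
        lo1, hi1 = percentile_ui(r1)
        assert (lo1, hi1) == pytest.approx((c * lo0, c * hi0))
        grid = np.array([0.0, 500.0, 1000.0])
        np.testing.assert_allclose(
            ceac(scaled, c * grid)["probability"], ceac(base, grid)["probability"]
        )
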