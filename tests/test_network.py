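"""Core network: place-code encoding, propagation, dynamics, single trials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numstroop import (
    ModelParameters,
    NetworkState,
    StimulusPair,
    comparison_net_input,
    congruency_of,
    demand_for_task,
    distance_class,
    encode_number,
    make_fixture,
    run_trial,
    step_dynamics,
)
from numstroop.control import TaskDemandState
from numstroop.weights import ComparisonWeights


class TestEncodeNumber:
    def test_peak_is_at_encoded_magnitude(self, params):
        for n in range(1, 10):
            field = encode_number(n, params)
            assert field.shape == (9,)
            assert np.all(field >= 0)
            assert field.argmax() == n - 1

    def test_extremes_are_mirror_images(self, params):
        assert np.allclose(encode_number(1, params), encode_number(9, params)[::-1])

    def test_small_sigma_limit_is_one_hot(self):
        """As the place-code width shrinks the profile collapses onto its
        peak node; checked against a brute-force evaluation of the profile."""
        p = ModelParameters(numberline_sigma=1e-3)
        field = encode_number(4, p)
        nodes = np.arange(1, 10)
        brute = np.exp(-((nodes - 4) ** 2) / (2 * 1e-6))
        assert np.allclose(field, brute)
        onehot = np.zeros(9)
        onehot[3] = 1.0
        assert np.allclose(field, onehot, atol=1e-12)

    @given(n=st.integers(1, 9), sigma=st.floats(0.1, 3.0))
    @settings(deadline=None, max_examples=50)
    def test_symmetry_about_peak(self, n, sigma):
        field = encode_number(n, ModelParameters(numberline_sigma=sigma))
        for k in range(1, 9):
            lo, hi = n - k, n + k
            if 1 <= lo <= 9 and 1 <= hi <= 9:
                assert field[lo - 1] == pytest.approx(field[hi - 1])

    @pytest.mark.parametrize("bad", [0, 10, -1, 2.5, "3"])
    def test_out_of_range_magnitude_rejected(self, bad, params):
        with pytest.raises(ValueError):
            encode_number(bad, params)


class TestComparisonNetInput:
    def test_zero_weights_give_zero_net_input(self, params):
        left, right = encode_number(3, params), encode_number(7, params)
        assert np.array_equal(
            comparison_net_input(left, right, ComparisonWeights.zeros()),
            np.zeros(2),
        )

    def test_linear_in_weights(self, params):
        left, right = encode_number(2, params), encode_number(6, params)
        w = make_fixture("monotone-ramp")
        doubled = ComparisonWeights(2.0 * w.w)
        assert np.allclose(
            comparison_net_input(left, right, doubled),
            2.0 * comparison_net_input(left, right, w),
        )

    def test_hand_set_weights_match_brute_force_dot_product(self):
        """+1 from left-field nodes above 5 to "left larger", one-hot codes
        for the pair (8, 2) -> net input exactly (1, 0)."""
        p = ModelParameters(numberline_sigma=0.0)
        w = np.zeros((2, 18))
        w[0, 5:9] = 1.0  # left-field nodes 6..9 -> "left larger"
        net = comparison_net_input(
            encode_number(8, p), encode_number(2, p), ComparisonWeights(w)
        )
        assert np.array_equal(net, [1.0, 0.0])

    def test_dimension_mismatch_rejected(self, params):
        with pytest.raises(ValueError):
            comparison_net_input(np.zeros(8), np.zeros(9), ComparisonWeights.zeros())


class TestStepDynamics:
    def test_zero_drive_zero_state_is_fixed_point(self, params):
        demand = TaskDemandState(0.0, 0.0)  # gates closed
        state = NetworkState.zeros()
        for _ in range(10):
            state = step_dynamics(state, np.zeros(2), np.zeros(2), demand, params)
        assert np.array_equal(state.response, np.zeros(2))
        assert np.array_equal(state.c_numerical, np.zeros(2))
        assert state.step == 10

    def test_constant_drive_accumulates_linearly(self, params):
        """A single constant drive I to one response node only gives
        activation t * tau * I after t steps (closed form)."""
        td = np.zeros((2, 4))
        td[0, 0] = 0.4  # numerical demand -> left comparison node only
        demand = TaskDemandState(1.0, 0.0, td_weights=td)
        # comparison activation rests at 0.5 with zero weights, so the gated
        # drive is 0.5 * 1.0 * 0.4 = 0.2 to the left node only
        state = NetworkState.zeros()
        drive = 0.5 * 1.0 * 0.4
        for t in range(1, 8):
            state = step_dynamics(state, np.zeros(2), np.zeros(2), demand, params)
            assert state.response[0] == pytest.approx(t * params.tau * drive)
            assert state.response[1] == 0.0

    def test_symmetric_drive_keeps_activations_equal(self, params):
        demand = demand_for_task("numerical", params)
        state = NetworkState.zeros()
        net = np.array([1.3, 1.3])
        for _ in range(20):
            state = step_dynamics(state, net, net, demand, params)
            assert state.response[0] == state.response[1]

    def test_activations_remain_bounded(self, params):
        demand = demand_for_task("numerical", params)
        state = NetworkState.zeros()
        for _ in range(300):
            state = step_dynamics(state, np.array([9.0, -9.0]), np.array([9.0, -9.0]), demand, params)
        assert np.all(state.response >= 0) and np.all(state.response <= 1)


class TestRunTrial:
    def test_rt_matches_closed_form_ceiling(self, params):
        """Constant drive 0.1 to the left node, tau 0.25, theta 0.75:
        the first step with t * 0.25 * 0.1 >= 0.75 is t = 30."""
        td = np.zeros((2, 4))
        td[0, 0] = 0.2  # left numerical gate only: drive = 0.5 * 1.0 * 0.2 = 0.1
        demand = TaskDemandState(1.0, 0.0, td_weights=td)
        result = run_trial(
            StimulusPair(8, 2),
            ComparisonWeights.zeros(),
            None,
            params,
            task="comparison",
            demand=demand,
        )
        assert result.response == "left"
        assert result.rt == 30
        assert len(result.conflict_trace) == 30

    def test_zero_weights_time_out(self, params):
        result = run_trial(
            StimulusPair(3, 7),
            make_fixture("zero"),
            make_fixture("zero"),
            params,
            task="numerical",
        )
        assert result.response == "none"
        assert result.rt == params.t_max
        assert result.correct is False

    def test_trained_congruent_trial_is_correct(self, params, trained_weights):
        """Digit 1 (small font) vs digit 8 (large font): the right side is
        larger on both dimensions and the model answers right."""
        result = run_trial(
            StimulusPair(1, 8, 2, 8),
            trained_weights,
            trained_weights,
            params,
            task="numerical",
        )
        assert result.response == "right"
        assert result.correct is True

    def test_mirror_symmetry_with_symmetric_weights(self, params):
        """Swapping left and right stimuli swaps the winning response and
        leaves the response time unchanged, exactly."""
        w = make_fixture("symmetric")
        for a, b in [(2, 7), (8, 9), (1, 5)]:
            r1 = run_trial(StimulusPair(a, b), w, None, params, task="comparison")
            r2 = run_trial(StimulusPair(b, a), w, None, params, task="comparison")
            assert r1.rt == r2.rt
            assert {r1.response, r2.response} == {"left", "right"}

    def test_rt_monotone_in_threshold_and_rate(self, params, trained_weights):
        stim = StimulusPair(8, 9)
        base = run_trial(stim, trained_weights, None, params, task="comparison")
        higher = run_trial(
            stim, trained_weights, None, params.replace(theta=0.9), task="comparison"
        )
        faster = run_trial(
            stim, trained_weights, None, params.replace(tau=0.5), task="comparison"
        )
        assert higher.rt >= base.rt
        assert faster.rt <= base.rt

    def test_rt_monotone_in_relevant_attention(self, params, trained_weights):
        stim = StimulusPair(2, 9)
        rts = []
        for scale in (1.0, 0.9, 0.7, 0.5):
            p = params.replace(attention_scale_numerical=scale)
            rts.append(
                run_trial(stim, trained_weights, None, p, task="comparison").rt
            )
        assert all(b >= a for a, b in zip(rts, rts[1:]))

    def test_physical_gate_zero_reduces_to_comparison_task(
        self, params, trained_weights
    ):
        """With the physical route's demand gated to 0, numerical Stroop
        trials reproduce comparison-only trials exactly."""
        demand = demand_for_task("numerical", params)
        demand.d_physical = 0.0
        for stim in [StimulusPair(1, 8, 8, 2), StimulusPair(9, 8, 2, 8)]:
            stroop = run_trial(
                stim, trained_weights, trained_weights, params,
                task="numerical", demand=demand,
            )
            comp = run_trial(
                StimulusPair(stim.num_left, stim.num_right),
                trained_weights, None, params, task="comparison",
            )
            assert stroop.rt == comp.rt
            assert stroop.response == comp.response


class TestCongruency:
    def test_published_example_is_congruent(self):
        assert congruency_of(StimulusPair(1, 8, 2, 8)) == "congruent"

    def test_larger_number_physically_smaller_is_incongruent(self):
        assert congruency_of(StimulusPair(1, 2, 8, 2)) == "incongruent"

    @given(
        nl=st.integers(1, 9), nr=st.integers(1, 9),
        pl=st.integers(1, 9), pr=st.integers(1, 9),
    )
    @settings(deadline=None, max_examples=100)
    def test_swapping_sides_preserves_label(self, nl, nr, pl, pr):
        if nl == nr or pl == pr:
            return
        s = StimulusPair(nl, nr, pl, pr)
        swapped = StimulusPair(nr, nl, pr, pl)
        assert congruency_of(s) == congruency_of(swapped)

    def test_missing_physical_dimension_rejected(self):
        with pytest.raises(ValueError):
            congruency_of(StimulusPair(1, 2))


class TestDistanceClass:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(2, 8, "small"), (1, 2, "small"), (8, 9, "small"),
         (1, 9, "large"), (1, 8, "large"), (2, 9, "large")],
    )
    def test_design_distances(self, a, b, expected):
        assert distance_class(a, b) == expected

    def test_other_distances_rejected(self):
        with pytest.raises(ValueError):
            distance_class(3, 5)

    def test_validation_set_balances_distance_classes(self):
        from numstroop import build_validation_set

        trials = build_validation_set()
        classes = [distance_class(s.num_left, s.num_right) for s in trials]
        assert classes.count("small") == classes.count("large") == 72
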