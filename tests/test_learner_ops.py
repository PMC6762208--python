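"""Unit tests of each learner operation against hand-computed values."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from lslearn import (
    ContextEvent,
    FeatureVector,
    ModelParams,
    apply_context_shift,
    center_reward,
    compute_errors,
    predict_rewards,
    report_associative_strength,
    ruminate,
    spawn_state,
    update_beliefs,
    update_change_stat,
    update_effort,
    update_strengths,
    update_variance,
)

from conftest import make_state


@pytest.mark.parametrize(
    "reinforced, centering, expected",
    [(True, True, 0.5), (False, True, -0.5), (True, False, 1.0), (False, False, 0.0)],
)
def test_center_reward(reinforced, centering, expected):
    assert center_reward(reinforced, centering) == expected


class TestPredictAndErrors:
    def test_single_state(self, params):
        state = make_state([[0.4, 0.0]], params)
        cues = FeatureVector(np.array([1.0, 0.0]), ("A", "B"))
        preds, marginal = predict_rewards(state, cues)
        assert preds.tolist() == [0.4]
        assert marginal == 0.4

    def test_symmetric_beliefs_cancel(self, params):
        state = make_state([[0.2], [-0.2]], params, beliefs=[0.5, 0.5])
        cues = FeatureVector(np.array([1.0]), ("A",))
        _, marginal = predict_rewards(state, cues)
        assert marginal == 0.0

    def test_belief_weighted_marginal(self, params):
        state = make_state([[0.4], [0.0]], params, beliefs=[0.8808, 0.1192])
        cues = FeatureVector(np.array([1.0]), ("A",))
        _, marginal = predict_rewards(state, cues)
        assert marginal == pytest.approx(0.35232, abs=1e-12)

    def test_dimension_mismatch(self, params):
        state = make_state([[0.0, 0.0]], params)
        with pytest.raises(ValueError, match="dimension"):
            predict_rewards(state, FeatureVector(np.array([1.0]), ("A",)))

    def test_zero_strengths_error_is_reward(self, params):
        state = make_state([[0.0], [0.0]], params, beliefs=[0.5, 0.5])
        cues = FeatureVector(np.array([1.0]), ("A",))
        np.testing.assert_array_equal(compute_errors(state, cues, 0.5), [0.5, 0.5])

    def test_errors_subtract_predictions(self, params):
        state = make_state([[0.5], [-0.5]], params, beliefs=[0.5, 0.5])
        cues = FeatureVector(np.array([1.0]), ("A",))
        np.testing.assert_allclose(compute_errors(state, cues, 0.5), [0.0, 1.0])


class TestBeliefFilter:
    def test_single_state_stays_one(self, params):
        state = make_state([[0.0]], params)
        beliefs, l0 = update_beliefs(state, np.array([3.7]), params)
        assert beliefs.tolist() == [1.0]
        assert l0 > 0

    def test_symmetry(self, params):
        state = make_state([[0.0], [0.0]], params, beliefs=[0.5, 0.5])
        beliefs, _ = update_beliefs(state, np.array([0.7, 0.7]), params)
        np.testing.assert_allclose(beliefs, [0.5, 0.5], atol=1e-15)

    def test_normal_density_reweighting(self, params):
        # equal priors, sigma = 0.5, errors (0, 1): posterior is
        # phi(0) / (phi(0) + phi(2)) on the first state
        state = make_state([[0.0], [0.0]], params, beliefs=[0.5, 0.5], variance=0.25)
        beliefs, l0 = update_beliefs(state, np.array([0.0, 1.0]), params)
        expected_p1 = norm.pdf(0.0) / (norm.pdf(0.0) + norm.pdf(2.0))
        assert beliefs[0] == pytest.approx(expected_p1, abs=1e-14)
        assert beliefs[0] == pytest.approx(0.88080, abs=5e-6)
        assert beliefs[1] == pytest.approx(0.11920, abs=5e-6)
        assert l0 == pytest.approx(0.5 * (norm.pdf(0.0) + norm.pdf(2.0)), abs=1e-14)

    def test_underflow_falls_back_to_prior(self, params, caplog):
        state = make_state([[0.0]], params, variance=1e-8)
        with caplog.at_level("WARNING", logger="lslearn.learner"):
            beliefs, l0 = update_beliefs(state, np.array([100.0]), params)
        assert beliefs.tolist() == [1.0]
        assert l0 == 1e-300
        assert any("underflow" in rec.message for rec in caplog.records)


class TestChangeStat:
    def test_perfect_prediction_clamps_at_zero(self, params):
        state = make_state([[0.0]], params)
        assert update_change_stat(state, norm.pdf(0.0), params) == 0.0

    def test_log_ratio_of_densities(self, params):
        # log(phi(0)/phi(2)) = 2 exactly, minus delta=0.6 -> 1.4
        state = make_state([[0.0]], params)
        cand = update_change_stat(state, norm.pdf(2.0), params)
        assert cand == pytest.approx(1.4, abs=1e-12)

    def test_drift_subtracts(self, params):
        state = make_state([[0.0]], params)
        state.change_stat = 5.0
        assert update_change_stat(state, norm.pdf(0.0), params) == pytest.approx(4.4, abs=1e-12)

    def test_does_not_mutate(self, params):
        state = make_state([[0.0]], params)
        state.change_stat = 5.0
        update_change_stat(state, norm.pdf(0.0), params)
        assert state.change_stat == 5.0


class TestSpawn:
    def test_single_cue(self, params):
        state = make_state([[0.0, 0.0]], params)
        cues = FeatureVector(np.array([1.0, 0.0]), ("A", "B"))
        spawn_state(state, cues, 0.5)
        np.testing.assert_array_equal(state.components[-1].strengths, [0.5, 0.0])

    def test_compound_prediction_equals_reward(self, params):
        state = make_state([[0.0, 0.0]], params)
        cues = FeatureVector(np.array([1.0, 1.0]), ("A", "B"))
        spawn_state(state, cues, 0.5)
        new = state.components[-1]
        np.testing.assert_array_equal(new.strengths, [0.25, 0.25])
        assert float(cues.values @ new.strengths) == 0.5

    def test_resets_q_and_belief(self, params):
        state = make_state([[0.0]], params)
        state.change_stat = 1.4
        spawn_state(state, FeatureVector(np.array([1.0]), ("A",)), 0.5)
        assert state.change_stat == 0.0
        assert state.components[-1].belief == 0.0
        assert state.beliefs.sum() == 1.0

    def test_zero_cues_error(self, params):
        state = make_state([[0.0]], params)
        with pytest.raises(ValueError, match="all-zero"):
            spawn_state(state, FeatureVector(np.array([0.0]), ("A",)), 0.5)


class TestValueUpdate:
    def test_zero_belief_untouched(self, params):
        # the second state owns all belief so the simplex still sums to one
        state2 = make_state([[0.3], [0.0]], params, beliefs=[0.0, 1.0])
        cues = FeatureVector(np.array([1.0]), ("A",))
        update_strengths(state2, cues, np.array([0.5, 0.0]), params)
        assert state2.components[0].strengths[0] == 0.3

    def test_zero_error_untouched(self, params):
        state = make_state([[0.3]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        update_strengths(state, cues, np.array([0.0]), params)
        assert state.components[0].strengths[0] == 0.3

    def test_scalar_delta(self, params):
        state = make_state([[0.0]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        update_strengths(state, cues, np.array([0.5]), params)
        assert state.components[0].strengths[0] == pytest.approx(0.025, abs=1e-15)

    def test_singular_effort_is_reported(self, params):
        state = make_state([[0.0]], params, efforts=[np.array([[0.0]])])
        cues = FeatureVector(np.array([1.0]), ("A",))
        with pytest.raises(np.linalg.LinAlgError, match="latent state 0"):
            update_strengths(state, cues, np.array([0.5]), params)


class TestEffortUpdate:
    def test_zero_belief_pure_decay(self, params):
        state = make_state([[0.0], [0.0]], params, beliefs=[1.0, 0.0])
        cues = FeatureVector(np.array([1.0]), ("A",))
        update_effort(state, cues, params)
        assert state.components[1].effort[0, 0] == pytest.approx(0.95, abs=1e-15)

    def test_scalar_fixed_point(self, params):
        state = make_state([[0.0]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        update_effort(state, cues, params)
        assert state.components[0].effort[0, 0] == pytest.approx(1.0, abs=1e-15)

    def test_two_feature_update(self, params):
        state = make_state([[0.0, 0.0]], params)
        cues = FeatureVector(np.array([1.0, 1.0]), ("A", "B"))
        update_effort(state, cues, params)
        np.testing.assert_allclose(
            state.components[0].effort, [[1.0, 0.05], [0.05, 1.0]], atol=1e-15
        )

    def test_symmetry_exact(self, params):
        state = make_state([[0.0, 0.0, 0.0]], params)
        cues = FeatureVector(np.array([1.0, 0.3, 0.7]), ("A", "B", "C"))
        for _ in range(50):
            update_effort(state, cues, params)
        B = state.components[0].effort
        assert np.array_equal(B, B.T)


class TestVarianceUpdate:
    def test_zero_errors_decay(self, params):
        state = make_state([[0.0]], params, variance=0.25)
        update_variance(state, np.array([0.0]), params)
        assert state.variance == pytest.approx(0.95 * 0.25, abs=1e-15)

    def test_fixed_point(self, params):
        state = make_state([[0.0]], params, variance=0.25)
        update_variance(state, np.array([0.5]), params)
        assert state.variance == pytest.approx(0.25, abs=1e-15)

    def test_moves_toward_mean_square(self, params):
        state = make_state([[0.0]], params, variance=0.25)
        update_variance(state, np.array([1.0]), params)
        assert state.variance == pytest.approx(0.2875, abs=1e-15)

    def test_floor(self, params):
        state = make_state([[0.0]], params, variance=1e-8)
        update_variance(state, np.array([0.0]), params)
        assert state.variance == 1e-8


class TestContextShift:
    def test_temporal_iti_one_is_identity(self, params):
        state = make_state([[0.0], [0.0]], params, beliefs=[0.9, 0.1])
        apply_context_shift(state, ContextEvent("temporal", iti=1), params)
        np.testing.assert_array_equal(state.beliefs, [0.9, 0.1])

    def test_spatial_is_uniform(self, params):
        state = make_state([[0.0], [0.0], [0.0]], params, beliefs=[1.0, 0.0, 0.0])
        apply_context_shift(state, ContextEvent("spatial"), params)
        np.testing.assert_array_equal(state.beliefs, [1 / 3, 1 / 3, 1 / 3])

    def test_temporal_corrosion_value(self, params):
        state = make_state([[0.0], [0.0]], params, beliefs=[1.0, 0.0])
        apply_context_shift(state, ContextEvent("temporal", iti=3), params)
        w = 0.95**2
        np.testing.assert_allclose(
            state.beliefs, [w + (1 - w) / 2, (1 - w) / 2], atol=1e-15
        )
        assert state.beliefs[0] == pytest.approx(0.95125, abs=1e-12)
        assert state.beliefs[1] == pytest.approx(0.04875, abs=1e-12)

    def test_none_event_rejected(self, params):
        state = make_state([[0.0]], params)
        with pytest.raises(ValueError):
            apply_context_shift(state, ContextEvent("none"), params)


class TestRumination:
    def test_iti_one_is_noop(self, params):
        state = make_state([[0.3]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        ruminate(state, cues, 0.5, ContextEvent("temporal", iti=1), params)
        assert state.components[0].strengths[0] == 0.3

    def test_chi_caps_iterations(self, params):
        # scalar case with p=1, B=1: each iteration contracts V toward R by
        # (1 - alpha0); five iterations exactly for a huge interval
        state = make_state([[0.0]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        ruminate(state, cues, 0.5, ContextEvent("temporal", iti=100), params)
        expected = 0.5 * (1 - 0.95**5)
        assert state.components[0].strengths[0] == pytest.approx(expected, rel=1e-12)

    def test_two_iterations_contract_twice(self, params):
        state = make_state([[0.0]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        ruminate(state, cues, 0.5, ContextEvent("temporal", iti=3), params)
        assert state.components[0].strengths[0] == pytest.approx(
            0.5 * (1 - 0.95**2), rel=1e-12
        )

    def test_spatial_rejected(self, params):
        state = make_state([[0.0]], params)
        cues = FeatureVector(np.array([1.0]), ("A",))
        with pytest.raises(ValueError, match="temporal"):
            ruminate(state, cues, 0.5, ContextEvent("spatial"), params)


class TestReportedStrength:
    def test_single_state(self, params):
        state = make_state([[0.4, 0.1, 0.0]], params)
        template = FeatureVector(np.zeros(3), ("A", "B", "A*B"))
        assert report_associative_strength(state, template, "A") == 0.4

    def test_uniform_beliefs_average(self, params):
        state = make_state([[0.4, 0, 0], [-0.2, 0, 0]], params, beliefs=[0.5, 0.5])
        template = FeatureVector(np.zeros(3), ("A", "B", "A*B"))
        assert report_associative_strength(state, template, "A") == pytest.approx(0.1)

    def test_weighted(self, params):
        state = make_state([[0.4], [0.0]], params, beliefs=[0.8808, 0.1192])
        template = FeatureVector(np.zeros(1), ("A",))
        assert report_associative_strength(state, template, "A") == pytest.approx(
            0.35232, abs=1e-12
        )

    def test_uncenter_shifts_half(self, params):
        state = make_state([[0.4]], params)
        template = FeatureVector(np.zeros(1), ("A",))
        assert report_associative_strength(state, template, "A", uncenter=True) == 0.9

    def test_unknown_label(self, params):
        state = make_state([[0.4]], params)
        template = FeatureVector(np.zeros(1), ("A",))
        with pytest.raises(KeyError, match="Z"):
            report_associative_strength(state, template, "Z")


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha0": 1.5},
            {"beta0": -0.1},
            {"gamma": 2.0},
            {"sigma0": 0.0},
            {"nu": -1.0},
            {"delta": 0.0},
            {"chi": -1},
            {"chi": 2.5},
            {"max_states": 0},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_defaults_are_simulation_set(self, params):
        assert (
            params.alpha0,
            params.beta0,
            params.gamma,
            params.sigma0,
            params.nu,
            params.delta,
            params.chi,
            params.max_states,
        ) == (0.05, 0.05, 0.05, 0.5, 0.2, 0.6, 5, 15)
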