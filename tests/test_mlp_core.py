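"""Network arithmetic: forward pass, objective, gradient, training loop."""

import math

import numpy as np
import pytest

import adductrisk as ar
from adductrisk import mlp_core


def random_params(rng, p=4, m=10, scale=0.5):
    return ar.MLPParameters(
        hidden_weights=rng.uniform(-scale, scale, (m, p)),
        hidden_biases=rng.uniform(-scale, scale, m),
        output_weights=rng.uniform(-scale, scale, m),
        output_bias=float(rng.uniform(-scale, scale)),
    )


def random_features(rng, n=12, p=4):
    subset = ar.AdductSubset(ar.FULL_PANEL[:p])
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    return ar.FeatureMatrix(
        x=rng.normal(size=(n, p)),
        y=y,
        subject_ids=tuple(str(i) for i in range(n)),
        adducts=subset,
    )


def finite_difference_gradient(params, features, alpha, step=1e-6):
    """Central finite differences on the flat parameter vector."""
    w0 = params.to_vector()
    p, m = params.n_inputs, params.n_hidden
    grad = np.empty_like(w0)
    for i in range(w0.size):
        w_plus, w_minus = w0.copy(), w0.copy()
        w_plus[i] += step
        w_minus[i] -= step
        grad[i] = (
            ar.objective(ar.MLPParameters.from_vector(w_plus, p, m), features, alpha)
            - ar.objective(ar.MLPParameters.from_vector(w_minus, p, m), features, alpha)
        ) / (2 * step)
    return grad


class TestParameterCount:
    @pytest.mark.parametrize("p,m,expected", [(4, 10, 61), (1, 1, 4), (3, 7, 36)])
    def test_counts(self, p, m, expected):
        assert ar.parameter_count(p, m) == expected

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ar.parameter_count(0, 10)


class TestForward:
    def test_hidden_activation_closed_forms(self):
        assert mlp_core.hidden_activation(np.zeros(3), np.zeros(3), 0.0) == 0.5
        assert mlp_core.hidden_activation(np.zeros(2), np.zeros(2), 50.0) == pytest.approx(1.0)
        # affine term (1+1) - 2 = 0
        assert mlp_core.hidden_activation(
            np.array([1.0, 1.0]), np.array([1.0, 1.0]), -2.0
        ) == 0.5

    def test_all_zero_parameters_give_half(self):
        params = ar.MLPParameters(np.zeros((10, 4)), np.zeros(10), np.zeros(10), 0.0)
        assert ar.forward(np.ones(4), params) == 0.5

    def test_output_bias_only(self):
        params = ar.MLPParameters(np.zeros((10, 4)), np.zeros(10), np.zeros(10), math.log(3))
        assert ar.forward(np.zeros(4), params) == pytest.approx(0.75)

    def test_single_hidden_node_hand_evaluation(self):
        # hidden output 0.5, so logistic(2 * 0.5 - 1) = 0.5
        params = ar.MLPParameters(np.zeros((1, 2)), np.zeros(1), np.array([2.0]), -1.0)
        assert ar.forward(np.array([3.0, -1.0]), params) == pytest.approx(0.5)

    def test_batch_matches_single_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        params = random_params(rng, scale=3.0)
        x = rng.normal(scale=5.0, size=(20, 4))
        batch = ar.forward(x, params)
        assert np.all((batch > 0) & (batch < 1))
        for i in range(5):
            assert batch[i] == pytest.approx(ar.forward(x[i], params))

    def test_dimension_mismatch_rejected(self):
        params = random_params(np.random.default_rng(1), p=4)
        with pytest.raises(ValueError, match="dimension"):
            ar.forward(np.zeros(3), params)


class TestObjective:
    def test_zero_network_balanced_labels_gives_quarter(self):
        rng = np.random.default_rng(2)
        features = random_features(rng, n=10)
        params = ar.MLPParameters(np.zeros((10, 4)), np.zeros(10), np.zeros(10), 0.0)
        assert ar.objective(params, features, alpha=0.0) == pytest.approx(0.25)

    def test_decay_term_adds_half_alpha_norm(self):
        rng = np.random.default_rng(3)
        features = random_features(rng)
        params = random_params(rng)
        alpha = 0.0004
        base = ar.objective(params, features, alpha=0.0)
        penalised = ar.objective(params, features, alpha=alpha)
        assert penalised - base == pytest.approx(0.5 * alpha * params.squared_norm())

    def test_unit_norm_two_example(self):
        # ||w||^2 = 2 with alpha = 0.0004 contributes exactly 0.0004
        params = ar.MLPParameters(np.zeros((1, 1)), np.zeros(1), np.array([1.0]), 1.0)
        assert params.squared_norm() == pytest.approx(2.0)
        rng = np.random.default_rng(4)
        features = random_features(rng, p=1)
        delta = ar.objective(params, features, 0.0004) - ar.objective(params, features, 0.0)
        assert delta == pytest.approx(0.0004)


class TestGradient:
    def test_analytic_matches_central_finite_differences(self):
        rng = np.random.default_rng(5)
        features = random_features(rng, n=15)
        for _ in range(20):
            params = random_params(rng)
            analytic = ar.gradient(params, features, alpha=0.0004).to_vector()
            numeric = finite_difference_gradient(params, features, alpha=0.0004)
            assert np.max(np.abs(analytic - numeric)) < 1e-6

    def test_decay_contribution_is_alpha_times_w(self):
        rng = np.random.default_rng(6)
        features = random_features(rng)
        params = random_params(rng)
        alpha = 0.3
        with_decay = ar.gradient(params, features, alpha).to_vector()
        without = ar.gradient(params, features, 0.0).to_vector()
        np.testing.assert_allclose(with_decay - without, alpha * params.to_vector())

    def test_identical_hidden_nodes_receive_identical_gradients(self):
        rng = np.random.default_rng(7)
        features = random_features(rng)
        row = rng.normal(size=4)
        params = ar.MLPParameters(
            hidden_weights=np.tile(row, (3, 1)),
            hidden_biases=np.full(3, 0.2),
            output_weights=np.full(3, -0.4),
            output_bias=0.1,
        )
        grad = ar.gradient(params, features, alpha=0.01)
        np.testing.assert_allclose(grad.hidden_weights[0], grad.hidden_weights[1])
        np.testing.assert_allclose(grad.hidden_weights[0], grad.hidden_weights[2])
        assert grad.output_weights[0] == grad.output_weights[1] == grad.output_weights[2]
        assert grad.hidden_biases[0] == grad.hidden_biases[1] == grad.hidden_biases[2]


def toy_features(n_per_class=10):
    """1-D linearly separable toy: cases at +2, controls at -2."""
    x = np.r_[np.full(n_per_class, 2.0), np.full(n_per_class, -2.0)][:, None]
    y = np.r_[np.ones(n_per_class), np.zeros(n_per_class)]
    return ar.FeatureMatrix(
        x=x, y=y,
        subject_ids=tuple(str(i) for i in range(2 * n_per_class)),
        adducts=ar.AdductSubset((ar.Adduct.HB_34Q,)),
    )


class TestTraining:
    def test_separable_toy_is_fit_to_zero_error(self):
        params, trace = ar.train(toy_features(), ar.TrainingConfig(seed=1))
        assert trace.final_error_rate_at_half == 0.0
        assert trace.final_objective < trace.objective_values[0]

    def test_zero_step_leaves_initial_parameters(self):
        features = toy_features()
        one = ar.train(features, ar.TrainingConfig(mu=0.0, n_updates=1, seed=9))[0]
        many = ar.train(features, ar.TrainingConfig(mu=0.0, n_updates=500, seed=9))[0]
        np.testing.assert_array_equal(one.to_vector(), many.to_vector())

    def test_training_is_deterministic_given_seed(self, fast_tconfig, small_cohort):
        features = ar.build_features(small_cohort)
        first = ar.train(features, fast_tconfig)[0]
        second = ar.train(features, fast_tconfig)[0]
        np.testing.assert_array_equal(first.to_vector(), second.to_vector())

    def test_strong_decay_shrinks_the_weight_norm(self):
        features = toy_features()
        loose = ar.train(features, ar.TrainingConfig(alpha=0.0, n_updates=5000, seed=2))[0]
        tight = ar.train(features, ar.TrainingConfig(alpha=0.5, n_updates=5000, seed=2))[0]
        assert tight.squared_norm() < loose.squared_norm()

    def test_single_class_data_is_rejected(self):
        features = ar.FeatureMatrix(
            x=np.zeros((4, 1)),
            y=np.ones(4),
            subject_ids=("a", "b", "c", "d"),
            adducts=ar.AdductSubset((ar.Adduct.HB_34Q,)),
        )
        with pytest.raises(ValueError, match="case and one control"):
            ar.train(features, ar.TrainingConfig(n_updates=1))

    def test_trace_is_nonnegative_and_anchored(self, fast_tconfig):
        _, trace = ar.train(toy_features(), fast_tconfig)
        assert np.all(trace.objective_values >= 0)
        assert trace.iterations[0] == 0
        assert trace.iterations[-1] == fast_tconfig.n_updates
        assert trace.final_objective == trace.objective_values[-1]


class TestSerialization:
    def test_round_trip_restores_identical_outputs(self, tmp_path):
        rng = np.random.default_rng(8)
        params = random_params(rng)
        path = tmp_path / "params.txt"
        mlp_core.save_parameters(params, path)
        restored = mlp_core.load_parameters(path)
        np.testing.assert_array_equal(params.to_vector(), restored.to_vector())
        x = rng.normal(size=(7, 4))
        np.testing.assert_array_equal(ar.forward(x, params), ar.forward(x, restored))

    def test_vector_order_is_canonical(self):
        # (d, c0, a_1..a_m, c_1..c_m)
        params = ar.MLPParameters(
            hidden_weights=np.array([[1.0, 2.0], [3.0, 4.0]]),
            hidden_biases=np.array([5.0, 6.0]),
            output_weights=np.array([7.0, 8.0]),
            output_bias=9.0,
        )
        np.testing.assert_array_equal(
            params.to_vector(), [7, 8, 9, 1, 2, 3, 4, 5, 6]
        )
        rebuilt = ar.MLPParameters.from_vector(params.to_vector(), 2, 2)
        np.testing.assert_array_equal(rebuilt.hidden_weights, params.hidden_weights)
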