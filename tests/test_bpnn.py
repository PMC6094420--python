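import numpy as np
import pytest

from eemcalib.bpnn import (
    NetworkState,
    ScalingParams,
    TrainConfig,
    forward,
    gradients,
    init_network,
    load_state,
    mse_loss,
    predict,
    save_state,
    train,
    train_step,
)


def flatten_params(state):
    return np.concatenate([
        state.hidden_weights.ravel(),
        state.hidden_biases,
        state.output_weights,
        [state.output_bias],
    ])


class TestInit:
    def test_deterministic_under_seed(self):
        a, b = init_network(4, 3, seed=7), init_network(4, 3, seed=7)
        np.testing.assert_array_equal(flatten_params(a), flatten_params(b))
        c = init_network(4, 3, seed=8)
        assert not np.array_equal(flatten_params(a), flatten_params(c))

    def test_parameter_count_for_6_5_1(self):
        state = init_network(6, 5, seed=0)
        assert state.n_parameters == 6 * 5 + 5 + 5 + 1  # 41

    def test_weights_in_init_range_and_buffers_zero(self):
        state = init_network(10, 8, seed=1)
        assert np.abs(flatten_params(state)).max() <= 0.3
        assert not state.prev_dW1.any() and not state.prev_db1.any()
        assert not state.prev_dw2.any() and state.prev_db2 == 0.0

    @pytest.mark.parametrize("ni,nh", [(0, 3), (3, 0)])
    def test_degenerate_sizes_rejected(self, ni, nh):
        with pytest.raises(ValueError):
            init_network(ni, nh)


class TestForward:
    def test_zero_output_layer_gives_zero(self):
        state = init_network(3, 4, seed=0)
        state.output_weights[:] = 0.0
        state.output_bias = 0.0
        assert forward(state, np.array([1.0, -2.0, 0.5])) == 0.0

    def test_matches_hand_computed_2_2_1(self):
        # by-hand evaluation of y = sum_J W_J sigmoid(sum_I W_JI x_I + b_J) + b_out
        state = NetworkState(
            hidden_weights=np.array([[1.0, -1.0], [0.5, 0.25]]),
            hidden_biases=np.array([0.1, -0.2]),
            output_weights=np.array([2.0, -3.0]),
            output_bias=0.5,
        )
        x = np.array([0.4, 0.6])
        h1 = 1 / (1 + np.exp(-(1.0 * 0.4 - 1.0 * 0.6 + 0.1)))
        h2 = 1 / (1 + np.exp(-(0.5 * 0.4 + 0.25 * 0.6 - 0.2)))
        expected = 2.0 * h1 - 3.0 * h2 + 0.5
        assert forward(state, x) == pytest.approx(expected, rel=1e-12)

    def test_output_finite_for_extreme_inputs(self):
        state = init_network(2, 3, seed=2)
        assert np.isfinite(forward(state, np.array([1e6, -1e6])))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            forward(init_network(3, 2), np.array([1.0, 2.0]))


class TestGradients:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        state = init_network(3, 4, seed=seed)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        analytic = gradients(state, X, y)
        eps = 1e-6

        def fd(getter, setter, idx):
            orig = getter()[idx]
            setter(idx, orig + eps)
            up = mse_loss(state, X, y)
            setter(idx, orig - eps)
            down = mse_loss(state, X, y)
            setter(idx, orig)
            return (up - down) / (2 * eps)

        for (j, i) in [(0, 0), (1, 2), (3, 1)]:
            num = fd(lambda: state.hidden_weights,
                     lambda idx, v: state.hidden_weights.__setitem__(idx, v), (j, i))
            assert analytic["hidden_weights"][j, i] == pytest.approx(num, rel=1e-6, abs=1e-10)
        for j in range(4):
            num = fd(lambda: state.hidden_biases,
                     lambda idx, v: state.hidden_biases.__setitem__(idx, v), j)
            assert analytic["hidden_biases"][j] == pytest.approx(num, rel=1e-6, abs=1e-10)
            num = fd(lambda: state.output_weights,
                     lambda idx, v: state.output_weights.__setitem__(idx, v), j)
            assert analytic["output_weights"][j] == pytest.approx(num, rel=1e-6, abs=1e-10)
        orig = state.output_bias
        state.output_bias = orig + eps
        up = mse_loss(state, X, y)
        state.output_bias = orig - eps
        down = mse_loss(state, X, y)
        state.output_bias = orig
        assert float(analytic["output_bias"]) == pytest.approx((up - down) / (2 * eps),
                                                               rel=1e-6, abs=1e-10)


class TestTrainStep:
    def test_zero_learning_rate_is_fixed_point(self):
        rng = np.random.default_rng(0)
        state = init_network(3, 2, seed=0)
        before = flatten_params(state).copy()
        cfg = TrainConfig(learning_rate=0.0, momentum=0.0, max_epochs=1)
        for _ in range(5):
            train_step(state, rng.normal(size=(4, 3)), rng.normal(size=4), cfg)
        np.testing.assert_array_equal(flatten_params(state), before)

    def test_zero_learning_rate_fixed_point_even_with_momentum(self):
        rng = np.random.default_rng(1)
        state = init_network(3, 2, seed=1)
        before = flatten_params(state).copy()
        cfg = TrainConfig(learning_rate=0.0, momentum=0.8, max_epochs=1)
        for _ in range(5):
            train_step(state, rng.normal(size=(4, 3)), rng.normal(size=4), cfg)
        np.testing.assert_array_equal(flatten_params(state), before)

    def test_momentum_free_update_is_plain_gradient_descent(self):
        rng = np.random.default_rng(2)
        state = init_network(3, 2, seed=2)
        X, y = rng.normal(size=(5, 3)), rng.normal(size=5)
        grads = gradients(state, X, y)
        expected_W1 = state.hidden_weights - 0.4 * grads["hidden_weights"]
        cfg = TrainConfig(learning_rate=0.4, momentum=0.0, max_epochs=1)
        train_step(state, X, y, cfg)
        np.testing.assert_allclose(state.hidden_weights, expected_W1, rtol=1e-12)

    def test_momentum_adds_previous_update(self):
        rng = np.random.default_rng(3)
        state = init_network(2, 2, seed=3)
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        cfg = TrainConfig(learning_rate=0.3, momentum=0.6, max_epochs=1)
        train_step(state, X, y, cfg)
        prev = state.prev_dW1.copy()
        grads = gradients(state, X, y)
        expected = state.hidden_weights - 0.3 * grads["hidden_weights"] + 0.6 * prev
        train_step(state, X, y, cfg)
        np.testing.assert_allclose(state.hidden_weights, expected, rtol=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            train_step(init_network(2, 2), np.empty((0, 2)), np.empty(0), TrainConfig())


class TestTrain:
    @pytest.fixture()
    def linear_problem(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        w = np.array([0.5, -0.3, 0.2])
        y = X @ w  # noiseless, linearly predictable
        return X[:24], y[:24], X[24:], y[24:]

    def test_training_error_collapses_on_noiseless_linear_targets(self, linear_problem):
        X_tr, y_tr, X_val, y_val = linear_problem
        state = init_network(3, 3, seed=5)
        initial = mse_loss(state, X_tr, y_tr)
        cfg = TrainConfig(learning_rate=0.7, momentum=0.9, max_epochs=2000, patience=2000, seed=5)
        result = train(state, X_tr, y_tr, X_val, y_val, cfg)
        assert result.train_mse[-1] < 1e-4 * initial

    def test_infinite_patience_runs_to_max_epochs(self, linear_problem):
        X_tr, y_tr, X_val, y_val = linear_problem
        cfg = TrainConfig(max_epochs=50, patience=10**9)
        result = train(init_network(3, 2, seed=1), X_tr, y_tr, X_val, y_val, cfg)
        assert result.stopping_epoch == 50

    def test_returned_state_attains_minimum_validation_mse(self, linear_problem):
        X_tr, y_tr, X_val, y_val = linear_problem
        cfg = TrainConfig(max_epochs=400, patience=30, seed=2)
        result = train(init_network(3, 4, seed=2), X_tr, y_tr, X_val, y_val, cfg)
        returned_val = mse_loss(result.state, X_val, y_val)
        assert returned_val <= min(result.validation_mse) + 1e-15

    def test_early_stopping_halts_before_max_epochs_when_stuck(self, linear_problem):
        X_tr, y_tr, X_val, y_val = linear_problem
        cfg = TrainConfig(learning_rate=0.0, momentum=0.0, max_epochs=500, patience=5)
        result = train(init_network(3, 2, seed=3), X_tr, y_tr, X_val, y_val, cfg)
        assert result.stopping_epoch == 5  # no improvement possible at mu = 0

    def test_determinism(self, linear_problem):
        X_tr, y_tr, X_val, y_val = linear_problem
        cfg = TrainConfig(max_epochs=100, seed=4)
        r1 = train(init_network(3, 3, seed=4), X_tr, y_tr, X_val, y_val, cfg)
        r2 = train(init_network(3, 3, seed=4), X_tr, y_tr, X_val, y_val, cfg)
        np.testing.assert_array_equal(flatten_params(r1.state), flatten_params(r2.state))
        assert r1.validation_mse == r2.validation_mse

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train(init_network(2, 2), np.empty((0, 2)), np.empty(0),
                  np.ones((1, 2)), np.ones(1), TrainConfig())


class TestScalingAndPredict:
    def test_scaling_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 4)), rng.uniform(1e-8, 5e-6, size=20)
        sc = ScalingParams.fit(X, y)
        np.testing.assert_allclose(sc.unscale_y(sc.scale_y(y)), y, rtol=1e-12)
        t = sc.scale_y(y)
        assert t.min() >= 0.1 - 1e-12 and t.max() <= 0.9 + 1e-12

    def test_converged_fit_recovers_training_targets(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = 1e-6 * (2.0 + X @ np.array([0.5, -0.25]))  # molar-scale linear targets
        sc = ScalingParams.fit(X, y)
        state = init_network(2, 3, seed=1)
        cfg = TrainConfig(learning_rate=0.7, momentum=0.9, max_epochs=8000, patience=8000)
        train(state, sc.scale_x(X), sc.scale_y(y), sc.scale_x(X), sc.scale_y(y), cfg)
        pred = predict(state, sc, X)
        np.testing.assert_allclose(pred, y, rtol=0.01)

    def test_constant_network_predicts_inverse_scaled_bias(self):
        state = init_network(2, 2, seed=0)
        state.output_weights[:] = 0.0
        state.output_bias = 0.5
        sc = ScalingParams(x_mean=np.zeros(2), x_sd=np.ones(2), y_min=0.0, y_max=1e-6)
        pred = predict(state, sc, np.array([[1.0, 2.0], [-3.0, 4.0]]))
        np.testing.assert_allclose(pred, sc.unscale_y(np.array([0.5, 0.5])))

    def test_state_serialization_round_trip(self, tmp_path):
        state = init_network(3, 4, seed=9)
        sc = ScalingParams.fit(np.random.default_rng(0).normal(size=(10, 3)),
                               np.linspace(1e-8, 1e-6, 10))
        cfg = TrainConfig(seed=9)
        path = str(tmp_path / "net.json")
        save_state(state, sc, cfg, path)
        state2, sc2, cfg2 = load_state(path)
        np.testing.assert_array_equal(flatten_params(state), flatten_params(state2))
        np.testing.assert_array_equal(sc.x_mean, sc2.x_mean)
        assert cfg2 == cfg
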