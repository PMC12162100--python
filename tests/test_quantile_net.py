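"""Pinball loss, network construction/training contracts, and the
quantile-recovery behaviour of the two-headed regression network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conformix import (QuantileModelConfig, build_network, load_model,
                       pinball_loss, predict_quantiles, save_model, train)
from conformix.quantile_net import QuantileModel


class TestPinballLoss:
    @pytest.mark.parametrize("y,y_hat,alpha,expected", [
        (0.4, 0.4, 0.3, 0.0),
        (1.0, 0.0, 0.1, 0.1),
        (0.0, 1.0, 0.1, 0.9),
        (2.0, 0.5, 0.25, 0.25 * 1.5),
    ])
    def test_branch_values(self, y, y_hat, alpha, expected):
        assert pinball_loss(y, y_hat, alpha) == pytest.approx(expected)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_median_level_is_half_l1(self, y, y_hat):
        assert pinball_loss(y, y_hat, 0.5) == pytest.approx(0.5 * abs(y - y_hat))

    @given(st.floats(-5, 5), st.floats(-5, 5),
           st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative(self, y, y_hat, alpha):
        assert pinball_loss(y, y_hat, alpha) >= 0.0

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.7])
    def test_invalid_level_rejected(self, alpha):
        with pytest.raises(ValueError):
            pinball_loss(1.0, 0.0, alpha)


class TestBuildNetwork:
    def test_forward_shape_contract(self):
        cfg = QuantileModelConfig(hidden_sizes=(8, 8, 8, 8), seed=0, alpha=0.2)
        model = build_network(cfg, 20)
        out, _ = model._forward(np.random.default_rng(0).random((5, 20)))
        assert out.shape == (5, 2)

    def test_same_seed_identical_parameters(self):
        cfg = QuantileModelConfig(seed=11, alpha=0.1)
        a, b = build_network(cfg, 10), build_network(cfg, 10)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_eval_mode_forward_is_deterministic(self):
        cfg = QuantileModelConfig(dropout_rate=0.5, seed=3, alpha=0.1)
        model = build_network(cfg, 6)
        X = np.random.default_rng(1).random((7, 6))
        lo1, hi1 = predict_quantiles(model, X)
        lo2, hi2 = predict_quantiles(model, X)
        np.testing.assert_array_equal(lo1, lo2)
        np.testing.assert_array_equal(hi1, hi2)

    @pytest.mark.parametrize("bad", [
        dict(hidden_sizes=(8, 8, 8)), dict(hidden_sizes=(8, 8, 8, 0)),
        dict(dropout_rate=1.0), dict(alpha=0.0), dict(epochs=0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            QuantileModelConfig(**bad)


class TestTraining:
    def test_constant_target_recovered(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((200, 5)), np.full(200, 0.37)
        cfg = QuantileModelConfig(hidden_sizes=(8, 8, 8, 8), dropout_rate=0.0,
                                  learning_rate=0.01, epochs=300, batch_size=64,
                                  alpha=0.2, seed=2)
        model = train(build_network(cfg, 5), X, y, cfg)
        lo, hi = predict_quantiles(model, X)
        assert np.abs(lo - 0.37).mean() < 0.05
        assert np.abs(hi - 0.37).mean() < 0.05

    def test_unconditional_quantiles_of_uniform_target(self):
        # y independent of X: heads should settle at the 0.1 / 0.9 quantiles
        rng = np.random.default_rng(0)
        X, y = rng.random((2000, 5)), rng.random(2000)
        cfg = QuantileModelConfig(hidden_sizes=(16, 8, 8, 8), dropout_rate=0.0,
                                  learning_rate=0.05, epochs=200, batch_size=256,
                                  alpha=0.2, seed=1)
        model = train(build_network(cfg, 5), X, y, cfg)
        lo, hi = predict_quantiles(model, X)
        assert abs(lo.mean() - 0.1) < 0.05
        assert abs(hi.mean() - 0.9) < 0.05

    def test_loss_decreases_and_training_is_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.random((300, 8))
        y = np.clip(X[:, 0] * 0.8 + rng.normal(0, 0.05, 300), 0, 1)
        cfg = QuantileModelConfig(hidden_sizes=(16, 8, 8, 8), dropout_rate=0.1,
                                  learning_rate=0.01, epochs=30, batch_size=64,
                                  alpha=0.1, seed=9)
        m1 = train(build_network(cfg, 8), X, y, cfg)
        m2 = train(build_network(cfg, 8), X, y, cfg)
        assert m1.loss_history[-1] <= m1.loss_history[0]
        assert m1.loss_history == m2.loss_history

    def test_feature_mismatch_rejected(self):
        cfg = QuantileModelConfig(alpha=0.1, seed=0)
        model = build_network(cfg, 4)
        with pytest.raises(ValueError):
            train(model, np.zeros((10, 5)), np.zeros(10), cfg)
        with pytest.raises(ValueError):
            predict_quantiles(model, np.zeros((3, 5)))


class TestPredict:
    def test_crossed_outputs_swapped(self):
        # zero weights, head biases (0.6, 0.4): raw outputs cross on purpose
        cfg = QuantileModelConfig(hidden_sizes=(4, 4, 4, 4), alpha=0.2, seed=0)
        model = build_network(cfg, 3)
        for W in model.weights:
            W[:] = 0.0
        model.biases[-1][:] = [0.6, 0.4]
        lo, hi = predict_quantiles(model, np.ones((2, 3)))
        np.testing.assert_allclose(lo, 0.4)
        np.testing.assert_allclose(hi, 0.6)
        assert (lo <= hi).all()

    def test_pinball_minimizer_matches_empirical_quantile(self):
        # grid-search oracle: the constant minimizing mean pinball loss is
        # the empirical alpha-quantile
        y = np.random.default_rng(7).random(500)
        grid = np.linspace(0, 1, 401)
        for alpha in (0.1, 0.5, 0.9):
            losses = [np.mean(pinball_loss(y, np.full_like(y, c), alpha)) for c in grid]
            c_star = grid[int(np.argmin(losses))]
            assert abs(c_star - np.quantile(y, alpha)) < 0.02


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(0)
        X, y = rng.random((100, 6)), rng.random(100)
        cfg = QuantileModelConfig(hidden_sizes=(8, 8, 8, 8), epochs=5,
                                  alpha=0.1, seed=4)
        model = train(build_network(cfg, 6), X, y, cfg)
        from conformix import TransformSpec
        model.transform_spec = TransformSpec(
            retained_genes=np.array([f"g{i}" for i in range(6)], dtype=object))
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        loaded = load_model(path)
        assert isinstance(loaded, QuantileModel)
        np.testing.assert_array_equal(
            np.c_[predict_quantiles(model, X)], np.c_[predict_quantiles(loaded, X)])
        assert list(loaded.transform_spec.retained_genes) == [f"g{i}" for i in range(6)]
        assert loaded.config.alpha == 0.1
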