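import numpy as np
import pytest

from idrpred.errors import DataError
from idrpred.network import (
    DisorderNet,
    ModelConfig,
    TrainConfig,
    bce_loss,
    build_model,
    load_checkpoint,
    predict_protein,
    save_checkpoint,
    train,
)

TINY = ModelConfig(
    block_channels=(4, 4, 8, 8, 8),
    mlp2_hidden=64,
)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(TINY, seed=0)


class TestArchitecture:
    def test_mlp1_output_width_is_image_volume(self):
        cfg = ModelConfig()
        assert cfg.projection_width == 35 * 35 * 3 == 3675
        model = build_model(ModelConfig.small(), seed=0)
        assert model.mlp1[2].W.shape == (35, 3675)
        assert model.projection.W.shape[1] == 3675

    def test_backbone_spatial_collapse(self, tiny_model):
        # five 2x2 floor pools: 35 -> 17 -> 8 -> 4 -> 2 -> 1
        assert tiny_model._flat_width == 1 * 1 * TINY.block_channels[-1]

    def test_forward_shape_contract(self, tiny_model, rng):
        for m in (1, 3, 17):
            p = tiny_model.forward(rng.normal(size=(m, 35)))
            assert p.shape == (m,)
            assert np.all((p > 0) & (p < 1))

    def test_bad_input_width(self, tiny_model):
        with pytest.raises(DataError):
            tiny_model.forward(np.zeros((4, 12)))

    def test_seeded_builds_identical(self, rng):
        X = rng.normal(size=(5, 35))
        a = build_model(TINY, seed=42).forward(X)
        b = build_model(TINY, seed=42).forward(X)
        np.testing.assert_array_equal(a, b)
        c = build_model(TINY, seed=43).forward(X)
        assert not np.array_equal(a, c)

    def test_pretrained_without_weights_errors(self):
        cfg = ModelConfig(
            block_channels=(4, 4, 8, 8, 8), mlp2_hidden=64,
            pretrained_backbone=True, pretrained_path=None,
        )
        with pytest.raises(DataError, match="pretrained"):
            build_model(cfg, seed=0)


class TestLoss:
    def test_perfect_prediction_vanishes(self):
        assert bce_loss(np.array([1.0 - 1e-9]), np.array([1.0])) < 1e-5

    def test_half_probability_is_ln2(self):
        assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(0.693147, abs=1e-6)

    def test_mean_of_equal_terms(self):
        assert bce_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(
            0.693147, abs=1e-6
        )

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            bce_loss(np.array([0.5]), np.array([1.0, 0.0]))

    def test_gradient_matches_finite_difference(self, rng):
        # backprop through the full network vs. central differences on a
        # handful of weights; biases are shifted positive so the probed
        # weights sit away from ReLU/max-pool kinks where the loss is
        # non-differentiable
        model = build_model(TINY, seed=1)
        model.config.dropout = 0.0
        for layer in model._layers():
            if hasattr(layer, "b"):
                layer.b += 0.5
        X = rng.normal(size=(6, 35)).astype(np.float32)
        y = (rng.random(6) < 0.5).astype(np.float32)

        def loss_now():
            return bce_loss(model.forward(X.copy()), y)

        a = model.forward(X, train=True, rng=None)
        model.backward(((np.clip(a, 1e-7, 1 - 1e-7) - y) / len(y)).astype(np.float32))
        checks = [
            (model.mlp1[0].W, model.mlp1[0].dW),
            (model.projection.W, model.projection.dW),
            (model.mlp2_out.W, model.mlp2_out.dW),
        ]
        eps = 1e-2
        for W, dW in checks:
            # probe the largest-magnitude gradient entry: best signal-to-noise
            # against float32 forward-pass rounding
            idx = np.unravel_index(np.abs(dW).argmax(), dW.shape)
            orig = W[idx]
            W[idx] = orig + eps
            up = loss_now()
            W[idx] = orig - eps
            down = loss_now()
            W[idx] = orig
            fd = (up - down) / (2 * eps)
            assert dW[idx] == pytest.approx(fd, rel=0.05, abs=1e-5)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(9)
    n = 512
    y = (rng.random(n) < 0.4).astype(np.float32)
    X = rng.normal(size=(n, 35)).astype(np.float32)
    X[:, 0] += 4.0 * (2 * y - 1)  # strongly informative channel
    return X, y


class TestTraining:
    def test_loss_decreases_on_separable_data(self, separable):
        X, y = separable
        model = build_model(TINY, seed=3)
        history = train(
            model, X, y,
            TrainConfig(package_size=128, learning_rate=0.05, max_epochs=15, seed=4),
        )
        assert history[-1] < history[0]

    def test_same_seed_identical_history(self, separable):
        X, y = separable
        tc = TrainConfig(package_size=128, learning_rate=0.05, max_epochs=3, seed=5)
        h1 = train(build_model(TINY, seed=3), X, y, tc)
        h2 = train(build_model(TINY, seed=3), X, y, tc)
        assert h1 == h2

    def test_zero_learning_rate_constant_history(self, separable):
        X, y = separable
        model = build_model(TINY, seed=3)
        history = train(
            model, X, y,
            TrainConfig(package_size=128, learning_rate=0.0, max_epochs=3, seed=6),
        )
        assert len(set(np.round(history, 12))) == 1

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            train(build_model(TINY, seed=0), np.zeros((0, 35)), np.zeros(0), TrainConfig())

    def test_single_class_warns(self, separable):
        X, _ = separable
        y = np.zeros(len(X), dtype=np.float32)
        with pytest.warns(UserWarning, match="single class"):
            train(
                build_model(TINY, seed=0), X[:128], y[:128],
                TrainConfig(package_size=128, learning_rate=0.01, max_epochs=1, seed=0),
            )


class TestPrediction:
    def test_single_residue_protein(self, tiny_model):
        res = predict_protein(tiny_model, np.zeros((35, 1)))
        assert res.probabilities.shape == (1,)
        assert 0 < res.probabilities[0] < 1

    def test_threshold_rule_is_geq(self, tiny_model, monkeypatch):
        # a probability exactly at the threshold is called positive
        monkeypatch.setattr(
            tiny_model, "predict_proba", lambda X, batch=512: np.array([0.49, 0.50, 0.51])
        )
        res = predict_protein(tiny_model, np.zeros((35, 3)), threshold=0.5)
        assert list(res.calls) == [0, 1, 1]

    def test_eval_mode_deterministic(self, tiny_model, rng):
        F = rng.normal(size=(35, 40))
        a = predict_protein(tiny_model, F)
        b = predict_protein(tiny_model, F)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_wrong_row_count(self, tiny_model):
        with pytest.raises(DataError):
            predict_protein(tiny_model, np.zeros((34, 5)))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        model = build_model(TINY, seed=8)
        X = rng.normal(size=(7, 35))
        before = model.forward(X)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(before, restored.forward(X))
        assert restored.config.block_channels == TINY.block_channels
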