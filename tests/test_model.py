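import dataclasses

import numpy as np
import pytest

from mowsense import ModelConfig, MowingDetector, sweep
from mowsense.features import FEATURE_NAMES, FeatureMatrix
from mowsense.model import build_network


def _random_matrix(n_fields=4, n_days=215, seed=0, with_events=True):
    rng = np.random.default_rng(seed)
    values = rng.random((n_fields, n_days, 14))
    labels = np.zeros((n_fields, n_days))
    starts = []
    for i in range(n_fields):
        if with_events and i % 2 == 0:
            s = int(rng.integers(20, n_days - 30))
            labels[i, s : s + 7] = 1.0
            starts.append(np.array([s]))
        else:
            starts.append(np.array([], dtype=int))
    return FeatureMatrix([f"F{i}" for i in range(n_fields)], values, labels,
                         event_starts=starts)


class TestArchitecture:
    def test_output_shape_and_sigmoid_range(self):
        net = build_network(ModelConfig(), np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 14, 215))
        logits = net.forward(x, train=False)
        probs = 1 / (1 + np.exp(-logits))
        assert logits.shape == (1, 1, 215)
        assert np.all((probs > 0) & (probs < 1))

    def test_inference_is_deterministic(self):
        net = build_network(ModelConfig(), np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 14, 215))
        np.testing.assert_array_equal(net.forward(x, train=False),
                                      net.forward(x, train=False))

    def test_same_padding_preserves_arbitrary_length(self):
        net = build_network(ModelConfig(n_days=100), np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 14, 100))
        assert net.forward(x, train=False).shape == (1, 1, 100)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kernel_size=8)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_activation="swish")

    @pytest.mark.parametrize("k", [5, 21])
    def test_translation_equivariance_in_the_interior(self, k):
        """Shifting the input in time shifts the output, up to edge effects.

        conv / channel-softmax / batch-norm (inference) are all
        time-equivariant, so interior outputs must match exactly; the
        receptive field half-width is 3*(kernel-1)/2 = 12 days.
        """
        cfg = ModelConfig()
        net = build_network(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 14, 215))
        base = net.forward(x, train=False)[0, 0]
        shifted = net.forward(np.roll(x, k, axis=2), train=False)[0, 0]
        rf = 3 * (cfg.kernel_size - 1) // 2
        lo, hi = rf + k, 215 - rf - k
        np.testing.assert_allclose(shifted[lo:hi], np.roll(base, k)[lo:hi],
                                   atol=1e-10)


class TestTraining:
    def test_capacity_to_overfit_small_dataset(self, small_matrix):
        """32 fields, 200 epochs, no early stop: training BCE collapses."""
        mat = small_matrix.subset_fields(np.arange(32))
        cfg = ModelConfig(max_epochs=200, learning_rate=1e-3, seed=0,
                          early_stopping_patience=10**9)
        res = MowingDetector(mat, None, cfg).fit()
        assert res.history["train_loss"][-1] < 0.15

    def test_identical_seeds_give_identical_histories(self):
        mat = _random_matrix(6, seed=3)
        cfg = ModelConfig(max_epochs=8, seed=4)
        h1 = MowingDetector(mat, None, cfg).fit().history["train_loss"]
        h2 = MowingDetector(mat, None, cfg).fit().history["train_loss"]
        assert h1 == h2

    def test_early_stopping_restores_best_validation_epoch(self, trained_results):
        res, _ = trained_results
        val = res.history["val_loss"]
        assert val[res.best_epoch] == min(val)
        assert val[res.best_epoch] <= val[-1]

    def test_divergence_raises_naming_epoch(self):
        mat = _random_matrix(4, seed=5)
        cfg = ModelConfig(max_epochs=30, learning_rate=1e9, optimizer="sgd", seed=0)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="epoch"):
                MowingDetector(mat, None, cfg).fit()

    def test_empty_validation_rejected(self):
        mat = _random_matrix(4)
        empty = mat.subset_fields(np.array([], dtype=int))
        with pytest.raises(ValueError):
            MowingDetector(mat, empty)


class TestPrediction:
    def test_shapes_and_range(self, trained_results):
        res, val = trained_results
        probs = res.predict(val)
        assert probs.shape == (val.n_fields, 215)
        assert np.all((probs > 0) & (probs < 1))

    def test_duplicated_field_gets_identical_predictions(self, trained_results):
        res, val = trained_results
        doubled = val.subset_fields(np.array([0, 1, 0]))
        probs = res.predict(doubled)
        # identical up to summation-order floating noise in the conv einsum
        np.testing.assert_allclose(probs[0], probs[2], atol=1e-12)

    def test_feature_order_mismatch_rejected(self, trained_results):
        res, val = trained_results
        wrong = val.subset_features(list(FEATURE_NAMES[::-1]))
        with pytest.raises(ValueError, match="feature order"):
            res.predict(wrong)

    def test_checkpoint_round_trip(self, trained_results, tmp_path):
        from mowsense import MowingDetectorResults

        res, val = trained_results
        res.save(tmp_path / "ckpt")
        back = MowingDetectorResults.load(tmp_path / "ckpt")
        np.testing.assert_allclose(back.predict(val), res.predict(val), atol=1e-12)

    def test_summary_mentions_key_settings(self, trained_results):
        res, _ = trained_results
        text = res.summary()
        assert "nadam" in text and "215 days" in text


@pytest.fixture(scope="module")
def tiny():
    train = _random_matrix(8, seed=0)
    val = _random_matrix(4, seed=1)
    test = _random_matrix(4, seed=2)
    return train, val, test


class TestSweep:

    def test_two_learning_rates_give_two_rows(self, tiny):
        train, val, test = tiny
        base = ModelConfig(max_epochs=3, seed=0)
        table = sweep({"learning_rate": [1e-4, 1e-3]}, train, val, test, base)
        assert len(table) == 2
        assert set(table["learning_rate"]) == {1e-4, 1e-3}

    def test_repeated_setting_is_deterministic(self, tiny):
        train, val, test = tiny
        base = ModelConfig(max_epochs=3, seed=0)
        t1 = sweep({"learning_rate": [1e-3]}, train, val, test, base)
        t2 = sweep({"learning_rate": [1e-3]}, train, val, test, base)
        assert t1.equals(t2)

    def test_sane_rate_beats_divergent_rate(self, tiny):
        train, val, test = tiny
        base = ModelConfig(max_epochs=10, seed=0)
        table = sweep({"learning_rate": [1e-4, 10.0]}, train, val, test, base)
        row = table.set_index("learning_rate")["val_loss"]
        assert row[1e-4] < row[10.0] or np.isnan(row[10.0])

    def test_empty_grid_rejected(self, tiny):
        train, val, test = tiny
        with pytest.raises(ValueError):
            sweep({}, train, val, test)
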