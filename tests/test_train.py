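"""Loss algebra, class weights, schedule, augmentation and the fit loop."""

from __future__ import annotations

import numpy as np
import pytest

from leukofrac.core import Mosaic
from leukofrac.model import ModelConfig, build
from leukofrac.train import (
    AugmentConfig,
    TrainConfig,
    TrainSample,
    augment,
    compute_class_weights,
    fit,
    one_cycle_lr,
    weighted_mae,
)


def _inverse_frequency_oracle(means, eps=0.01):
    """Independent arithmetic for the expected weights."""
    w = [1.0 / (m + eps) for m in means]
    norm = sum(w) / len(w)
    return [x / norm for x in w]


class TestClassWeights:
    def test_balanced_fractions_give_unit_weights(self):
        w = compute_class_weights([[0.25, 0.25, 0.25, 0.25]] * 3)
        np.testing.assert_allclose(w, np.ones(4), atol=1e-12)

    def test_imbalanced_fractions_match_hand_computation(self):
        w = compute_class_weights([[0.5, 0.3, 0.1, 0.1]])
        expected = _inverse_frequency_oracle([0.5, 0.3, 0.1, 0.1])
        np.testing.assert_allclose(w, expected, atol=1e-12)
        # spot values of the hand computation:
        # 1/(0.51, 0.31, 0.11, 0.11) = (1.9608, 3.2258, 9.0909, 9.0909),
        # mean 5.8421 -> normalized (0.3356, 0.5522, 1.5561, 1.5561)
        np.testing.assert_allclose(
            w, [0.33563, 0.55217, 1.55610, 1.55610], atol=1e-4
        )
        assert w.mean() == pytest.approx(1.0, abs=1e-12)

    def test_permutation_equivariance(self):
        base = np.array([[0.6, 0.25, 0.1, 0.05]])
        perm = [2, 0, 3, 1]
        w = compute_class_weights(base)
        w_perm = compute_class_weights(base[:, perm])
        np.testing.assert_allclose(w_perm, w[perm], atol=1e-12)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights([])


class TestWeightedMae:
    def test_identity_is_zero(self):
        y = [0.1, 0.2, 0.3, 0.4]
        assert weighted_mae(y, y) == 0.0

    def test_uniform_prediction_example(self):
        y_true = [0.5, 0.5, 0.0, 0.0]
        y_pred = [0.25, 0.25, 0.25, 0.25]
        assert weighted_mae(y_true, y_pred) == pytest.approx(0.25, abs=1e-12)
        assert weighted_mae(y_true, y_pred, [2, 2, 0.5, 0.5]) == pytest.approx(
            0.3125, abs=1e-12
        )

    def test_unit_weights_equal_raw_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.dirichlet(np.ones(4))
            p = rng.dirichlet(np.ones(4))
            assert weighted_mae(t, p, np.ones(4)) == pytest.approx(
                np.abs(t - p).mean(), abs=1e-15
            )


class TestOneCycle:
    def test_shape(self):
        cfg = TrainConfig(initial_lr=1e-5, epochs=200)
        lrs = [one_cycle_lr(e, cfg) for e in range(200)]
        assert lrs[0] == pytest.approx(1e-5)
        assert max(lrs) == pytest.approx(1e-4, rel=1e-6)
        assert np.argmax(lrs) == pytest.approx(60, abs=1)  # 30% warm-up
        assert lrs[-1] < 3e-6  # annealed well below the initial rate


class TestAugment:
    @pytest.fixture()
    def mosaic(self):
        rng = np.random.default_rng(5)
        return Mosaic(rng.random((64, 80, 2), dtype=np.float32), pixel_size=0.5)

    def test_deterministic_per_seed(self, mosaic):
        a = augment(mosaic, seed=9)
        b = augment(mosaic, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_null_config_is_identity(self, mosaic):
        cfg = AugmentConfig(rotate90=False, flip=False, brightness=0, contrast=0)
        out = augment(mosaic, seed=1, config=cfg)
        np.testing.assert_array_equal(out.pixels, mosaic.pixels)

    def test_range_and_geometry_preserved(self, mosaic):
        out = augment(mosaic, seed=3)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert sorted(out.pixels.shape) == sorted(mosaic.pixels.shape)
        assert out.pixel_size == mosaic.pixel_size

    def test_labels_unchanged_by_construction(self, mosaic):
        sample = TrainSample(mosaic, [0.1, 0.2, 0.3, 0.4])
        aug = augment(sample.mosaic, seed=2)
        np.testing.assert_array_equal(sample.fractions, [0.1, 0.2, 0.3, 0.4])
        assert aug.pixels.shape[2] == 2


def _toy_samples(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pixels = rng.random((64, 64, 2), dtype=np.float32)
        out.append(TrainSample(Mosaic(pixels, 0.5), rng.dirichlet(np.ones(4)), f"c{i}"))
    return out


class TestFit:
    def test_early_stop_after_patience_with_flat_validation(self):
        # a vanishing learning rate freezes the model, so the validation
        # loss never improves: patience 1 stops after two epochs
        model = build(ModelConfig(widths=(4, 8), seed=0))
        cfg = TrainConfig(
            initial_lr=1e-12, epochs=10, early_stop_patience=1, seed=0,
            augment=AugmentConfig(rotate90=False, flip=False, brightness=0, contrast=0),
        )
        result = fit(model, _toy_samples(2, 0), _toy_samples(1, 1), cfg)
        assert result.stopped_early
        assert len(result.history) == 2

    def test_weighted_equals_raw_when_weights_disabled(self):
        model = build(ModelConfig(widths=(4, 8), seed=0))
        cfg = TrainConfig(
            initial_lr=1e-4, epochs=2, use_class_weights=False, seed=0
        )
        result = fit(model, _toy_samples(3, 2), _toy_samples(1, 3), cfg)
        np.testing.assert_allclose(
            result.history["raw_train_mae"], result.history["weighted_train_mae"],
            rtol=1e-12,
        )

    def test_history_columns_and_best_checkpoint(self):
        model = build(ModelConfig(widths=(4, 8), seed=1))
        cfg = TrainConfig(initial_lr=1e-4, epochs=3, seed=0)
        result = fit(model, _toy_samples(3, 4), _toy_samples(2, 5), cfg)
        assert list(result.history.columns) == [
            "epoch", "raw_train_mae", "weighted_train_mae", "val_mae", "lr",
        ]
        assert 0 <= result.best_epoch < 3
        assert result.best_val_mae <= result.history["val_mae"].min() + 1e-12

    def test_empty_split_rejected(self):
        model = build(ModelConfig(widths=(4, 8), seed=0))
        with pytest.raises(ValueError):
            fit(model, [], _toy_samples(1, 0), TrainConfig())
        with pytest.raises(ValueError):
            fit(model, _toy_samples(1, 0), [], TrainConfig())

    def test_reproducible_given_seed(self):
        results = []
        for _ in range(2):
            model = build(ModelConfig(widths=(4, 8), seed=2))
            cfg = TrainConfig(initial_lr=1e-4, epochs=2, seed=7)
            res = fit(model, _toy_samples(3, 6), _toy_samples(1, 7), cfg)
            results.append(res.history["val_mae"].to_numpy())
        np.testing.assert_array_equal(results[0], results[1])
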