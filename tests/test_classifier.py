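"""CNN architecture, parameter accounting, gradients and training behavior."""

import numpy as np
import pytest

import histomap as hm
from histomap.classifier import Conv2D, Dense, _softmax

TINY = hm.ArchitectureConfig(
    input_side=8,
    conv_widths=(2, 2, 3, 3, 4, 4),
    n_classes=3,
    dropout_rate=0.0,
)


class TestParameterAccounting:
    def test_default_architecture_parameter_count(self):
        model = hm.build_model()
        assert hm.count_parameters(model) == 1_894_438
        assert round(hm.count_parameters(model) / 1e6, 1) == 1.9

    def test_output_layer_is_only_difference_between_6_and_8_classes(self):
        six = hm.count_parameters(hm.build_model())
        eight = hm.count_parameters(hm.build_model(hm.ArchitectureConfig(n_classes=8)))
        assert eight - six == 2 * 257  # two extra softmax units, 256 weights + bias each

    def test_75px_input_flatten_width(self):
        model = hm.build_model(hm.ArchitectureConfig(input_side=75))
        assert model.flatten_width == 9 * 9 * 128  # 75 -> 37 -> 18 -> 9

    def test_single_layer_counts(self):
        rng = np.random.default_rng(0)
        assert hm.count_parameters(Dense(10, 5, rng, np.float32)) == 55
        assert hm.count_parameters(Conv2D(3, 32, 3, rng, np.float32)) == 896

    def test_closed_form_sum_matches_layer_walk(self):
        cfg = hm.ArchitectureConfig()
        widths = (3,) + cfg.conv_widths
        conv = sum(9 * widths[i] * widths[i + 1] + widths[i + 1] for i in range(6))
        side = cfg.input_side // 8  # three 2x2 pools
        flat = side * side * cfg.conv_widths[-1]
        dense = flat * 256 + 256 + 256 * cfg.n_classes + cfg.n_classes
        assert conv + dense == hm.count_parameters(hm.build_model(cfg))


class TestModelStructure:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            hm.ArchitectureConfig(n_classes=1)
        with pytest.raises(ValueError):
            hm.ArchitectureConfig(conv_widths=(32, 32, 64))
        with pytest.raises(ValueError):
            hm.ArchitectureConfig(input_side=4)

    def test_probabilities_form_a_simplex_and_are_order_stable(self):
        model = hm.build_model(TINY, seed=1)
        rng = np.random.default_rng(2)
        patches = rng.integers(0, 256, (7, 8, 8, 3), dtype=np.uint8)
        probs = model.predict_proba(patches)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        # duplicated patch -> identical output; permutation permutes rows
        dup = model.predict_proba(patches[[0, 0]])
        np.testing.assert_array_equal(dup[0], dup[1])
        perm = model.predict_proba(patches[::-1])
        np.testing.assert_allclose(perm, probs[::-1], atol=1e-7)

    def test_input_scaling_maps_extremes_to_unit_range(self):
        lo = np.zeros((1, 8, 8, 3), dtype=np.uint8)
        hi = np.full((1, 8, 8, 3), 255, dtype=np.uint8)
        assert (lo.astype(np.float32) / 255.0).max() == 0.0
        assert (hi.astype(np.float32) / 255.0).max() == 1.0

    def test_side_mismatch_rejected(self):
        model = hm.build_model(TINY, seed=1)
        patches = np.zeros((2, 16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="side"):
            model.predict_proba(patches)

    def test_save_load_round_trip(self, tmp_path):
        model = hm.build_model(TINY, seed=3)
        path = str(tmp_path / "model.npz")
        model.save(path)
        back = hm.Model.load(path)
        rng = np.random.default_rng(4)
        patches = rng.integers(0, 256, (3, 8, 8, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            model.predict_proba(patches), back.predict_proba(patches)
        )


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference check of the full conv/pool/dense stack."""
        model = hm.Model(TINY, seed=5, dtype=np.float64)
        rng = np.random.default_rng(6)
        x = rng.random((4, 8, 8, 3))
        y = np.array([0, 1, 2, 1])

        def loss_value():
            probs = _softmax(model.forward(x, training=False))
            return -np.mean(np.log(probs[np.arange(4), y]))

        probs = _softmax(model.forward(x, training=False))
        onehot = np.zeros_like(probs)
        onehot[np.arange(4), y] = 1.0
        model.backward((probs - onehot) / 4)

        eps = 1e-6
        checked = 0
        for layer in model.trainable_layers():
            grads = {"W": layer.dW, "b": layer.db}
            for name, param in layer.params():
                flat = param.reshape(-1)
                gflat = grads[name].reshape(-1)
                for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up = loss_value()
                    flat[idx] = orig - eps
                    down = loss_value()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    assert gflat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                    checked += 1
        assert checked >= 24  # every layer's weights and biases sampled


def _constant_color_dataset(side=8, n_per_class=20, seed=0):
    """Degenerate, linearly separable patches: each class one constant color."""
    colors = [(220, 40, 40), (40, 220, 40), (40, 40, 220)]
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for c, col in enumerate(colors):
        block = np.full((n_per_class, side, side, 3), col, dtype=np.int16)
        block = block + rng.integers(-5, 6, block.shape)
        patches.append(np.clip(block, 0, 255).astype(np.uint8))
        labels.extend([c] * n_per_class)
    return hm.PatchDataset(
        np.concatenate(patches),
        np.arange(3 * n_per_class),
        labels=np.asarray(labels),
        class_names=["r", "g", "b"],
    )


class TestTraining:
    def test_constant_colors_reach_perfect_validation_accuracy(self):
        # enough samples that 5 epochs supply a few hundred optimizer steps
        ds = _constant_color_dataset(n_per_class=200)
        model = hm.build_model(TINY, seed=7)
        cfg = hm.TrainingConfig(epochs=5, batch_size=8, validation_fraction=0.2, seed=7)
        model, history = hm.train(model, ds, cfg)
        assert max(h["val_acc"] for h in history) == 1.0

    def test_training_is_deterministic_given_seed(self):
        ds = _constant_color_dataset(seed=1)
        cfg = hm.TrainingConfig(epochs=1, batch_size=16, validation_fraction=0.2, seed=11)
        _, h1 = hm.train(hm.build_model(TINY, seed=11), ds, cfg)
        _, h2 = hm.train(hm.build_model(TINY, seed=11), ds, cfg)
        assert h1[0]["train_loss"] == h2[0]["train_loss"]

    def test_max_norm_constraint_holds_after_training(self):
        ds = _constant_color_dataset(seed=2)
        model = hm.build_model(TINY, seed=13)
        model, _ = hm.train(
            model, ds, hm.TrainingConfig(epochs=2, batch_size=16, validation_fraction=0.2, seed=13)
        )
        assert model.max_norm_excess() <= 1e-6

    def test_best_validation_weights_are_kept(self):
        ds = _constant_color_dataset(seed=3)
        model = hm.build_model(TINY, seed=17)
        cfg = hm.TrainingConfig(epochs=4, batch_size=16, validation_fraction=0.2, seed=17)
        model, history = hm.train(model, ds, cfg)
        best = max(h["val_acc"] for h in history)
        # re-evaluate the returned weights on the same validation split
        from histomap.classifier import _stratified_split, _evaluate

        rng = np.random.default_rng(cfg.seed)
        _, va_idx = _stratified_split(ds.labels, cfg.validation_fraction, rng)
        _, val_acc = _evaluate(model, ds.patches[va_idx].astype(model.dtype) / 255.0,
                               ds.labels[va_idx], 16)
        assert val_acc == pytest.approx(best)

    def test_single_class_training_rejected(self):
        ds = _constant_color_dataset()
        ds.labels[:] = 0
        with pytest.raises(ValueError, match="2 classes"):
            hm.train(hm.build_model(TINY, seed=1), ds, hm.TrainingConfig(epochs=1, batch_size=8))
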