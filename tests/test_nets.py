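"""Patch machinery and the three learnable components."""

import numpy as np
import pytest

from hsibrain.nets import (
    Cnn2DModel,
    TrainConfig,
    augment_batch,
    balance_classes,
    build_cnn2d,
    extract_patches,
    load_model,
    predict_dnn1d,
    save_model,
    train_cnn2d,
    train_dnn1d,
    train_parenchyma_net,
    predict_parenchyma,
)
from hsibrain.preprocess import ProcessedCube


class TestExtractPatches:
    def test_interior_patch_is_literal_window(self):
        img = np.arange(100.0).reshape(10, 10)
        patch = extract_patches(img, [(5, 5)], 3)[0]
        np.testing.assert_array_equal(patch, img[4:7, 4:7])

    def test_corner_patch_matches_reflect_pad_oracle(self):
        img = np.arange(25.0).reshape(5, 5)
        patch = extract_patches(img, [(0, 0)], 3)[0]
        oracle = np.pad(img, 1, mode="reflect")[0:3, 0:3]
        np.testing.assert_array_equal(patch, oracle)

    def test_constant_image_gives_constant_patches(self):
        img = np.full((8, 8, 4), 2.5)
        patches = extract_patches(img, [(0, 0), (7, 7), (4, 4)], 5)
        assert patches.shape == (3, 5, 5, 4)
        np.testing.assert_array_equal(patches, 2.5)

    def test_center_outside_image_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            extract_patches(np.zeros((4, 4)), [(4, 0)], 3)


class TestAugment:
    def test_batch_of_12_becomes_96(self):
        patches = np.random.default_rng(0).normal(size=(12, 11, 11, 3))
        assert augment_batch(patches).shape[0] == 96

    def test_constant_patch_gives_8_identical_copies(self):
        out = augment_batch(np.full((1, 4, 4), 7.0))
        assert out.shape == (8, 4, 4)
        np.testing.assert_array_equal(out, 7.0)

    def test_asymmetric_patch_gives_8_distinct_value_preserving_variants(self):
        patch = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = augment_batch(patch[None])
        flat = {tuple(v.ravel()) for v in out}
        assert len(flat) == 8  # full dihedral orbit
        for v in out:
            assert sorted(v.ravel()) == [1.0, 2.0, 3.0, 4.0]

    def test_dihedral_orbit_closed_under_reapplication(self):
        patch = np.arange(9.0).reshape(1, 3, 3)
        once = {tuple(v.ravel()) for v in augment_batch(patch)}
        twice = {tuple(v.ravel()) for v in augment_batch(augment_batch(patch))}
        assert twice == once

    def test_non_square_patch_is_error(self):
        with pytest.raises(ValueError, match="square"):
            augment_batch(np.zeros((2, 3, 4)))


class TestBalance:
    def test_counts_reduce_to_minimum(self):
        rng = np.random.default_rng(0)
        samples = {c: np.arange(n) for c, n in zip((1, 2, 3, 4), (10, 4, 6, 8))}
        out = balance_classes(samples, rng)
        assert all(len(v) == 4 for v in out.values())
        for c, v in out.items():
            assert set(v) <= set(samples[c])  # without replacement
            assert len(set(v)) == len(v)

    def test_equal_counts_give_permutation(self):
        samples = {1: np.arange(5), 2: np.arange(5) + 10}
        out = balance_classes(samples, np.random.default_rng(1))
        assert sorted(out[1]) == list(range(5))

    def test_seeded_selection_is_reproducible(self):
        samples = {1: np.arange(50), 2: np.arange(10)}
        a = balance_classes(samples, np.random.default_rng(7))
        b = balance_classes(samples, np.random.default_rng(7))
        np.testing.assert_array_equal(a[1], b[1])

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            balance_classes({1: np.arange(3), 2: np.array([])})


def separable_spectra(n_per_class, rng, n_bands=128):
    """Two Gaussian classes at distance >> spread."""
    a = rng.normal(0.2, 0.01, size=(n_per_class, n_bands))
    b = rng.normal(0.8, 0.01, size=(n_per_class, n_bands))
    x = np.vstack([a, b])
    y = np.r_[np.ones(n_per_class, dtype=int), 2 * np.ones(n_per_class, dtype=int)]
    return x, y


class TestDnn1D:
    def test_separable_classes_reach_high_training_accuracy(self):
        x, y = separable_spectra(200, np.random.default_rng(0))
        model = train_dnn1d(x, y, TrainConfig(epochs=20, seed=0, batch_size=128))
        preds = model.classes[model.predict_proba(x).argmax(axis=1)]
        assert (preds == y).mean() >= 0.99

    def test_probabilities_sum_to_one(self):
        x, y = separable_spectra(50, np.random.default_rng(1))
        model = train_dnn1d(x, y, TrainConfig(epochs=3, seed=0, batch_size=128))
        np.testing.assert_allclose(model.predict_proba(x).sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_weights_hash(self):
        x, y = separable_spectra(50, np.random.default_rng(2))
        cfg = TrainConfig(epochs=3, seed=5, batch_size=128)
        assert train_dnn1d(x, y, cfg).weights_hash() == train_dnn1d(x, y, cfg).weights_hash()

    def test_predict_cube_band_mismatch_is_error(self):
        x, y = separable_spectra(30, np.random.default_rng(3), n_bands=16)
        model = train_dnn1d(x, y, TrainConfig(epochs=2, seed=0, batch_size=64))
        cube = ProcessedCube(np.zeros((2, 2, 8)), np.arange(8.0))
        with pytest.raises(ValueError, match="bands"):
            predict_dnn1d(model, cube)

    def test_predict_cube_shape_and_normalization(self):
        x, y = separable_spectra(50, np.random.default_rng(4), n_bands=16)
        model = train_dnn1d(x, y, TrainConfig(epochs=3, seed=0, batch_size=64))
        cube = ProcessedCube(
            np.random.default_rng(0).uniform(0, 1, (3, 4, 16)), np.arange(16.0)
        )
        pc = predict_dnn1d(model, cube)
        assert pc.probs.shape == (3, 4, 2)
        np.testing.assert_allclose(pc.probs.sum(axis=2), 1.0, atol=1e-6)


class TestCnn2D:
    def test_flatten_size_matches_printed_architecture(self):
        """11x11x128 input, three 'same' convs, 3x3 'valid' average pool
        -> 9x9x128 = 10368 flattened features."""
        cfg = TrainConfig(seed=0)
        net = build_cnn2d(patch_size=11, n_channels=128, n_classes=4, cfg=cfg)
        dense = net.layers[-3]
        assert dense.W.value.shape[0] == 9 * 9 * 128 == 10368
        assert dense.W.value.shape[1] == 1000

    def test_textured_vs_flat_patches_learned(self):
        rng = np.random.default_rng(0)
        n = 60
        flat = rng.normal(0.2, 0.02, size=(n, 9, 9))
        stripes = np.zeros((n, 9, 9)) + 0.2
        stripes[:, ::2] = 0.8
        stripes += rng.normal(0, 0.02, size=stripes.shape)
        x = np.concatenate([flat, stripes])
        y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
        cfg = TrainConfig(
            optimizer_name="adadelta", learning_rate=1.0, epochs=10, patch_size=9,
            conv_filters=(4, 6, 8), fc_width=32, conv_activation="relu",
            dropout_rate=0.2, seed=0,
        )
        model = train_cnn2d(x, y, cfg)
        preds = model.classes[model.predict_proba(x).argmax(axis=1)]
        assert (preds == y).mean() >= 0.95

    def test_seeded_training_reproducible(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 5, 5))
        y = rng.integers(0, 2, size=20)
        cfg = TrainConfig(
            optimizer_name="adadelta", learning_rate=1.0, epochs=2, patch_size=5,
            conv_filters=(2, 3, 4), fc_width=8, seed=3,
        )
        assert train_cnn2d(x, y, cfg).weights_hash() == train_cnn2d(x, y, cfg).weights_hash()

    def test_wrong_patch_geometry_is_error(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(16, 5, 5))
        y = rng.integers(0, 2, size=16)
        cfg = TrainConfig(
            optimizer_name="adadelta", epochs=1, patch_size=5,
            conv_filters=(2, 2, 2), fc_width=4, seed=0,
        )
        model = train_cnn2d(x, y, cfg)
        with pytest.raises(ValueError, match="geometry"):
            model.predict_proba(rng.normal(size=(2, 7, 7)))


class TestParenchymaNet:
    def test_training_set_augmented_by_factor_eight(self):
        # augmentation factor is the documented 8x dihedral expansion
        imgs = np.random.default_rng(0).uniform(size=(20, 8, 8))
        assert augment_batch(imgs).shape[0] == 160

    def test_learns_bright_ellipse_and_outputs_probabilities(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[:16, :16]
        imgs, masks = [], []
        for _ in range(6):
            cy, cx = rng.uniform(6, 10, 2)
            mask = ((yy - cy) / 5.0) ** 2 + ((xx - cx) / 6.0) ** 2 <= 1.0
            img = np.where(mask, 0.8, 0.2) + rng.normal(0, 0.02, (16, 16))
            imgs.append(img)
            masks.append(mask)
        cfg = TrainConfig(
            optimizer_name="adadelta", learning_rate=1.0, epochs=6,
            base_filters=4, batch_size=12, seed=0,
        )
        model = train_parenchyma_net(np.stack(imgs), np.stack(masks, 0).astype(float), cfg)
        prob = predict_parenchyma(model, imgs[0])
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        pred = prob >= 0.5
        inter = (pred & masks[0]).sum()
        dice = 2 * inter / (pred.sum() + masks[0].sum())
        assert dice >= 0.9

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError, match="shape"):
            train_parenchyma_net(np.zeros((2, 8, 8)), np.zeros((2, 8, 4)))


class TestCheckpoints:
    def test_dnn_round_trip_identical_predictions(self, tmp_path):
        x, y = separable_spectra(40, np.random.default_rng(0), n_bands=16)
        model = train_dnn1d(x, y, TrainConfig(epochs=3, seed=0, batch_size=64))
        path = tmp_path / "dnn.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict_proba(x), model.predict_proba(x))

    def test_cnn_round_trip_identical_predictions(self, tmp_path):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(16, 5, 5))
        y = rng.integers(0, 2, size=16)
        cfg = TrainConfig(
            optimizer_name="adadelta", epochs=1, patch_size=5,
            conv_filters=(2, 3, 4), fc_width=8, seed=0,
        )
        model = train_cnn2d(x, y, cfg)
        path = tmp_path / "cnn.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.predict_proba(x), model.predict_proba(x), atol=1e-6)
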