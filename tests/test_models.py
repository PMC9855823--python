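"""Architecture contracts and training behavior of the CNN variants.

Most tests use a miniature spec (same five-block structure, far fewer
channels) so the suite stays fast; the full-size 256/768 dimensional
contracts are exercised in the acceptance tests.
"""

import dataclasses

import numpy as np
import pytest

from stressrp import nn
from stressrp.models import (
    ModelSpec,
    TrainConfig,
    build_branch_cnn,
    build_frozen_vgg_baseline,
    build_multimodal_1d_cnn,
    build_multimodal_cnn,
    build_unimodal_cnn,
    snapshot,
    train_model,
)


def _images(rng, n, branches, size=32, separable=False, labels=None):
    x = rng.random((n, branches, size, size), dtype=np.float32)
    if separable:
        for i, lbl in enumerate(labels):
            if lbl == "stressed":
                x[i] += 0.8  # constant offset: linearly separable
    return x


class TestArchitecture:
    def test_branch_output_dimension(self, tiny_spec, rng):
        branch = build_branch_cnn(tiny_spec, seed=0)
        out = branch.forward(rng.random((3, 1, 32, 32), dtype=np.float32))
        assert out.shape == (3, tiny_spec.branch_output_dim)

    def test_conv_layer_count_is_thirteen(self, tiny_spec):
        branch = build_branch_cnn(tiny_spec, seed=0)
        convs = [l for l in branch.layers if isinstance(l, nn.Conv2d)]
        assert len(convs) == sum(tiny_spec.conv_layers_per_block) == 13

    def test_spatial_halving_per_block(self, tiny_spec, rng):
        """After block k the spatial size is input_size / 2^k."""
        branch = build_branch_cnn(tiny_spec, seed=0)
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        sizes = []
        for layer in branch.layers:
            x = layer.forward(x)
            if isinstance(layer, nn.MaxPool2d):
                sizes.append(x.shape[-1])
        assert sizes == [16, 8, 4, 2, 1]

    def test_fused_dimension_is_three_branches(self, tiny_spec):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        assert tiny_spec.fused_dim == 3 * tiny_spec.branch_output_dim
        dense = handle.head.layers[0]
        assert dense.w.shape[0] == tiny_spec.fused_dim

    def test_incompatible_input_size_rejected_at_build(self):
        with pytest.raises(ValueError, match="divisible"):
            build_multimodal_cnn(ModelSpec(input_size=50), seed=0)

    def test_zero_input_gives_finite_probabilities(self, tiny_spec):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        proba = handle.predict_proba(np.zeros((2, 3, 32, 32), np.float32))
        assert np.all(np.isfinite(proba))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_probabilities_sum_to_one(self, tiny_spec, rng):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        proba = handle.predict_proba(_images(rng, 5, 3))
        assert proba.shape == (5, 2)
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_branches_are_not_weight_shared(self, tiny_spec, rng):
        """Permuting input channels changes the prediction."""
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        x = _images(rng, 4, 3)
        base = handle.predict_proba(x)
        permuted = handle.predict_proba(x[:, [2, 0, 1]])
        assert not np.allclose(base, permuted)

    def test_duplicated_input_rows_get_identical_probabilities(
            self, tiny_spec, rng):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        x = _images(rng, 2, 3)
        x[1] = x[0]
        proba = handle.predict_proba(x)
        assert np.allclose(proba[0], proba[1])

    def test_shape_mismatch_rejected(self, tiny_spec, rng):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        with pytest.raises(ValueError):
            handle.predict_proba(_images(rng, 2, 2))
        with pytest.raises(ValueError):
            handle.predict_proba(rng.random((2, 3, 16, 16),
                                            dtype=np.float32))


class TestOneDimensional:
    def test_mirrors_2d_dimension_contract(self, tiny_spec, rng):
        handle = build_multimodal_1d_cnn(tiny_spec, seed=0)
        proba = handle.predict_proba(
            rng.random((4, 3, 480), dtype=np.float32))
        assert proba.shape == (4, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert handle.branches[0].forward(
            rng.random((2, 1, 480), dtype=np.float32)
        ).shape == (2, tiny_spec.branch_output_dim)

    def test_too_short_sequence_rejected(self, tiny_spec, rng):
        handle = build_multimodal_1d_cnn(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            handle.predict_proba(rng.random((2, 3, 20), dtype=np.float32))


class TestFrozenBaseline:
    def test_frozen_branches_bit_identical_after_training(self, tiny_spec, rng):
        handle = build_frozen_vgg_baseline(tiny_spec, seed=0)
        before = [w.copy() for w in handle.branch_state()]
        labels = ["stressed", "relaxed"] * 6
        x = _images(rng, 12, 3, separable=True, labels=labels)
        train_model(handle, x, labels, TrainConfig(epochs=2, batch_size=4))
        after = handle.branch_state()
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_head_changes_after_training(self, tiny_spec, rng):
        handle = build_frozen_vgg_baseline(tiny_spec, seed=0)
        before = [w.copy() for w in handle.head.state()]
        labels = ["stressed", "relaxed"] * 4
        train_model(handle, _images(rng, 8, 3), labels,
                    TrainConfig(epochs=1, batch_size=4))
        after = handle.head.state()
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))

    def test_same_seed_identical_initial_weights(self, tiny_spec):
        a = build_frozen_vgg_baseline(tiny_spec, seed=7)
        b = build_frozen_vgg_baseline(tiny_spec, seed=7)
        assert all(np.array_equal(x, y)
                   for x, y in zip(snapshot(a), snapshot(b)))

    def test_pretrained_mode_rejected_without_source(self, tiny_spec):
        with pytest.raises(ValueError, match="pretrained"):
            build_frozen_vgg_baseline(tiny_spec, weights_mode="pretrained")


class TestTraining:
    def test_overfits_linearly_separable_set(self, tiny_spec, rng):
        labels = ["stressed", "relaxed"] * 10
        x = _images(rng, 20, 3, separable=True, labels=labels)
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        train_model(handle, x, labels,
                    TrainConfig(learning_rate=0.01, epochs=30, batch_size=4,
                                seed=0))
        pred = handle.predict_proba(x)[:, 1] >= 0.5
        truth = np.array([lbl == "stressed" for lbl in labels])
        assert np.array_equal(pred, truth)

    def test_zero_epochs_returns_initialization(self, tiny_spec, rng):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        before = snapshot(handle)
        labels = ["stressed", "relaxed"] * 2
        trained = train_model(handle, _images(rng, 4, 3), labels,
                              TrainConfig(epochs=0))
        assert trained.history == []
        assert all(np.array_equal(a, b)
                   for a, b in zip(before, snapshot(handle)))

    def test_fixed_seeds_reproduce_final_loss(self, tiny_spec, rng):
        labels = ["stressed", "relaxed"] * 4
        x = _images(rng, 8, 3)
        runs = []
        for _ in range(2):
            handle = build_multimodal_cnn(tiny_spec, seed=3)
            trained = train_model(handle, x, labels,
                                  TrainConfig(epochs=2, batch_size=4, seed=5))
            runs.append(trained.history)
        assert runs[0] == runs[1]

    def test_single_class_training_rejected(self, tiny_spec, rng):
        handle = build_multimodal_cnn(tiny_spec, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train_model(handle, _images(rng, 4, 3), ["stressed"] * 4,
                        TrainConfig(epochs=1))

    def test_loss_decreases_on_separable_data(self, tiny_spec, rng):
        labels = ["stressed", "relaxed"] * 8
        x = _images(rng, 16, 3, separable=True, labels=labels)
        handle = build_multimodal_cnn(tiny_spec, seed=1)
        trained = train_model(handle, x, labels,
                              TrainConfig(learning_rate=0.01, epochs=10,
                                          batch_size=4, seed=1))
        first = np.mean(trained.history[:3])
        last = np.mean(trained.history[-3:])
        assert last < first
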