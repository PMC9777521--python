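"""Materialized models: layer correctness, shapes, determinism, training
dynamics and whole-image prediction."""

from itertools import product

import numpy as np
import pytest

from aidunet.archspec import ArchConfig, count_parameters, plan_layers
from aidunet.losses_metrics import generalized_dice_loss, one_hot
from aidunet.network import (
    BatchNorm,
    Conv,
    ConvTranspose,
    MaxPool,
    TrainConfig,
    build_model,
    dice_loss_and_grad,
    predict_mask,
    train,
)
from aidunet.preprocess import plan_patches
from aidunet.synthetic_data import make_dataset, FixtureSpec


def tiny_config(dims=2, extent=(8, 8), k=1, d=1, classes=2, channels=1):
    return ArchConfig(k, d, filter_factor=2, dims=dims, in_channels=channels,
                      num_classes=classes, input_extent=extent,
                      dropout_rate=0.0)


def tiny_dataset(n=8, extent=(8, 8), seed=0, channels=1):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mask = np.zeros(extent, dtype=np.int64)
        c = rng.integers(2, extent[0] - 2, size=2)
        mask[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2] = 1
        image = 0.2 + 0.6 * mask[..., None] + 0.05 * rng.normal(
            size=extent + (channels,))
        out.append((image.astype(np.float32), mask))
    return out


# ---------------------------------------------------------------------------
# Layer primitives against brute-force oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dims,extent", [(2, (5, 6)), (3, (3, 4, 4))])
def test_conv_matches_sliding_window_oracle(dims, extent, rng):
    conv = Conv(2, 3, 3, dims, rng)
    x = rng.normal(size=(2, 2) + extent).astype(np.float32)
    y = conv.forward(x)
    xp = np.pad(x, [(0, 0), (0, 0)] + [(1, 1)] * dims)
    expect = np.empty_like(y)
    for n in range(2):
        for o in range(3):
            for idx in np.ndindex(*extent):
                window = xp[(n, slice(None)) + tuple(
                    slice(i, i + 3) for i in idx
                )]
                expect[(n, o) + idx] = (window * conv.W.value[o]).sum() \
                    + conv.b.value[o]
    assert np.allclose(y, expect, atol=1e-4)


@pytest.mark.parametrize("dims", [2, 3])
def test_transposed_conv_matches_scatter_oracle(dims, rng):
    up = ConvTranspose(2, 3, dims, rng)
    extent = (3,) * dims
    x = rng.normal(size=(1, 2) + extent).astype(np.float32)
    y = up.forward(x)
    expect = np.zeros((1, 3) + tuple(2 * s for s in extent))
    for ci in range(2):
        for co in range(3):
            for idx in np.ndindex(*extent):
                for koff in np.ndindex(*(2,) * dims):
                    pos = tuple(2 * i + k for i, k in zip(idx, koff))
                    expect[(0, co) + pos] += (
                        x[(0, ci) + idx] * up.W.value[(ci, co) + koff]
                    )
    expect += up.b.value.reshape((1, -1) + (1,) * dims)
    assert np.allclose(y, expect, atol=1e-4)
    # backward data gradient is the adjoint of the forward scatter
    dy = rng.normal(size=y.shape).astype(np.float32)
    dx = up.backward(dy)
    dx_expect = np.zeros_like(x)
    for ci in range(2):
        for co in range(3):
            for idx in np.ndindex(*extent):
                for koff in np.ndindex(*(2,) * dims):
                    pos = tuple(2 * i + k for i, k in zip(idx, koff))
                    dx_expect[(0, ci) + idx] += (
                        dy[(0, co) + pos] * up.W.value[(ci, co) + koff]
                    )
    assert np.allclose(dx, dx_expect, atol=1e-4)


def test_conv_backward_is_adjoint_of_forward(rng):
    # <conv(x), R> == <x, conv_backward(R)> for a linear, bias-free layer
    conv = Conv(2, 3, 3, 2, rng)
    conv.b.value[:] = 0.0
    x = rng.normal(size=(2, 2, 6, 6)).astype(np.float32)
    r = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
    y = conv.forward(x)
    dx = conv.backward(r)
    assert float((y * r).sum()) == pytest.approx(float((x * dx).sum()), rel=1e-3)


@pytest.mark.parametrize("dims", [2, 3])
def test_maxpool_matches_block_maximum(dims, rng):
    pool = MaxPool(dims)
    extent = (4,) * dims
    x = rng.normal(size=(2, 3) + extent).astype(np.float32)
    y = pool.forward(x)
    for n in range(2):
        for c in range(3):
            for idx in np.ndindex(*(2,) * dims):
                block = x[(n, c) + tuple(slice(2 * i, 2 * i + 2) for i in idx)]
                assert y[(n, c) + idx] == block.max()
    # gradient routes one unit into each window, at a position achieving
    # the window maximum
    dy = np.ones_like(y)
    dx = pool.backward(dy)
    assert dx.sum() == y.size
    for n in range(2):
        for c in range(3):
            for idx in np.ndindex(*(2,) * dims):
                sl = (n, c) + tuple(slice(2 * i, 2 * i + 2) for i in idx)
                block, dblock = x[sl], dx[sl]
                assert dblock.sum() == 1.0
                assert block[dblock > 0] == block.max()


def test_batchnorm_standardizes_in_training_mode(rng):
    bn = BatchNorm(4)
    x = rng.normal(2.0, 3.0, size=(8, 4, 10, 10)).astype(np.float32)
    y = bn.forward(x, training=True)
    assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-4)
    assert np.allclose(y.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
    # inference mode uses running statistics, not batch statistics
    z = bn.forward(np.zeros_like(x), training=False)
    assert not np.allclose(z, 0.0)


# ---------------------------------------------------------------------------
# Model construction and forward contracts
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_2d_forward_preserves_spatial_extent(self):
        model = build_model(plan_layers(tiny_config(extent=(16, 16))), seed=0)
        out = model.forward(np.zeros((2, 1, 16, 16), dtype=np.float32))
        assert out.shape == (2, 2, 16, 16)

    def test_3d_forward_shape_propagation(self):
        cfg = ArchConfig(2, 1, filter_factor=2, dims=3, in_channels=4,
                         num_classes=2, input_extent=(64, 64, 32),
                         dropout_rate=0.0)
        model = build_model(plan_layers(cfg), seed=0)
        out = model.forward(np.zeros((1, 4, 64, 64, 32), dtype=np.float32))
        assert out.shape == (1, 2, 64, 64, 32)

    def test_probabilities_normalized_per_pixel(self, rng):
        model = build_model(plan_layers(tiny_config()), seed=1)
        out = model.forward(rng.normal(size=(2, 1, 8, 8)).astype(np.float32))
        assert (out >= 0).all()
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-5)

    def test_wrong_channel_count_rejected(self):
        model = build_model(plan_layers(tiny_config()), seed=0)
        with pytest.raises(ValueError, match="channels"):
            model.forward(np.zeros((1, 3, 8, 8), dtype=np.float32))

    @pytest.mark.parametrize("dims", [2, 3])
    def test_materialized_count_equals_planned_count(self, dims):
        extent = (8, 8) if dims == 2 else (8, 8, 8)
        for k, d in product((1, 2, 3), repeat=2):
            if d > k:
                continue
            cfg = ArchConfig(k, d, filter_factor=2, dims=dims, in_channels=2,
                             num_classes=3, input_extent=extent)
            graph = plan_layers(cfg)
            model = build_model(graph, seed=0)
            assert model.num_parameters() == count_parameters(graph)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

class TestDiceLossGradient:
    def test_value_agrees_with_metric_module(self, rng):
        logits = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        masks = rng.integers(0, 3, size=(2, 4, 4))
        loss, _ = dice_loss_and_grad(logits, masks)
        from aidunet.network import softmax

        p = softmax(logits)
        # class axis first, batch+spatial flattened into elements
        P = np.moveaxis(p, 1, 0).reshape(3, -1)
        G = one_hot(masks, 3).reshape(3, -1)  # class axis already leads
        assert loss == pytest.approx(generalized_dice_loss(P, G), abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(1, 2, 3, 3)).astype(np.float64)
        masks = rng.integers(0, 2, size=(1, 3, 3))
        _, grad = dice_loss_and_grad(logits, masks)
        eps = 1e-6
        for idx in [(0, 0, 1, 1), (0, 1, 2, 0), (0, 0, 0, 2)]:
            lp = dice_loss_and_grad(_bump(logits, idx, eps), masks)[0]
            lm = dice_loss_and_grad(_bump(logits, idx, -eps), masks)[0]
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-3)


def _bump(a, idx, eps):
    b = a.copy()
    b[idx] += eps
    return b


# ---------------------------------------------------------------------------
# Training dynamics
# ---------------------------------------------------------------------------

class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        model = build_model(plan_layers(tiny_config()), seed=3)
        before = [p.value.copy() for p in model.parameters()]
        cfg = TrainConfig(epochs=1, batch_size=4, learning_rate=0.0,
                          rng_seed=0, validation_fraction=0.25)
        train(model, tiny_dataset(), cfg)
        for old, p in zip(before, model.parameters()):
            assert np.array_equal(old, p.value)

    def test_identical_seeds_reproduce_epoch_zero_loss_bitwise(self):
        losses = []
        for _ in range(2):
            model = build_model(plan_layers(tiny_config()), seed=5)
            cfg = TrainConfig(epochs=1, batch_size=4, learning_rate=1e-3,
                              rng_seed=5, validation_fraction=0.25)
            _, hist = train(model, tiny_dataset(), cfg)
            losses.append(hist.train_loss[0])
        assert losses[0] == losses[1]

    def test_loss_non_increasing_over_first_epochs_at_small_step(self):
        model = build_model(plan_layers(tiny_config()), seed=2)
        cfg = TrainConfig(epochs=3, batch_size=8, learning_rate=1e-4,
                          rng_seed=2, validation_fraction=0.25)
        _, hist = train(model, tiny_dataset(n=16), cfg)
        assert hist.train_loss[0] >= hist.train_loss[1] >= hist.train_loss[2]

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_non_finite_loss_aborts_with_location(self):
        # an absurd step size overflows the weights to inf and the next
        # forward pass to NaN; training must abort naming epoch and batch
        model = build_model(plan_layers(tiny_config()), seed=0)
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=1e20,
                          rng_seed=0, validation_fraction=0.25)
        with pytest.raises(RuntimeError, match=r"epoch \d+, batch \d+"):
            train(model, tiny_dataset(n=8), cfg)

    def test_history_length_equals_completed_epochs(self):
        model = build_model(plan_layers(tiny_config()), seed=1)
        cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3,
                          rng_seed=1, validation_fraction=0.25)
        _, hist = train(model, tiny_dataset(), cfg)
        assert hist.epochs_completed == 2
        assert len(hist.val_iou) == 2
        assert all(np.isfinite(hist.train_loss))


# ---------------------------------------------------------------------------
# Whole-image prediction
# ---------------------------------------------------------------------------

def _background_only_model():
    model = build_model(plan_layers(tiny_config(extent=(8, 8))), seed=0)
    head = model.blocks[-1].convs[0]
    head.W.value[:] = 0.0
    head.b.value[:] = 0.0
    head.b.value[0] = 10.0
    return model


class TestPredictMask:
    def test_background_model_yields_background_mask(self, rng):
        model = _background_only_model()
        image = rng.random((8, 8, 1)).astype(np.float32)
        plan = plan_patches((8, 8), (8, 8), None)
        assert (predict_mask(model, image, plan) == 0).all()

    def test_single_patch_prediction_lands_at_crop_offset(self, rng):
        model = build_model(plan_layers(tiny_config(extent=(8, 8))), seed=4)
        image = rng.random((11, 8, 1)).astype(np.float32)
        plan = plan_patches((11, 8), (8, 8), None)
        assert plan.num_patches == 1
        off = plan.crop_offset
        pred = predict_mask(model, image, plan)
        patch = image[off[0]:off[0] + 8, off[1]:off[1] + 8]
        xb = np.moveaxis(patch, -1, 0)[None]
        direct = model.forward(xb, training=False)[0].argmax(axis=0)
        assert np.array_equal(pred[off[0]:off[0] + 8, off[1]:off[1] + 8], direct)
        pred[off[0]:off[0] + 8, off[1]:off[1] + 8] = 0
        assert (pred == 0).all()  # everything outside the crop is background

    def test_overlap_resolved_by_mean_class_score(self, rng):
        model = build_model(plan_layers(tiny_config(extent=(8, 8))), seed=6)
        image = rng.random((8, 12, 1)).astype(np.float32)
        mask = np.ones((8, 12), dtype=int)  # bbox wider than a patch -> overlap
        plan = plan_patches((8, 12), (8, 8), mask)
        assert plan.overlap_flag and plan.num_patches == 2
        pred = predict_mask(model, image, plan)
        # hand-average the two patch score maps
        scores = np.zeros((2, 8, 12))
        counts = np.zeros((8, 12))
        for origin in plan.patch_origins:
            patch = image[:, origin[1]:origin[1] + 8]
            probs = model.forward(np.moveaxis(patch, -1, 0)[None],
                                  training=False)[0]
            scores[:, :, origin[1]:origin[1] + 8] += probs
            counts[:, origin[1]:origin[1] + 8] += 1
        expect = (scores / counts).argmax(axis=0)
        assert np.array_equal(pred, expect)

    def test_extent_mismatch_rejected(self, rng):
        model = build_model(plan_layers(tiny_config(extent=(8, 8))), seed=0)
        plan = plan_patches((8, 8), (8, 8), None)
        with pytest.raises(ValueError, match="extent"):
            predict_mask(model, rng.random((9, 8, 1)), plan)
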