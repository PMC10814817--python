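"""Backbone contracts: shapes, determinism, gradients, training sanity."""

import numpy as np
import pytest

from disccascade.cropping import crop, window_from_center
from disccascade.model import (
    ModelConfig,
    TrainConfig,
    binarize_map,
    build_model,
    predict_map,
    train_model,
)
from disccascade.nn.backbones import multires_filter_split
from disccascade.nn.layers import BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d
from disccascade.nn.losses import LOSSES


def desk_model(**over):
    kw = dict(in_channels=1, out_channels=1, base_filters=8, depth=3,
              max_respath_len=1, seed=0)
    kw.update(over)
    return build_model(ModelConfig(**kw))


def test_forward_shape_and_range():
    m = desk_model(depth=4, base_filters=8)
    x = np.random.default_rng(0).random((1, 1, 64, 64), dtype=np.float32)
    y = m.predict(x)
    assert y.shape == (1, 1, 64, 64)
    assert y.min() >= 0.0 and y.max() <= 1.0


def test_constant_zero_input_is_finite():
    m = desk_model()
    y = predict_map(m, np.zeros((1, 64, 64), dtype=np.float32))
    assert np.isfinite(y).all()


def test_same_seed_same_initial_parameters():
    a, b = desk_model(), desk_model()
    for pa, pb in zip(a.net.params(), b.net.params()):
        assert np.array_equal(pa.value, pb.value)


def test_desk_parameter_count_under_a_million():
    assert desk_model(depth=3).n_params() < 1_000_000
    assert desk_model(in_channels=3, depth=4).n_params() < 1_000_000


def test_indivisible_spatial_dims_raise():
    m = desk_model(depth=3)
    with pytest.raises(ValueError, match="divisible"):
        m.predict(np.zeros((1, 60, 60), dtype=np.float32))


def test_channel_mismatch_raises():
    m = desk_model(in_channels=3)
    with pytest.raises(ValueError, match="channels"):
        m.predict(np.zeros((1, 64, 64), dtype=np.float32))


def test_multires_filter_allocation():
    """The three convolutions of a MultiRes block carry W/6, W/3, W/2
    filters for W = alpha * U."""
    m = build_model(ModelConfig(1, 1, base_filters=32, depth=2, seed=0))
    for lvl, blk in enumerate(m.net.enc_blocks):
        w = 1.67 * 32 * 2**lvl
        assert blk.filter_split == (int(w / 6), int(w / 3), int(w / 2))
        assert blk.filter_split == multires_filter_split(32, lvl, 1.67)
        # conv weight shapes agree with the split
        c1, c2, c3 = blk.filter_split
        assert blk.cbr1.conv.w.value.shape[1] == c1
        assert blk.cbr2.conv.w.value.shape[1] == c2
        assert blk.cbr3.conv.w.value.shape[1] == c3


def test_unet_backbone_same_contract():
    m = desk_model(arch="unet")
    y = m.predict(np.zeros((1, 64, 64), dtype=np.float32))
    assert y.shape == (1, 64, 64)


def test_binarize_threshold_convention():
    assert not binarize_map(np.full((4, 4), 0.4), 0.5).any()
    assert binarize_map(np.full((4, 4), 0.5), 0.5).all()
    with pytest.raises(ValueError):
        binarize_map(np.zeros((2, 2)), 0.0)


def test_binarize_monotone_in_threshold(rng):
    p = rng.random((32, 32))
    counts = [binarize_map(p, t).sum() for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)


def directional_check(layer, xshape, rng, tol=1e-3):
    """Forward-mode finite difference along a random direction vs backprop."""
    x = rng.standard_normal(xshape).astype(np.float32)
    y = layer.forward(x, train=True)
    gy = rng.standard_normal(y.shape).astype(np.float32)
    for p in layer.params():
        p.zero_grad()
    layer.forward(x, train=True)
    gx = layer.backward(gy.copy())
    vparams = [rng.standard_normal(p.value.shape).astype(np.float32) for p in layer.params()]
    vx = rng.standard_normal(x.shape).astype(np.float32)
    eps = 1e-3

    def loss_at(sign):
        for p, v in zip(layer.params(), vparams):
            p.value += np.float32(sign * eps) * v
        out = layer.forward(x + np.float32(sign * eps) * vx, train=True)
        for p, v in zip(layer.params(), vparams):
            p.value -= np.float32(sign * eps) * v
        return float((out.astype(np.float64) * gy).sum())

    fd = (loss_at(+1) - loss_at(-1)) / (2 * eps)
    ana = float(
        sum((p.grad * v).sum() for p, v in zip(layer.params(), vparams))
        + (gx.astype(np.float64) * vx).sum()
    )
    assert abs(fd - ana) / max(1e-6, abs(fd) + abs(ana)) < tol


def test_layer_gradients_match_finite_differences(rng):
    directional_check(Conv2d(3, 5, 3, rng), (2, 6, 6, 3), rng)
    directional_check(Conv2d(3, 5, 1, rng), (2, 6, 6, 3), rng)
    directional_check(BatchNorm2d(4), (2, 6, 6, 4), rng)
    directional_check(MaxPool2d(), (2, 6, 6, 4), rng)
    directional_check(ConvTranspose2d(3, 5, rng), (2, 6, 6, 3), rng)


def test_direct_and_gemm_conv_paths_agree(rng):
    """The numba direct kernel and the im2col GEMM path are the same conv."""
    c = Conv2d(4, 6, 3, rng)
    x = rng.random((2, 64, 64, 4)).astype(np.float32)
    g = rng.random((2, 64, 64, 6)).astype(np.float32)
    assert c._use_direct(64, 64)
    y1 = c.forward(x, train=True)
    dx1 = c.backward(g)
    gw1 = c.w.grad.copy()
    c._use_direct = lambda h, w: False
    for p in c.params():
        p.zero_grad()
    y2 = c.forward(x, train=True)
    dx2 = c.backward(g)
    assert np.allclose(y1, y2, atol=1e-5)
    assert np.allclose(dx1, dx2, atol=1e-5)
    assert np.allclose(gw1, c.w.grad, atol=1e-3)


def test_loss_gradients_match_finite_differences(rng):
    z = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)
    t = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
    for name, fn in LOSSES.items():
        _, dz = fn(z, t)
        v = rng.standard_normal(z.shape).astype(np.float32)
        eps = 1e-3
        lp, _ = fn(z + eps * v, t)
        lm, _ = fn(z - eps * v, t)
        fd = (lp - lm) / (2 * eps)
        ana = float((dz.astype(np.float64) * v).sum())
        assert abs(fd - ana) / max(1e-8, abs(fd) + abs(ana)) < 5e-3, name


def test_training_history_and_determinism():
    rng = np.random.default_rng(0)
    pairs = [(rng.random((1, 16, 16), dtype=np.float32),
              (rng.random((1, 16, 16)) > 0.5).astype(np.float32)) for _ in range(4)]
    cfg = TrainConfig(epochs=3, batch_size=2, loss="bce_dice", seed=1)
    m1 = train_model(desk_model(depth=2), pairs, cfg)
    m2 = train_model(desk_model(depth=2), pairs, cfg)
    assert len(m1.history) == 3
    assert m1.history == m2.history


def test_overfit_single_subimage(sample):
    """A desk-size model memorizes one crop: binarized IoU >= 0.9."""
    win = window_from_center(sample.centers["L5S1"], 64, sample.image.shape)
    x = crop(sample.image, win)[None]
    t = crop(sample.masks["L5S1"], win)[None].astype(np.float32)
    model = desk_model(depth=3)
    train_model(model, [(x, t)], TrainConfig(epochs=120, batch_size=1, loss="bce_dice",
                                             learning_rate=3e-3, seed=0))
    pred = binarize_map(model.predict(x)[0], 0.5)
    truth = t[0] > 0.5
    iou = (pred & truth).sum() / (pred | truth).sum()
    assert iou >= 0.9


def test_empty_training_set_raises():
    with pytest.raises(ValueError):
        train_model(desk_model(), [], TrainConfig(epochs=1))
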