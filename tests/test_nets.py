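import numpy as np
import pytest
from scipy import ndimage as ndi

from kymotrace.nets.data import (
    ANCHOR,
    crop_at,
    find_branch_points,
    make_decision_training_set,
    normalize_image,
    render_tracks_binary,
    track_chain,
)
from kymotrace.nets.layers import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dense,
    MaxPool2,
    Upsample2,
    cross_entropy,
    leaky_relu,
)
from kymotrace.nets.unet import Classifier, UNet, feature_widths, softmax
from kymotrace.simgen import GroundTruthTrack


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def test_leaky_relu_values():
    assert leaky_relu(2.0) == 2.0
    assert leaky_relu(-2.0) == pytest.approx(-0.2)
    assert leaky_relu(0.0) == 0.0
    np.testing.assert_allclose(leaky_relu(np.array([-1.0, 1.0])),
                               [-0.1, 1.0])


def test_cross_entropy_values():
    assert cross_entropy([1.0], [1.0]) == pytest.approx(0.0, abs=1e-5)
    assert cross_entropy([1.0], [0.5]) == pytest.approx(np.log(2), rel=1e-5)
    # clipping keeps impossible predictions finite
    assert np.isfinite(cross_entropy([1.0], [0.0]))


def test_conv2d_matches_scipy_correlate():
    rng = np.random.default_rng(0)
    conv = Conv2D(2, 3, 3, rng)
    x = rng.normal(size=(1, 2, 7, 9)).astype(np.float32)
    y = conv.forward(x)
    for o in range(3):
        expect = sum(
            ndi.correlate(x[0, c].astype(float),
                          conv.W[o, c].astype(float),
                          mode="constant")
            for c in range(2)) + conv.b[o]
        np.testing.assert_allclose(y[0, o], expect, atol=1e-4)


def test_conv2d_gradient_check():
    rng = np.random.default_rng(1)
    conv = Conv2D(1, 1, 3, rng)
    x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)

    def loss(W):
        conv.W = W.astype(np.float32)
        return float((conv.forward(x) ** 2).sum())

    y = conv.forward(x)
    conv.backward(2.0 * y)
    analytic = conv.dW.copy()
    eps = 1e-3
    W0 = conv.W.astype(np.float64).copy()
    for idx in [(0, 0, 0, 0), (0, 0, 1, 1), (0, 0, 2, 0)]:
        Wp, Wm = W0.copy(), W0.copy()
        Wp[idx] += eps
        Wm[idx] -= eps
        num = (loss(Wp) - loss(Wm)) / (2 * eps)
        assert analytic[idx] == pytest.approx(num, rel=2e-2, abs=1e-3)
    conv.W = W0.astype(np.float32)


def test_conv2d_input_gradient():
    rng = np.random.default_rng(2)
    conv = Conv2D(1, 2, 3, rng)
    x = rng.normal(size=(1, 1, 5, 5)).astype(np.float32)
    y = conv.forward(x)
    dx = conv.backward(2.0 * y)
    eps = 1e-2
    for idx in [(0, 0, 2, 2), (0, 0, 0, 4)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num = (float((conv.forward(xp) ** 2).sum())
               - float((conv.forward(xm) ** 2).sum())) / (2 * eps)
        assert dx[idx] == pytest.approx(num, rel=5e-2, abs=1e-2)


def test_maxpool_and_upsample_shapes():
    x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
    pooled = MaxPool2().forward(x)
    assert pooled.shape == (1, 1, 2, 2)
    np.testing.assert_array_equal(pooled[0, 0], [[5, 7], [13, 15]])
    up = Upsample2().forward(pooled)
    assert up.shape == (1, 1, 4, 4)
    assert up[0, 0, 0, 0] == 5 and up[0, 0, 1, 1] == 5


def test_batchnorm_normalizes_in_train_mode():
    bn = BatchNorm2D(3)
    x = np.random.default_rng(0).normal(5.0, 3.0, (4, 3, 8, 8)) \
        .astype(np.float32)
    y = bn.forward(x, train=True)
    assert abs(float(y.mean())) < 1e-4
    assert float(y.std()) == pytest.approx(1.0, abs=1e-3)


def test_adam_reduces_quadratic():
    rng = np.random.default_rng(0)
    w = rng.normal(size=3).astype(np.float32)
    g = np.zeros_like(w)
    opt = Adam([w], [g], lr=0.1)
    for _ in range(200):
        g[...] = 2.0 * w
        opt.step()
    assert np.abs(w).max() < 1e-2


# ---------------------------------------------------------------------------
# U-Net / classifier
# ---------------------------------------------------------------------------

def test_feature_widths_scaling():
    assert feature_widths(1.0) == [64, 128, 256, 512, 1024]
    assert feature_widths(1 / 16) == [4, 8, 16, 32, 64]
    assert feature_widths(1 / 64)[0] >= 2   # floor of 2 channels


def test_unet_shapes_and_range():
    net = UNet(in_ch=1, out_ch=2, width_multiplier=1 / 32, seed=0)
    x = np.random.default_rng(0).normal(size=(2, 1, 32, 48)) \
        .astype(np.float32)
    y = net.forward(x)
    assert y.shape == (2, 2, 32, 48)
    assert y.min() >= 0.0 and y.max() <= 1.0


def test_unet_rejects_bad_dims():
    net = UNet(width_multiplier=1 / 32)
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 1, 30, 32), np.float32))


def test_unet_whole_model_gradient_check():
    net = UNet(width_multiplier=1 / 32, dropout=0.0, seed=3)
    rng = np.random.default_rng(4)
    x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
    t = (rng.random((1, 1, 16, 16)) < 0.3).astype(np.float32)
    net.train_step_loss(x, t)  # populate grads
    params = net.params()
    grads = net.grads()
    # finite differences in float32 are only trustworthy for the layers
    # nearest the loss (perturbations through the full depth of batch
    # norms and LeakyReLU kinks are too non-linear at a usable epsilon),
    # so check the head and the last decoder block
    rng2 = np.random.default_rng(5)
    checked = 0
    for p, g in zip(params[-6:], grads[-6:]):
        flat = int(rng2.integers(p.size))
        idx = np.unravel_index(flat, p.shape)
        if abs(g[idx]) < 1e-4:
            continue
        eps = 1e-2
        orig = p[idx]
        p[idx] = orig + eps
        lp = _train_loss_eval(net, x, t)
        p[idx] = orig - eps
        lm = _train_loss_eval(net, x, t)
        p[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=0.15, abs=1e-4)
        checked += 1
    assert checked >= 3


def _train_loss_eval(net, x, t):
    # forward in train mode (batch statistics) without touching grads
    from kymotrace.nets.unet import sigmoid
    from kymotrace.nets.layers import EPS
    z = net.forward_logits(x, train=True)
    o = np.clip(sigmoid(z), EPS, 1 - EPS)
    return float(np.mean(-(t * np.log(o) + (1 - t) * np.log(1 - o))))


def test_unet_overfits_tiny_example():
    from kymotrace.nets.layers import Adam

    net = UNet(width_multiplier=1 / 16, dropout=0.0, seed=0)
    rng = np.random.default_rng(0)
    t = np.zeros((1, 1, 32, 32), np.float32)
    for r in range(32):
        t[0, 0, r, min(r, 31)] = 1.0
    x = (t + 0.1 * rng.normal(size=t.shape)).astype(np.float32)
    opt = Adam(net.params(), net.grads(), lr=2e-3)
    first = net.train_step_loss(x, t)
    for _ in range(400):
        loss = net.train_step_loss(x, t)
        opt.step()
    assert loss < 0.15 * first


def test_classifier_probabilities():
    clf = Classifier(width_multiplier=1 / 32, seed=0)
    x = np.random.default_rng(0).normal(size=(3, 1, 64, 64)) \
        .astype(np.float32)
    p = clf.forward(x)
    assert p.shape == (3, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
    assert clf.predict(x).shape == (3,)


def test_softmax_stable():
    p = softmax(np.array([[1000.0, 1000.0]]))
    np.testing.assert_allclose(p, [[0.5, 0.5]])


# ---------------------------------------------------------------------------
# training data construction
# ---------------------------------------------------------------------------

def _gt(tid, frames, positions):
    frames = np.asarray(frames)
    return GroundTruthTrack(id=tid, frames=frames,
                            positions=np.asarray(positions, float),
                            visible=np.ones(len(frames), bool))


def test_normalize_image():
    img = np.random.default_rng(0).uniform(3, 9, (10, 10))
    out = normalize_image(img)
    assert abs(float(out.mean())) < 1e-5
    assert float(out.std()) == pytest.approx(1.0, abs=1e-4)


def test_track_chain_contiguous():
    t = _gt(0, [0, 1, 2], [0.0, 3.0, 6.0])
    ch = track_chain(t)
    # consecutive chain pixels are 8-connected
    d = np.abs(np.diff(ch, axis=0)).max(axis=1)
    assert np.all(d == 1)
    assert tuple(ch[0]) == (0, 0) and tuple(ch[-1]) == (2, 6)


def test_render_tracks_binary_bridges_gaps():
    t = _gt(0, range(10), np.zeros(10))
    t.visible[4:6] = False
    img = render_tracks_binary([t], (10, 5), dilate=False)
    assert img[4, 0] and img[5, 0]   # gap frames still drawn in the target


def test_crop_at_anchor_and_padding():
    img = np.zeros((60, 60), np.float32)
    img[10, 20] = 7.0
    c = crop_at(img, (10, 20))
    assert c.shape == (48, 48)
    assert c[ANCHOR] == 7.0
    # near the border the out-of-image part is zero padded but in-image
    # content keeps its offset relative to the anchor
    c2 = crop_at(img, (2, 2))
    assert c2.shape == (48, 48)
    assert c2[ANCHOR[0] - 2 + 10, ANCHOR[1] - 2 + 20] == 7.0
    assert np.all(c2[:ANCHOR[0] - 2, :] == 0.0)   # rows above the image


def test_find_branch_points_on_cross():
    img = np.zeros((9, 9), bool)
    img[4, :] = True
    img[:, 4] = True
    bps = find_branch_points(img)
    assert (4, 4) in {tuple(p) for p in bps}


def test_decision_training_set_x_crossing():
    # two straight tracks crossing once -> one decision sample per track
    n = 61
    a = _gt(0, range(n), np.linspace(5, 55, n))
    b = _gt(1, range(n), np.linspace(55, 5, n))
    kymo = np.random.default_rng(0).uniform(0, 1, (n, 61))
    samples = make_decision_training_set(kymo, [a, b])
    assert len(samples) == 2
    for inputs, target in samples:
        assert inputs.shape == (3, 48, 48)
        assert target.shape == (48, 48)
        # upstream segment ends at the anchor pixel
        assert inputs[2][ANCHOR] == 1.0
        # downstream target exists and does not contain the anchor
        assert target.sum() > 0
        assert target[ANCHOR] == 0.0


def test_decision_training_set_no_branches():
    a = _gt(0, range(20), np.linspace(0, 19, 20))
    kymo = np.zeros((20, 20))
    assert make_decision_training_set(kymo, [a]) == []
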