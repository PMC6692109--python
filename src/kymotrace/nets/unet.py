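"""U-Net core and classifier head built from conv blocks.

A *conv block* is a padded 3x3 convolution followed by batch
normalisation and a leaky ramp activation.  The segmentation/decision
core is a U-Net: a contracting path of four pooling levels (optionally
with dropout for regularisation), a bottleneck, and an expanding path
with skip connections at every level.  Feature counts run from
``64 * width_multiplier`` at the top level to ``1024 * width_multiplier``
at the bottom; reduced multipliers make CPU training practical.  Because
of the four pooling levels, input height and width must be multiples of
16 (callers resize and restore when they are not).

The classifier shares the contracting path and bottleneck, then applies
global average pooling and a dense softmax over the two kymograph
classes (unidirectional / bidirectional).
"""

from __future__ import annotations

import numpy as np

from .layers import (Adam, BatchNorm2D, Conv2D, Dense, Dropout, LeakyReLU,
                     MaxPool2, Sequential, Upsample2, EPS)

__all__ = ["UNet", "Classifier", "sigmoid", "softmax", "DEPTH"]

DEPTH = 4
TOP_FEATURES = 64


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def conv_block(cin, cout, rng):
    return Sequential(Conv2D(cin, cout, 3, rng), BatchNorm2D(cout),
                      LeakyReLU())


def feature_widths(width_multiplier: float, depth: int = DEPTH):
    """Feature counts per level, top to bottom (depth+1 entries)."""
    return [max(2, int(round(TOP_FEATURES * width_multiplier)) * 2 ** i)
            for i in range(depth + 1)]


class _Encoder:
    """Contracting path + bottleneck, shared by U-Net and classifier."""

    def __init__(self, in_ch: int, widths: list[int], dropout: float,
                 rng: np.random.Generator):
        self.blocks = []   # per level: Sequential of two conv blocks (+dropout)
        self.pools = []
        cin = in_ch
        for f in widths[:-1]:
            layers = [*conv_block(cin, f, rng).layers,
                      *conv_block(f, f, rng).layers]
            if dropout > 0:
                layers.append(Dropout(dropout, rng))
            self.blocks.append(Sequential(*layers))
            self.pools.append(MaxPool2())
            cin = f
        self.bottom = Sequential(*conv_block(cin, widths[-1], rng).layers,
                                 *conv_block(widths[-1], widths[-1], rng).layers)

    def modules(self):
        return [*self.blocks, self.bottom]

    def forward(self, x, train=False):
        skips = []
        for blk, pool in zip(self.blocks, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        return self.bottom.forward(x, train), skips

    def backward(self, dy, dskips):
        dy = self.bottom.backward(dy)
        for blk, pool, dskip in zip(reversed(self.blocks),
                                    reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            if dskip is not None:
                dy = dy + dskip
            dy = blk.backward(dy)
        return dy


class UNet:
    """Segmentation core: ``in_ch`` input channels to ``out_ch`` per-pixel
    maps squashed to [0, 1]."""

    def __init__(self, in_ch: int = 1, out_ch: int = 1,
                 width_multiplier: float = 1.0, dropout: float = 0.1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = feature_widths(width_multiplier)
        self.widths = widths
        self.in_ch, self.out_ch = in_ch, out_ch
        self.width_multiplier = width_multiplier
        self.dropout = dropout
        self.enc = _Encoder(in_ch, widths, dropout, rng)
        self.ups = []
        self.dec = []
        for lvl in reversed(range(DEPTH)):
            f = widths[lvl]
            self.ups.append(Sequential(Upsample2(),
                                       *conv_block(widths[lvl + 1], f,
                                                   rng).layers))
            self.dec.append(Sequential(*conv_block(2 * f, f, rng).layers,
                                       *conv_block(f, f, rng).layers))
        self.head = Conv2D(widths[0], out_ch, 1, rng)

    def modules(self):
        return [*self.enc.modules(), *self.ups, *self.dec, self.head]

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def grads(self):
        return [g for m in self.modules() for g in m.grads()]

    def forward_logits(self, x, train=False):
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input height/width must be multiples of 16")
        y, skips = self.enc.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            y = up.forward(y, train)
            y = np.concatenate([skip, y], axis=1)
            dec._split = skip.shape[1]
            y = dec.forward(y, train)
        return self.head.forward(y, train)

    def forward(self, x, train=False):
        return sigmoid(self.forward_logits(x, train))

    def backward_from_logits(self, dz):
        dy = self.head.backward(dz)
        dskips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            dcat = dec.backward(dy)
            split = dec._split
            dskips.append(dcat[:, :split])
            dy = up.backward(dcat[:, split:])
        # dskips were collected top level first (reversed decoder order),
        # which is exactly the top..bottom order enc.backward expects
        return self.enc.backward(dy, dskips)

    def train_step_loss(self, x, t):
        """Fused sigmoid + cross-entropy step: returns the loss and leaves
        gradients in place for the optimiser."""
        z = self.forward_logits(x, train=True)
        o = sigmoid(z)
        oc = np.clip(o, EPS, 1 - EPS)
        loss = float(np.mean(-(t * np.log(oc) + (1 - t) * np.log(1 - oc))))
        dz = (o - t) / o.size
        self.backward_from_logits(dz)
        return loss

    def loss(self, x, t):
        o = np.clip(self.forward(x), EPS, 1 - EPS)
        return float(np.mean(-(t * np.log(o) + (1 - t) * np.log(1 - o))))

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())


class Classifier:
    """Kymograph class probabilities (unidirectional vs bidirectional)
    from a 64x64 input: U-Net contracting path, global average pooling,
    dense softmax."""

    def __init__(self, width_multiplier: float = 1.0, dropout: float = 0.0,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = feature_widths(width_multiplier)
        self.widths = widths
        self.width_multiplier = width_multiplier
        self.dropout = dropout
        self.enc = _Encoder(1, widths, dropout, rng)
        self.fc = Dense(widths[-1], 2, rng)

    def modules(self):
        return [*self.enc.modules(), self.fc]

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def grads(self):
        return [g for m in self.modules() for g in m.grads()]

    def forward_logits(self, x, train=False):
        y, skips = self.enc.forward(x, train)
        self._pool_shape = y.shape
        feat = y.mean(axis=(2, 3))
        self._nskip = len(skips)
        return self.fc.forward(feat, train)

    def forward(self, x, train=False):
        return softmax(self.forward_logits(x, train))

    def train_step_loss(self, x, labels):
        z = self.forward_logits(x, train=True)
        p = softmax(z)
        n = len(labels)
        onehot = np.zeros_like(p)
        onehot[np.arange(n), labels] = 1.0
        loss = float(-np.log(np.clip(p[np.arange(n), labels], EPS, 1)).mean())
        dz = (p - onehot) / n
        dfeat = self.fc.backward(dz)
        N, C, H, W = self._pool_shape
        dy = np.broadcast_to(dfeat[:, :, None, None] / (H * W),
                             self._pool_shape).copy()
        self.enc.backward(dy, [None] * self._nskip)
        return loss

    def predict(self, x):
        return self.forward(x).argmax(axis=-1)

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())
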