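"""The four network modules: build, augment, train, bundle, decide.

Module kinds:

* ``class``    — 64x64 resized kymograph -> two class probabilities
  (unidirectional / bidirectional), softmax.
* ``uniseg``   — kymograph -> two trackness maps (positive-slope and
  negative-slope particles).
* ``biseg``    — kymograph -> one trackness map.
* ``decision`` — three 48x48 crops (raw kymograph, full skeleton,
  current-track segment) -> one 48x48 future-path trackness map.

Training follows per-pixel cross entropy with Adam (initial learning
rate 0.001) and a step learning-rate schedule (x0.5 after a per-module
fraction of the batch budget); 95% of the data trains, 5% validates,
and the best-validation checkpoint over the configured restarts is
returned.  Defaults use the full-width architecture; ``width_multiplier``
scales every feature count down for CPU-scale training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin as _thin
from skimage.transform import resize

from .data import ANCHOR, CROP, normalize_image
from .layers import EPS, Adam, BatchNorm2D, Sequential
from .unet import Classifier, UNet, sigmoid

__all__ = [
    "build_module", "TrainConfig", "train_module", "TrainingError",
    "ModelBundle", "decide_nn", "save_bundle", "load_bundle",
    "MODULE_KINDS",
]

MODULE_KINDS = ("class", "uniseg", "biseg", "decision")

# paper-scale schedule step (batches after which the learning rate halves)
DECAY_STEP = {"uniseg": 4000, "biseg": 3000, "decision": 8000, "class": None}
DEFAULT_BATCH = {"class": 50, "uniseg": 20, "biseg": 20, "decision": 50}
DEFAULT_CROP = {"uniseg": (128, 80), "biseg": (128, 80)}


class TrainingError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


def build_module(kind: str, width_multiplier: float = 1.0,
                 dropout: float = 0.1, seed: int = 0):
    """Instantiate one of the four network modules."""
    if kind == "class":
        return Classifier(width_multiplier=width_multiplier, seed=seed)
    if kind == "uniseg":
        return UNet(1, 2, width_multiplier, dropout, seed)
    if kind == "biseg":
        return UNet(1, 1, width_multiplier, dropout, seed)
    if kind == "decision":
        return UNet(3, 1, width_multiplier, dropout, seed)
    raise ValueError(f"unknown module kind {kind!r}")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _background_gradient(shape, rng, scale=0.5):
    r = np.linspace(-1, 1, shape[0], dtype=np.float32)[:, None]
    c = np.linspace(-1, 1, shape[1], dtype=np.float32)[None, :]
    return (rng.uniform(-scale, scale) * r
            + rng.uniform(-scale, scale) * c).astype(np.float32)


def _noise(img, rng, gauss_max=0.4, uniform_max=0.4):
    out = img + rng.normal(0, rng.uniform(0, gauss_max),
                           img.shape).astype(np.float32)
    out = out + rng.uniform(-rng.uniform(0, uniform_max),
                            rng.uniform(0, uniform_max),
                            img.shape).astype(np.float32)
    return out + _background_gradient(img.shape, rng)


def augment_segmentation_pair(img: np.ndarray, tgt: np.ndarray,
                              rng: np.random.Generator, uni: bool):
    """Geometry-preserving augmentation of an (image, target) pair.

    Reflections along either axis reverse the slope sign of every track,
    so for the two-channel unidirectional target a single reflection
    swaps the channels; a 180-degree rotation (both reflections) keeps
    them.  Noise and background gradients touch only the image.
    """
    swaps = 0
    if rng.random() < 0.5:
        img = img[:, ::-1]
        tgt = tgt[:, :, ::-1]
        swaps += 1
    if rng.random() < 0.5:
        img = img[::-1]
        tgt = tgt[:, ::-1]
        swaps += 1
    if uni and swaps % 2 == 1:
        tgt = tgt[::-1]
    img = _noise(np.ascontiguousarray(img), rng)
    return normalize_image(img), np.ascontiguousarray(tgt)


def augment_class_image(img: np.ndarray, rng: np.random.Generator):
    if rng.random() < 0.5:
        img = img[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1]
    # random resize (zoom crop) before the final 64x64 resize
    if rng.random() < 0.5:
        h, w = img.shape
        f = rng.uniform(0.6, 1.0)
        ch, cw = max(32, int(h * f)), max(32, int(w * f))
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        img = img[r0:r0 + ch, c0:c0 + cw]
    img = resize(np.ascontiguousarray(img, np.float32), (64, 64),
                 preserve_range=True, anti_aliasing=True).astype(np.float32)
    if rng.random() < 0.3:      # colour negation
        img = img.max() - img
    img = _noise(img, rng)
    return normalize_image(img)


def augment_decision_pair(inputs: np.ndarray, tgt: np.ndarray,
                          rng: np.random.Generator):
    """Flips keep the anchor pixel fixed (roll-by-one after reflection);
    random morphological thinning of the binary channels simulates
    skeletonization artefacts; noise goes on the raw channel only."""
    if rng.random() < 0.5:
        inputs = np.roll(inputs[:, :, ::-1], 1, axis=2)
        tgt = np.roll(tgt[:, ::-1], 1, axis=1)
    if rng.random() < 0.5:
        inputs = np.roll(inputs[:, ::-1], 1, axis=1)
        tgt = np.roll(tgt[::-1], 1, axis=0)
    inputs = np.ascontiguousarray(inputs)
    tgt = np.ascontiguousarray(tgt)
    if rng.random() < 0.3:
        for ch in (1, 2):
            inputs[ch] = _thin(inputs[ch] > 0.5, max_num_iter=1
                               ).astype(np.float32)
    inputs[0] = normalize_image(_noise(inputs[0], rng))
    return inputs, tgt


# ---------------------------------------------------------------------------
# batch samplers
# ---------------------------------------------------------------------------

def _sample_seg_batch(dataset, batch_size, crop, rng, uni):
    xs, ts = [], []
    ch, cw = crop
    for _ in range(batch_size):
        img, tgt = dataset[rng.integers(len(dataset))]
        H, W = img.shape
        r0 = rng.integers(0, max(H - ch, 0) + 1)
        c0 = rng.integers(0, max(W - cw, 0) + 1)
        ic = img[r0:r0 + ch, c0:c0 + cw]
        tc = tgt[:, r0:r0 + ch, c0:c0 + cw]
        ic, tc = augment_segmentation_pair(ic, tc, rng, uni)
        xs.append(ic[None])
        ts.append(tc)
    return np.stack(xs), np.stack(ts)


def _sample_class_batch(dataset, batch_size, rng):
    uni_pool = [d for d in dataset if d[1] == 0]
    bi_pool = [d for d in dataset if d[1] == 1]
    half = batch_size // 2
    xs, ys = [], []
    for pool, n in ((uni_pool, half), (bi_pool, batch_size - half)):
        for _ in range(n):
            img, lbl = pool[rng.integers(len(pool))]
            xs.append(augment_class_image(img, rng)[None])
            ys.append(lbl)
    return np.stack(xs), np.array(ys)


def _sample_decision_batch(dataset, batch_size, rng):
    xs, ts = [], []
    for _ in range(batch_size):
        inp, tgt = dataset[rng.integers(len(dataset))]
        inp, tgt = augment_decision_pair(inp.copy(), tgt.copy(), rng)
        xs.append(inp)
        ts.append(tgt[None])
    return np.stack(xs), np.stack(ts)


def _eval_pairs(kind, pairs):
    """Deterministic evaluation pairs (no augmentation) for validation."""
    xs, ts = [], []
    for a, b in pairs:
        if kind == "class":
            img = resize(a, (64, 64), preserve_range=True,
                         anti_aliasing=True).astype(np.float32)
            xs.append(normalize_image(img)[None])
            ts.append(b)
        elif kind == "decision":
            a = a.copy()
            a[0] = normalize_image(a[0])
            xs.append(a)
            ts.append(b[None])
        else:
            H = (a.shape[0] // 16) * 16
            W = (a.shape[1] // 16) * 16
            xs.append(normalize_image(a[:H, :W])[None])
            ts.append(b[:, :H, :W])
    if kind == "class":
        return np.stack(xs), np.array(ts)
    return np.stack(xs), np.stack(ts)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the full-scale recipe."""

    lr: float = 1e-3
    n_batches: int = 8000
    batch_size: Optional[int] = None        # None -> per-kind default
    decay_step: Optional[int] = None        # None -> per-kind default,
                                            # scaled when n_batches differs
    width_multiplier: float = 1.0
    dropout: float = 0.1
    val_fraction: float = 0.05
    val_every: int = 50
    n_restarts: int = 3
    seed: int = 0
    crop: Optional[tuple[int, int]] = None


def _decay_step_for(kind: str, cfg: TrainConfig) -> Optional[int]:
    if cfg.decay_step is not None:
        return cfg.decay_step
    full = DECAY_STEP[kind]
    if full is None:
        return None
    # at reduced batch budgets the step point scales proportionally
    full_budget = {"uniseg": 8000, "biseg": 6000, "decision": 16000}[kind]
    return max(1, int(round(full * cfg.n_batches / full_budget)))


def train_module(kind: str, dataset, cfg: TrainConfig):
    """Train one module; returns ``(network, history)`` where history is a
    list of dicts with train/validation losses (and the classification
    validation error rate for the class module).  The checkpoint with the
    best validation loss across restarts is returned."""
    if not dataset:
        raise ValueError("empty dataset")
    if kind not in MODULE_KINDS:
        raise ValueError(kind)
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(len(dataset) * cfg.val_fraction)))
    idx = rng.permutation(len(dataset))
    val_pairs = [dataset[i] for i in idx[:n_val]]
    train_pairs = [dataset[i] for i in idx[n_val:]]
    xval, tval = _eval_pairs(kind, val_pairs)

    batch_size = cfg.batch_size or DEFAULT_BATCH[kind]
    crop = cfg.crop or DEFAULT_CROP.get(kind)
    decay = _decay_step_for(kind, cfg)
    uni = kind == "uniseg"

    best = None
    history_all = []
    for restart in range(cfg.n_restarts):
        net = build_module(kind, cfg.width_multiplier, cfg.dropout,
                           seed=cfg.seed + 1000 * restart)
        opt = Adam(net.params(), net.grads(), lr=cfg.lr)
        history = []
        for step in range(cfg.n_batches):
            if kind == "class":
                x, t = _sample_class_batch(train_pairs, batch_size, rng)
            elif kind == "decision":
                x, t = _sample_decision_batch(train_pairs, batch_size, rng)
            else:
                x, t = _sample_seg_batch(train_pairs, batch_size, crop,
                                         rng, uni)
            loss = net.train_step_loss(x, t)
            if not np.isfinite(loss):
                raise TrainingError("training diverged (non-finite loss)",
                                    history)
            scale = 0.5 if (decay is not None and step >= decay) else 1.0
            opt.step(scale)
            if (step + 1) % cfg.val_every == 0 or step == cfg.n_batches - 1:
                rec = {"restart": restart, "step": step + 1,
                       "train_loss": loss}
                if kind == "class":
                    p = net.forward(xval)
                    vl = float(-np.log(np.clip(
                        p[np.arange(len(tval)), tval], EPS, 1)).mean())
                    rec["val_loss"] = vl
                    rec["val_error"] = float((p.argmax(-1) != tval).mean())
                else:
                    rec["val_loss"] = net.loss(xval, tval)
                history.append(rec)
                if best is None or rec["val_loss"] < best[0]:
                    best = (rec["val_loss"], get_state(net), restart)
        history_all.extend(history)

    net = build_module(kind, cfg.width_multiplier, cfg.dropout, seed=cfg.seed)
    set_state(net, best[1])
    return net, history_all


# ---------------------------------------------------------------------------
# state (de)serialisation
# ---------------------------------------------------------------------------

def _walk_layers(net):
    for m in net.modules():
        if isinstance(m, Sequential):
            yield from m.layers
        else:
            yield m


def get_state(net) -> list[np.ndarray]:
    """All learnable parameters plus batch-norm running statistics."""
    arrays = []
    for layer in _walk_layers(net):
        arrays.extend(p.copy() for p in layer.params())
        if isinstance(layer, BatchNorm2D):
            arrays.append(layer.running_mean.copy())
            arrays.append(layer.running_var.copy())
    return arrays


def set_state(net, arrays: list[np.ndarray]) -> None:
    it = iter(arrays)
    for layer in _walk_layers(net):
        for p in layer.params():
            p[...] = next(it)
        if isinstance(layer, BatchNorm2D):
            layer.running_mean[...] = next(it)
            layer.running_var[...] = next(it)


# ---------------------------------------------------------------------------
# inference wrappers
# ---------------------------------------------------------------------------

def _to_mult16(n: int) -> int:
    return max(16, int(round(n / 16)) * 16)


def _segment(net: UNet, kymo: np.ndarray) -> np.ndarray:
    """Run a segmentation net on an arbitrary-size kymograph; inputs are
    resized to multiples of 16 and the maps resized back."""
    H, W = kymo.shape
    h, w = _to_mult16(H), _to_mult16(W)
    img = normalize_image(kymo)
    if (h, w) != (H, W):
        img = resize(img, (h, w), preserve_range=True).astype(np.float32)
    maps = net.forward(img[None, None])[0]
    if (h, w) != (H, W):
        maps = np.stack([resize(m, (H, W), preserve_range=True)
                         for m in maps])
    return np.clip(maps, 0.0, 1.0)


@dataclass
class ModelBundle:
    """The trained modules, routed by :func:`kymotrace.tracer.run_pipeline`."""

    classifier: Optional[Classifier] = None
    uniseg: Optional[UNet] = None
    biseg: Optional[UNet] = None
    decision: Optional[UNet] = None
    width_multiplier: float = 1.0
    meta: dict = field(default_factory=dict)

    def classify(self, kymo: np.ndarray) -> int:
        """0 = unidirectional, 1 = bidirectional."""
        if self.classifier is None:
            raise ValueError("classification module not loaded")
        img = resize(np.asarray(kymo, np.float32), (64, 64),
                     preserve_range=True, anti_aliasing=True)
        x = normalize_image(img)[None, None]
        return int(self.classifier.predict(x)[0])

    def segment_unidirectional(self, kymo):
        if self.uniseg is None:
            raise ValueError("unidirectional segmentation module not loaded")
        maps = _segment(self.uniseg, kymo)
        return maps[0], maps[1]

    def segment_bidirectional(self, kymo):
        if self.biseg is None:
            raise ValueError("bidirectional segmentation module not loaded")
        return _segment(self.biseg, kymo)[0]


def decide_nn(kymo: np.ndarray, skel: np.ndarray, current, net: UNet,
              threshold: float = 0.5):
    """Branch-point resolution with the decision network.

    Crops the raw kymograph, the full skeleton and the current track to
    48x48 with the track end at the anchor pixel, predicts the
    future-path map, binarizes it at 0.5 (the output was found
    insensitive to this value), thins, and returns the largest connected
    component as an ordered pixel list together with its mean predicted
    trackness (the decision confidence).  Returns ``(None, 0.0)`` when no
    future path is predicted.
    """
    from .data import crop_at  # local import to avoid cycle at module load

    end = current.pixels[-1]
    cur_img = np.zeros(skel.shape, np.float32)
    for p in current.pixels:
        cur_img[p] = 1.0
    inputs = np.stack([
        crop_at(normalize_image(kymo), end),
        crop_at(skel.astype(np.float32), end),
        crop_at(cur_img, end),
    ])
    pred = net.forward(inputs[None])[0, 0]
    mask = pred >= threshold
    # the anchor area belongs to the already-traced past, not the future
    mask[ANCHOR[0], ANCHOR[1]] = False
    if not mask.any():
        return None, 0.0
    mask = _thin(mask)
    lbl, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return None, 0.0
    # prefer the largest component adjacent to the anchor; fall back to
    # the globally largest one
    sizes = ndi.sum_labels(mask, lbl, index=np.arange(1, n + 1))
    near = lbl[max(ANCHOR[0] - 2, 0):ANCHOR[0] + 3,
               max(ANCHOR[1] - 2, 0):ANCHOR[1] + 3]
    near_labels = np.unique(near[near > 0])
    if len(near_labels):
        k = int(near_labels[np.argmax(sizes[near_labels - 1])])
    else:
        k = int(np.argmax(sizes)) + 1
    comp = np.argwhere(lbl == k)
    confidence = float(pred[lbl == k].mean())
    # order pixels by path distance from the anchor, then map to global
    d2 = ((comp - np.array(ANCHOR)) ** 2).sum(axis=1)
    order = _order_component(comp, int(np.argmin(d2)))
    r_off = end[0] - ANCHOR[0]
    c_off = end[1] - ANCHOR[1]
    out = []
    for r, c in order:
        gr, gc = r + r_off, c + c_off
        if 0 <= gr < skel.shape[0] and 0 <= gc < skel.shape[1]:
            out.append((int(gr), int(gc)))
    if not out:
        return None, 0.0
    return out, confidence


def _order_component(pixels: np.ndarray, start_idx: int):
    """BFS ordering of a pixel component from a start pixel."""
    pix = [tuple(p) for p in pixels]
    pset = set(pix)
    start = pix[start_idx]
    order = [start]
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    p = (r + dr, c + dc)
                    if p in pset and p not in seen:
                        seen.add(p)
                        order.append(p)
                        nxt.append(p)
        frontier = nxt
    return order


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path) -> None:
    """Write all modules to a single ``.npz`` checkpoint with embedded
    configuration."""
    arrays = {}
    meta = {"width_multiplier": bundle.width_multiplier,
            "modules": {}, **({"meta": bundle.meta} if bundle.meta else {})}
    for kind, net in (("class", bundle.classifier), ("uniseg", bundle.uniseg),
                      ("biseg", bundle.biseg), ("decision", bundle.decision)):
        if net is None:
            continue
        meta["modules"][kind] = {
            "width_multiplier": net.width_multiplier,
            "dropout": getattr(net, "dropout", 0.0),
        }
        for i, a in enumerate(get_state(net)):
            arrays[f"{kind}_{i}"] = a
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_bundle(path) -> ModelBundle:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        bundle = ModelBundle(width_multiplier=meta["width_multiplier"],
                             meta=meta.get("meta", {}))
        for kind, spec in meta["modules"].items():
            net = build_module(kind, spec["width_multiplier"],
                               spec.get("dropout", 0.0), seed=0)
            arrays = []
            i = 0
            while f"{kind}_{i}" in z:
                arrays.append(z[f"{kind}_{i}"])
                i += 1
            set_state(net, arrays)
            if kind == "class":
                bundle.classifier = net
            elif kind == "uniseg":
                bundle.uniseg = net
            elif kind == "biseg":
                bundle.biseg = net
            else:
                bundle.decision = net
    return bundle
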