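"""Classical comparator: stationary-wavelet trackness + linear prediction.

A non-learning baseline for bidirectional kymographs.  A stationary
(undecimated) Haar wavelet transform decomposes the kymograph into
same-size coefficient images; the detail bands that emphasise horizontal
and vertical line structure are rescaled, overlaid by maximum, binarized
at a fixed threshold (default 0.3) and thinned into a skeleton.  The
skeleton is traced with the same engine as the trained pipeline, but
branch points are resolved by *linear prediction*: the dilated terminal
segment of the current track is rotated 180 degrees about the track end,
multiplied with the skeleton, and the largest connected component of the
product is taken as the future path.  No decision confidence exists, so
track overlaps are assigned randomly (seeded).

This baseline was tuned to synthetic kymographs and is kept as a
benchmark comparator rather than a recommended tracer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pywt
from scipy import ndimage as ndi

from .tracer import thin_prune, trace_skeleton
from .tracks import RawTrack, Track

__all__ = ["WaveletParams", "wavelet_trackness", "wavelet_skeleton",
           "linear_predict", "trace_wavelet"]


@dataclass
class WaveletParams:
    wavelet: str = "haar"
    levels: int = 2
    # (level, band) pairs overlaid into the trackness map; bands are
    # 'h' (horizontal detail), 'v' (vertical detail), 'd' (diagonal).
    # All three orientations are needed: sloped track lines load mostly
    # on 'd', near-stationary (vertical) lines on 'h'/'v'.
    selected_bands: tuple = ((1, "h"), (1, "v"), (1, "d"),
                             (2, "h"), (2, "v"), (2, "d"))
    threshold: float = 0.3
    tail_px: int = 6          # terminal-segment length used for prediction

    def validate(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


def _rescale01(a: np.ndarray) -> np.ndarray:
    a = np.abs(a)
    lo, hi = a.min(), a.max()
    if hi - lo < 1e-12:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def wavelet_trackness(kymo: np.ndarray, params: WaveletParams | None = None
                      ) -> np.ndarray:
    """Overlay (max) of the selected rescaled SWT detail bands, in [0, 1]."""
    params = params or WaveletParams()
    params.validate()
    img = np.asarray(kymo, float)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else img * 0.0
    # SWT needs dims divisible by 2**levels: pad symmetrically, crop after
    m = 2 ** params.levels
    ph = (-img.shape[0]) % m
    pw = (-img.shape[1]) % m
    padded = np.pad(img, ((0, ph), (0, pw)), mode="symmetric")
    coeffs = pywt.swt2(padded, params.wavelet, level=params.levels,
                       norm=True)
    # pywt returns [(cA_n, (cH_n, cV_n, cD_n)), ...] with the *deepest*
    # level first; map to 1-based level numbers shallow..deep
    by_level = {}
    for i, (_, (ch, cv, cd)) in enumerate(coeffs):
        level = params.levels - i
        by_level[level] = {"h": ch, "v": cv, "d": cd}
    out = np.zeros_like(padded)
    for level, band in params.selected_bands:
        if level not in by_level:
            continue
        out = np.maximum(out, _rescale01(by_level[level][band]))
    return out[:img.shape[0], :img.shape[1]]


def wavelet_skeleton(kymo: np.ndarray, params: WaveletParams | None = None
                     ) -> np.ndarray:
    """Binarized (fixed threshold) and iteratively thinned trackness map."""
    params = params or WaveletParams()
    trackness = wavelet_trackness(kymo, params)
    return thin_prune(trackness >= params.threshold)


def linear_predict(current: RawTrack, skel: np.ndarray,
                   tail_px: int = 6):
    """Continuation by point reflection of the recent past.

    The last ``tail_px`` pixels of the track are dilated once (3x3) and
    rotated 180 degrees about the track end; the result, multiplied with
    the skeleton, marks where the track would go if it continued
    straight.  The largest connected component of the product is
    returned (ordered away from the track end), with no confidence.
    """
    if len(current.pixels) < 2:
        return None, 0.0
    end = current.pixels[-1]
    tail = current.pixels[-min(len(current.pixels), tail_px + 1):-1]
    field_img = np.zeros(skel.shape, bool)
    hits = []
    for r, c in tail:
        # 180-degree rotation about the end pixel
        pr, pc = 2 * end[0] - r, 2 * end[1] - c
        hits.append((pr, pc))
    for pr, pc in hits:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):   # dilation with a 3x3 element
                q = (pr + dr, pc + dc)
                if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]:
                    field_img[q] = True
    product = field_img & skel.astype(bool)
    product[end] = False
    if not product.any():
        return None, 0.0
    lbl, n = ndi.label(product, structure=np.ones((3, 3), int))
    sizes = ndi.sum_labels(product, lbl, index=np.arange(1, n + 1))
    k = int(np.argmax(sizes)) + 1
    comp = np.argwhere(lbl == k)
    # order by distance from the track end
    d2 = ((comp - np.array(end)) ** 2).sum(axis=1)
    comp = comp[np.argsort(d2, kind="stable")]
    return [tuple(map(int, p)) for p in comp], 0.0


def trace_wavelet(kymo: np.ndarray, params: WaveletParams | None = None,
                  seed: int = 0) -> list[Track]:
    """Full baseline tracer; deterministic given (kymo, params, seed)."""
    params = params or WaveletParams()
    skel = wavelet_skeleton(kymo, params)
    rng = np.random.default_rng(seed)

    def decide(k, s, current):
        return linear_predict(current, s, params.tail_px)

    return trace_skeleton(skel, kymo, decide, rng=rng)
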