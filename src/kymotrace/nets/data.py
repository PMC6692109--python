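"""Training-set construction from the synthetic simulators.

Segmentation targets are the ground-truth trajectories rendered as
digital lines — including the frames hidden by artificial gaps, so the
networks learn to bridge signal dropouts — dilated once with a 3x3
element so the positive class is three pixels wide (the tracer thins the
predicted maps back to one pixel).  Unidirectional targets are separated
by slope sign into two channels, which removes crossings from each map.

The decision training set mimics the situation the tracer faces at a
branch point: for every (branch point, incoming segment) pair found on
the combined ground-truth skeleton, a 48x48 window is cut with the
incoming segment's end at the anchor pixel (24, 24); the inputs are the
raw kymograph crop, the full-skeleton crop and the incoming-segment
crop, and the target is the segment continuing beyond the branch point.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import thin as _thin

from ..simgen import (BiSimConfig, GroundTruthTrack, UniSimConfig,
                      simulate_bidirectional, simulate_unidirectional)

__all__ = [
    "normalize_image", "track_chain", "render_tracks_binary",
    "make_segmentation_dataset", "make_class_dataset",
    "make_decision_training_set", "make_decision_dataset",
    "ANCHOR", "CROP",
]

CROP = 48
ANCHOR = (24, 24)   # 0-based anchor pixel for decision crops
DILATE_SELEM = np.ones((3, 3), bool)


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Standardize an image to zero mean, unit variance (float32)."""
    img = np.asarray(img, np.float32)
    std = img.std()
    return (img - img.mean()) / (std if std > 1e-8 else 1.0)


def track_chain(track: GroundTruthTrack) -> np.ndarray:
    """Ordered (row, col) pixel chain of a track, gaps included, with
    consecutive points joined by digital lines."""
    r = np.round(track.frames).astype(int)
    c = np.round(track.positions).astype(int)
    pts: list[tuple[int, int]] = []
    for k in range(len(r) - 1):
        rr, cc = draw_line(r[k], c[k], r[k + 1], c[k + 1])
        pts.extend(zip(rr.tolist(), cc.tolist()))
    pts.append((int(r[-1]), int(c[-1])))
    return np.array(list(dict.fromkeys(pts)), int).reshape(-1, 2)


def _chain_image(chain: np.ndarray, shape) -> np.ndarray:
    img = np.zeros(shape, bool)
    ok = ((chain[:, 0] >= 0) & (chain[:, 0] < shape[0])
          & (chain[:, 1] >= 0) & (chain[:, 1] < shape[1]))
    img[chain[ok, 0], chain[ok, 1]] = True
    return img


def track_slope_sign(track: GroundTruthTrack) -> int:
    """+1 for rightward (positive slope) motion, -1 for leftward."""
    d = track.positions[-1] - track.positions[0]
    return 1 if d >= 0 else -1


def render_tracks_binary(tracks, shape, dilate: bool = True,
                         slope_sign: int | None = None) -> np.ndarray:
    """Binary target map of full trajectories (gaps bridged)."""
    img = np.zeros(shape, bool)
    for t in tracks:
        if slope_sign is not None and track_slope_sign(t) != slope_sign:
            continue
        img |= _chain_image(track_chain(t), shape)
    if dilate:
        img = ndi.binary_dilation(img, DILATE_SELEM)
    return img


def make_segmentation_dataset(mode: str, n_samples: int, seed: int,
                              uni_cfg: UniSimConfig | None = None,
                              bi_cfg: BiSimConfig | None = None):
    """List of (kymograph, target) pairs for the segmentation modules.

    ``mode`` is ``"uni"`` (2-channel slope-separated target) or ``"bi"``
    (1-channel target).  Bidirectional training movies carry 30 tracks.
    """
    out = []
    for i in range(n_samples):
        s = seed * 100003 + i
        if mode == "uni":
            cfg = uni_cfg or UniSimConfig()
            sample = simulate_unidirectional(cfg, s, render_movie=False)
            tgt = np.stack([
                render_tracks_binary(sample.tracks, sample.kymograph.shape,
                                     slope_sign=+1),
                render_tracks_binary(sample.tracks, sample.kymograph.shape,
                                     slope_sign=-1),
            ]).astype(np.float32)
        elif mode == "bi":
            cfg = bi_cfg or BiSimConfig(n_tracks=30)
            sample = simulate_bidirectional(cfg, s, render_movie=False)
            tgt = render_tracks_binary(
                sample.tracks, sample.kymograph.shape
            )[None].astype(np.float32)
        else:
            raise ValueError(mode)
        out.append((sample.kymograph.astype(np.float32), tgt))
    return out


def make_class_dataset(n_per_class: int, seed: int,
                       uni_cfg: UniSimConfig | None = None,
                       bi_cfg: BiSimConfig | None = None):
    """Balanced list of (kymograph, label) pairs; 0 = unidirectional,
    1 = bidirectional."""
    out = []
    for i in range(n_per_class):
        s = seed * 200003 + i
        su = simulate_unidirectional(uni_cfg or UniSimConfig(), s,
                                     render_movie=False)
        sb = simulate_bidirectional(bi_cfg or BiSimConfig(n_tracks=30),
                                    s + 1, render_movie=False)
        out.append((su.kymograph.astype(np.float32), 0))
        out.append((sb.kymograph.astype(np.float32), 1))
    return out


# ---------------------------------------------------------------------------
# decision training set
# ---------------------------------------------------------------------------

def crop_at(img: np.ndarray, center: tuple[int, int],
            anchor: tuple[int, int] = ANCHOR, size: int = CROP) -> np.ndarray:
    """Size x size crop with ``center`` placed at ``anchor``; zero padded
    at the image borders."""
    out = np.zeros((size, size), img.dtype)
    r0 = center[0] - anchor[0]
    c0 = center[1] - anchor[1]
    rs, re = max(r0, 0), min(r0 + size, img.shape[0])
    cs, ce = max(c0, 0), min(c0 + size, img.shape[1])
    out[rs - r0:re - r0, cs - c0:ce - c0] = img[rs:re, cs:ce]
    return out


def find_branch_points(skel: np.ndarray) -> np.ndarray:
    """(n, 2) array of skeleton pixels with more than two neighbours."""
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    counts = ndi.convolve(skel.astype(int), kernel, mode="constant")
    return np.argwhere(skel & (counts > 2))


def make_decision_training_set(kymograph: np.ndarray, gt_tracks,
                               branch_tol: int = 3):
    """Emit (inputs (3, 48, 48), target (48, 48)) pairs, one per
    (branch point, incoming segment) pair on the combined skeleton."""
    shape = kymograph.shape
    chains = [track_chain(t) for t in gt_tracks]
    union = np.zeros(shape, bool)
    for ch in chains:
        union |= _chain_image(ch, shape)
    union = _thin(union)
    branch_pts = find_branch_points(union)
    if len(branch_pts) == 0:
        return []
    norm_kymo = normalize_image(kymograph)
    union_f = union.astype(np.float32)
    samples = []
    for ch in chains:
        # chain indices passing near a branch point (Chebyshev distance <=1)
        near = np.zeros(len(ch), bool)
        for bp in branch_pts:
            near |= np.abs(ch - bp).max(axis=1) <= 1
        # contiguous runs of near-indices -> one cut per encounter
        cuts = []
        i = 0
        while i < len(near):
            if near[i]:
                j = i
                while j < len(near) and near[j]:
                    j += 1
                cuts.append((i + j - 1) // 2)
                i = j
            else:
                i += 1
        bounds = [0] + cuts + [len(ch) - 1]
        for k, cut in enumerate(cuts):
            if cut <= bounds[k] or cut >= len(ch) - 1:
                continue  # need both an upstream and a downstream part
            end = tuple(ch[cut])
            upstream = ch[bounds[k]:cut + 1]
            downstream = ch[cut + 1:bounds[k + 2] + 1]
            if len(downstream) == 0:
                continue
            up_img = _chain_image(upstream, shape).astype(np.float32)
            down_img = _chain_image(downstream, shape).astype(np.float32)
            inputs = np.stack([
                crop_at(norm_kymo, end),
                crop_at(union_f, end),
                crop_at(up_img, end),
            ])
            samples.append((inputs, crop_at(down_img, end)))
    return samples


def make_decision_dataset(n_movies: int, seed: int,
                          bi_cfg: BiSimConfig | None = None):
    """Decision samples pooled over ``n_movies`` bidirectional training
    movies (30 tracks each)."""
    out = []
    for i in range(n_movies):
        cfg = bi_cfg or BiSimConfig(n_tracks=30)
        sample = simulate_bidirectional(cfg, seed * 300007 + i,
                                        render_movie=False)
        out.extend(make_decision_training_set(sample.kymograph,
                                              sample.tracks))
    return out
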