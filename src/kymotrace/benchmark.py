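"""Track-level benchmarking metrics.

Scores a set of predicted tracks against simulator ground truth with
deliberately strict, track-wise (not pixel-wise) metrics:

* **track recall** — for each ground-truth track, the best *single*
  predicted track is found and the fraction of ground-truth points it
  covers (within a spatial tolerance) is the recall.  A track predicted as
  two fragments therefore loses up to half its recall even if every pixel
  is segmented.
* **track precision** — symmetric: for each prediction, the fraction of
  its points covered by the best single ground-truth track.
* **track F1** — geometric mean of the per-kymograph average recall and
  average precision.
* **gap score** — fraction of artificial signal gaps bridged: a gap is
  resolved only if every invisible frame has a predicted point nearby.
* **crossing score** — fraction of ground-truth crossing segments (where
  two tracks intersect) covered >= 70% by a single prediction, computed on
  rasterized track images with dilated crossing disks.

The default matching tolerance of 3.2 px (two diagonal pixels, Euclidean
in the frame/position plane) absorbs the small deviations introduced by
skeletonization and row averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .simgen import GroundTruthTrack, SyntheticSample
from .tracks import Track

__all__ = [
    "track_recall", "track_precision", "track_f1",
    "gap_score", "crossing_score",
    "BenchmarkReport", "benchmark_sample", "benchmark_set",
    "DEFAULT_TOL",
]

DEFAULT_TOL = 3.2       # px, Euclidean; "two diagonal pixels"
GAP_TOL = 3.0           # px, per gap frame
CROSSING_DILATION_RADIUS = 16
CROSSING_COVER_FRACTION = 0.70


def _as_points(track) -> np.ndarray:
    """(n, 2) float array of (frame, position) for either track type."""
    if isinstance(track, GroundTruthTrack):
        return np.column_stack([track.frames.astype(float), track.positions])
    return np.column_stack([np.asarray(track.frames, float),
                            np.asarray(track.positions, float)])


def _coverage_fraction(pts_a: np.ndarray, pts_b: np.ndarray,
                       tol: float) -> float:
    """Fraction of points in A that have a point of B within Euclidean
    distance tol (frame axis counts as one pixel per frame)."""
    if len(pts_a) == 0:
        return 0.0
    if len(pts_b) == 0:
        return 0.0
    d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(-1)
    return float((d2.min(axis=1) <= tol * tol).mean())


def track_recall(gt_tracks: Sequence, pred_tracks: Sequence,
                 tol: float = DEFAULT_TOL) -> np.ndarray:
    """Per-ground-truth-track recall: max over single predictions of the
    fraction of ground-truth points covered within ``tol``."""
    gt_pts = [_as_points(t) for t in gt_tracks]
    pr_pts = [_as_points(t) for t in pred_tracks]
    out = np.zeros(len(gt_pts))
    for i, g in enumerate(gt_pts):
        out[i] = max((_coverage_fraction(g, p, tol) for p in pr_pts),
                     default=0.0)
    return out


def track_precision(gt_tracks: Sequence, pred_tracks: Sequence,
                    tol: float = DEFAULT_TOL) -> np.ndarray:
    """Per-prediction precision: fraction of the prediction covered by its
    best-overlapping single ground-truth track."""
    gt_pts = [_as_points(t) for t in gt_tracks]
    pr_pts = [_as_points(t) for t in pred_tracks]
    out = np.zeros(len(pr_pts))
    for i, p in enumerate(pr_pts):
        out[i] = max((_coverage_fraction(p, g, tol) for g in gt_pts),
                     default=0.0)
    return out


def track_f1(mean_recall: float, mean_precision: float) -> float:
    """Geometric mean of average track recall and average track precision."""
    return float(np.sqrt(mean_recall * mean_precision))


def gap_score(tracks: Sequence[GroundTruthTrack], pred_tracks: Sequence,
              tol: float = GAP_TOL) -> Optional[float]:
    """Fraction of ground-truth gaps resolved by the predictions.

    A gap is resolved iff every invisible frame of the gap has some
    predicted point within ``tol`` (Euclidean) of the ground-truth
    position at that frame.  Returns None when there are no gaps.
    """
    pr_pts = [_as_points(t) for t in pred_tracks]
    all_pred = (np.concatenate(pr_pts, axis=0) if pr_pts
                else np.zeros((0, 2)))
    n_gaps = 0
    n_resolved = 0
    for t in tracks:
        for (i0, i1) in t.gap_runs():
            n_gaps += 1
            gap_pts = np.column_stack([t.frames[i0:i1].astype(float),
                                       t.positions[i0:i1]])
            if len(all_pred) == 0:
                continue
            d2 = ((gap_pts[:, None, :] - all_pred[None, :, :]) ** 2).sum(-1)
            if (d2.min(axis=1) <= tol * tol).all():
                n_resolved += 1
    if n_gaps == 0:
        return None
    return n_resolved / n_gaps


# ---------------------------------------------------------------------------
# crossings (raster based)
# ---------------------------------------------------------------------------

def rasterize_track(track, shape: tuple[int, int]) -> np.ndarray:
    """Binary image of a track: rounded points joined by digital lines."""
    img = np.zeros(shape, bool)
    pts = _as_points(track)
    r = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
    c = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
    for k in range(len(r) - 1):
        rr, cc = draw_line(r[k], c[k], r[k + 1], c[k + 1])
        img[rr, cc] = True
    img[r, c] = True
    return img


def crossing_score(gt_tracks: Sequence, pred_tracks: Sequence,
                   shape: tuple[int, int],
                   dilation_radius: int = CROSSING_DILATION_RADIUS,
                   cover_fraction: float = CROSSING_COVER_FRACTION,
                   ) -> Optional[float]:
    """Fraction of crossing segments resolved by single predictions.

    Ground-truth tracks are rasterized; pairwise intersections give
    crossing dots, dilated to disks of ``dilation_radius``.  Each disk
    intersected with one track image yields that track's *cross segment*.
    A cross segment counts as resolved iff some single predicted track
    (dilated once with a 3x3 element) covers at least ``cover_fraction``
    of it.  Returns None when the ground truth has no crossings.
    """
    gt_imgs = [rasterize_track(t, shape) for t in gt_tracks]
    selem = disk(dilation_radius)
    pred_imgs = [binary_dilation(rasterize_track(t, shape),
                                 np.ones((3, 3), bool))
                 for t in pred_tracks]
    n_segments = 0
    n_resolved = 0
    for i in range(len(gt_imgs)):
        for j in range(i + 1, len(gt_imgs)):
            dots = gt_imgs[i] & gt_imgs[j]
            if not dots.any():
                continue
            circles = binary_dilation(dots, selem)
            for img in (gt_imgs[i], gt_imgs[j]):
                segment = circles & img
                seg_n = int(segment.sum())
                if seg_n == 0:
                    continue
                n_segments += 1
                for pimg in pred_imgs:
                    if (segment & pimg).sum() >= cover_fraction * seg_n:
                        n_resolved += 1
                        break
    if n_segments == 0:
        return None
    return n_resolved / n_segments


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-kymograph scores plus set-level medians."""

    recall: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    gap: list[Optional[float]] = field(default_factory=list)
    crossing: list[Optional[float]] = field(default_factory=list)

    @staticmethod
    def _median(values) -> Optional[float]:
        vals = [v for v in values if v is not None]
        return float(np.median(vals)) if vals else None

    @property
    def median_f1(self): return self._median(self.f1)

    @property
    def median_gap(self): return self._median(self.gap)

    @property
    def median_crossing(self): return self._median(self.crossing)

    def to_dict(self) -> dict:
        return {
            "per_kymograph": {
                "recall": self.recall, "precision": self.precision,
                "f1": self.f1, "gap": self.gap, "crossing": self.crossing,
            },
            "median_f1": self.median_f1,
            "median_gap": self.median_gap,
            "median_crossing": self.median_crossing,
        }


def prefilter_tracks(tracks: Sequence, min_frames: int = 3,
                     min_px: int = 3) -> list:
    """Shared quantification pre-filter: drop tracks spanning fewer than
    ``min_frames`` frames or shorter than ``min_px`` points."""
    out = []
    for t in tracks:
        pts = _as_points(t)
        if len(pts) < min_px:
            continue
        if pts[:, 0].max() - pts[:, 0].min() + 1 < min_frames:
            continue
        out.append(t)
    return out


def benchmark_sample(sample: SyntheticSample, pred_tracks: Sequence,
                     tol: float = DEFAULT_TOL) -> dict:
    """Score one kymograph's predictions against its ground truth."""
    gt = prefilter_tracks(sample.tracks)
    pred = prefilter_tracks(pred_tracks)
    rec = track_recall(gt, pred, tol)
    prec = track_precision(gt, pred, tol)
    mean_rec = float(rec.mean()) if len(rec) else 0.0
    mean_prec = float(prec.mean()) if len(prec) else 0.0
    return {
        "recall": mean_rec,
        "precision": mean_prec,
        "f1": track_f1(mean_rec, mean_prec),
        "gap": gap_score(gt, pred),
        "crossing": crossing_score(gt, pred, sample.kymograph.shape),
    }


def benchmark_set(samples: Sequence[SyntheticSample],
                  engine: Callable[[SyntheticSample], Sequence],
                  tol: float = DEFAULT_TOL) -> BenchmarkReport:
    """Run ``engine`` (sample -> predicted tracks) on every sample and
    aggregate the per-kymograph scores."""
    report = BenchmarkReport()
    for sample in samples:
        scores = benchmark_sample(sample, engine(sample), tol)
        report.recall.append(scores["recall"])
        report.precision.append(scores["precision"])
        report.f1.append(scores["f1"])
        report.gap.append(scores["gap"])
        report.crossing.append(scores["crossing"])
    return report
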