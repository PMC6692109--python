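"""Image and track I/O, and kymograph extraction from movies.

A kymograph is built by sampling, for every movie frame, the intensity
profile along a fixed polyline path at unit arc-length steps, and
stacking the profiles into image rows (row = frame, column = position
along the path).  Intensities across the transverse ``width`` of the
path are aggregated by maximum (default; robust to transverse particle
jitter) or mean.

Outputs per traced kymograph: a coordinates CSV (track_id, frame,
position — fractional positions preserved), a kinematic summary CSV,
and a colour overlay raster in which each track is drawn in a distinct
colour and dilated once (3x3) for visibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.ndimage import map_coordinates

from .kinematics import summary_frame
from .tracks import Track

__all__ = ["Kymograph", "PathSpec", "extract_kymograph", "write_outputs",
           "write_tracks_csv", "read_tracks_csv", "render_overlay",
           "save_movie_tiff", "load_movie_tiff", "GeometryError"]


class GeometryError(ValueError):
    """Raised when an extraction path leaves the movie bounds."""


@dataclass
class Kymograph:
    pixels: np.ndarray                 # (frames, path positions)
    frame_interval: float | None = None   # s
    pixel_size: float | None = None       # um

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class PathSpec:
    """Polyline path in movie-frame coordinates with transverse width."""

    polyline: list[tuple[float, float]]    # (row, col) control points
    width: int = 1

    def validate(self):
        if len(self.polyline) < 2:
            raise ValueError("path needs at least 2 control points")
        if self.width < 1:
            raise ValueError("width must be >= 1")


def _sample_path(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points at unit arc-length steps along the polyline and the local
    unit normals."""
    pts = np.asarray(polyline, float)
    segs = np.diff(pts, axis=0)
    seg_len = np.hypot(segs[:, 0], segs[:, 1])
    total = seg_len.sum()
    s = np.arange(0.0, total + 1e-9, 1.0)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rows = np.interp(s, cum, pts[:, 0])
    cols = np.interp(s, cum, pts[:, 1])
    # tangents via central differences -> normals
    dr = np.gradient(rows)
    dc = np.gradient(cols)
    norm = np.hypot(dr, dc)
    norm[norm == 0] = 1.0
    normals = np.stack([-dc / norm, dr / norm], axis=1)
    return np.stack([rows, cols], axis=1), normals


def extract_kymograph(movie: np.ndarray, path: PathSpec,
                      aggregator: str = "max") -> Kymograph:
    """Sample the movie along the path for every frame.

    ``movie`` is (frames, rows, cols).  For each arc-length step the
    intensities at ``width`` transverse offsets are aggregated by
    ``max`` or ``mean``; linear interpolation is used off-grid.
    """
    path.validate()
    if aggregator not in ("max", "mean"):
        raise ValueError("aggregator must be 'max' or 'mean'")
    centers, normals = _sample_path(np.asarray(path.polyline))
    offsets = np.arange(path.width, dtype=float) - (path.width - 1) / 2.0
    # sample positions: (n_offsets, n_steps, 2)
    pos = centers[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    H, W = movie.shape[1:]
    if (pos[..., 0].min() < -0.5 or pos[..., 0].max() > H - 0.5
            or pos[..., 1].min() < -0.5 or pos[..., 1].max() > W - 0.5):
        raise GeometryError("path (with width) leaves the movie bounds")
    n_frames = movie.shape[0]
    out = np.empty((n_frames, pos.shape[1]))
    coords = pos.reshape(-1, 2).T      # (2, n_offsets * n_steps)
    for f in range(n_frames):
        vals = map_coordinates(movie[f], coords, order=1, mode="nearest")
        vals = vals.reshape(path.width, -1)
        out[f] = vals.max(axis=0) if aggregator == "max" else vals.mean(axis=0)
    return Kymograph(pixels=out)


# ---------------------------------------------------------------------------
# track CSV round trip
# ---------------------------------------------------------------------------

def write_tracks_csv(tracks: Sequence[Track], path) -> None:
    rows = [{"track_id": t.id, "frame": int(f), "position": float(p)}
            for t in tracks for f, p in zip(t.frames, t.positions)]
    pd.DataFrame(rows, columns=["track_id", "frame", "position"]) \
        .to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(Track(id=int(tid),
                            frames=grp["frame"].to_numpy(int),
                            positions=grp["position"].to_numpy(float)))
    return tracks


# ---------------------------------------------------------------------------
# overlay and movie I/O
# ---------------------------------------------------------------------------

def render_overlay(tracks: Sequence[Track], shape: tuple[int, int],
                   color_seed: int = 0) -> np.ndarray:
    """RGB uint8 overlay: each track in a distinct colour, dilated once
    with a 3x3 element for visibility; deterministic given the seed."""
    from .benchmark import rasterize_track

    rng = np.random.default_rng(color_seed)
    out = np.zeros((*shape, 3), np.uint8)
    for t in tracks:
        color = rng.integers(64, 256, 3)
        img = ndi.binary_dilation(rasterize_track(t, shape),
                                  np.ones((3, 3), bool))
        out[img] = color
    return out


def save_movie_tiff(movie: np.ndarray, path, dtype: str = "float32") -> None:
    """Multi-page TIFF; 32-bit float or 16-bit integer (rescaled)."""
    if dtype == "float32":
        tifffile.imwrite(path, movie.astype(np.float32))
    elif dtype == "uint16":
        m = np.asarray(movie, float)
        hi = m.max() if m.max() > 0 else 1.0
        tifffile.imwrite(path, (m / hi * 65535).astype(np.uint16))
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")


def load_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_outputs(tracks: Sequence[Track], kymograph: np.ndarray, out_dir,
                  mode: str = "bi", color_seed: int = 0,
                  manifest: dict | None = None) -> dict:
    """Write the full per-kymograph output set.

    Returns a dict of the written paths: ``tracks`` CSV, ``summary``
    CSV (kinematics), ``overlay`` PNG, and optionally a JSON
    ``manifest``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["tracks"] = out_dir / "tracks.csv"
    write_tracks_csv(tracks, paths["tracks"])
    paths["summary"] = out_dir / "summary.csv"
    summary_frame(tracks, mode).to_csv(paths["summary"], index=False)
    paths["overlay"] = out_dir / "overlay.png"
    overlay = render_overlay(tracks, kymograph.shape, color_seed)
    iio.imwrite(paths["overlay"], overlay)
    if manifest is not None:
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2,
                                                default=str))
    return paths
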