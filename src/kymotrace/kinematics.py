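"""Derived per-track and per-kymograph transport quantities.

For each assembled track the summary reports the mean frame-to-frame
speed (px/frame), the total path length travelled (sum of absolute
frame-to-frame displacements, px), the travel time (frames visible), a
directionality score, the pause count, and whether the track reverses.

Directionality is regime dependent.  Unidirectional tracks take the
sign of the end-to-end displacement.  Bidirectional tracks are cut into
contiguous, non-overlapping segments of up to five frames; a segment
scores +1 when all its displacements are positive, -1 when all are
negative, and 0 otherwise, and the track's directionality is the sign
of the summed segment scores.  Pause time counts zero-displacement
segments; a track is *reversing* when it has segments of both signs.
Because consolidated positions are fractional (row averaging), "zero
displacement" uses a configurable tolerance (default 0.5 px/frame).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrackSummary", "summarize_track", "summarize_kymograph",
           "summary_frame", "SEGMENT_LEN", "PAUSE_TOL"]

SEGMENT_LEN = 5       # frames per directionality segment (bidirectional)
PAUSE_TOL = 0.5       # px/frame below which a displacement counts as zero


@dataclass
class TrackSummary:
    track_id: int
    mean_speed: float           # px/frame, mean |frame-to-frame displacement|
    total_displacement: float   # px, sum of |displacements|
    travel_time: int            # frames visible
    directionality: int         # -1, 0, +1
    pause_time: int             # number of zero-displacement segments
    reversing: bool


def _segment_scores(disp: np.ndarray, pause_tol: float) -> list[int]:
    scores = []
    for k in range(0, len(disp), SEGMENT_LEN):
        seg = disp[k:k + SEGMENT_LEN]
        if np.all(seg > pause_tol):
            scores.append(1)
        elif np.all(seg < -pause_tol):
            scores.append(-1)
        else:
            scores.append(0)
    return scores


def summarize_track(track, mode: str = "bi",
                    pause_tol: float = PAUSE_TOL) -> TrackSummary:
    """Kinematic summary of one track (``mode``: ``"uni"`` or ``"bi"``)."""
    pos = np.asarray(track.positions, float)
    frames = np.asarray(track.frames)
    tid = getattr(track, "id", -1)
    if len(pos) < 2:
        return TrackSummary(tid, 0.0, 0.0, max(len(pos), 1), 0, 0, False)
    disp = np.diff(pos)
    mean_speed = float(np.abs(disp).mean())
    total = float(np.abs(disp).sum())
    travel_time = int(frames[-1] - frames[0] + 1)
    if mode == "uni":
        end_to_end = pos[-1] - pos[0]
        direction = int(np.sign(end_to_end)) if abs(end_to_end) > 0 else 0
        return TrackSummary(tid, mean_speed, total, travel_time,
                            direction, 0, False)
    scores = _segment_scores(disp, pause_tol)
    ssum = sum(scores)
    direction = int(np.sign(ssum))
    # pause segments: all displacements ~0 (distinct from mixed-sign 0 score)
    pause = 0
    for k in range(0, len(disp), SEGMENT_LEN):
        seg = disp[k:k + SEGMENT_LEN]
        if np.all(np.abs(seg) <= pause_tol):
            pause += 1
    reversing = (1 in scores) and (-1 in scores)
    return TrackSummary(tid, mean_speed, total, travel_time, direction,
                        pause, reversing)


def summarize_kymograph(tracks: Sequence, mode: str = "bi",
                        pause_tol: float = PAUSE_TOL) -> dict:
    """Per-kymograph averages of the per-track quantities, the reversal
    percentage (tracks with segments in both directions), and the
    particle count."""
    summaries = [summarize_track(t, mode, pause_tol) for t in tracks]
    n = len(summaries)
    if n == 0:
        return {"n_tracks": 0, "mean_speed": None,
                "mean_total_displacement": None, "mean_travel_time": None,
                "mean_directionality": None, "mean_pause_time": None,
                "reversing_percent": None}
    return {
        "n_tracks": n,
        "mean_speed": float(np.mean([s.mean_speed for s in summaries])),
        "mean_total_displacement":
            float(np.mean([s.total_displacement for s in summaries])),
        "mean_travel_time":
            float(np.mean([s.travel_time for s in summaries])),
        "mean_directionality":
            float(np.mean([s.directionality for s in summaries])),
        "mean_pause_time":
            float(np.mean([s.pause_time for s in summaries])),
        "reversing_percent":
            100.0 * sum(s.reversing for s in summaries) / n,
    }


def summary_frame(tracks: Sequence, mode: str = "bi",
                  pause_tol: float = PAUSE_TOL) -> pd.DataFrame:
    """One row per track plus an ``aggregate`` row of the per-kymograph
    means (the contents of the summary CSV)."""
    rows = []
    for t in tracks:
        s = summarize_track(t, mode, pause_tol)
        rows.append({
            "track_id": s.track_id, "mean_speed": s.mean_speed,
            "total_displacement": s.total_displacement,
            "travel_time": s.travel_time,
            "directionality": s.directionality,
            "pause_time": s.pause_time, "reversing": s.reversing,
        })
    df = pd.DataFrame(rows, columns=["track_id", "mean_speed",
                                     "total_displacement", "travel_time",
                                     "directionality", "pause_time",
                                     "reversing"])
    agg = summarize_kymograph(tracks, mode, pause_tol)
    if agg["n_tracks"]:
        df.loc[len(df)] = {
            "track_id": "aggregate", "mean_speed": agg["mean_speed"],
            "total_displacement": agg["mean_total_displacement"],
            "travel_time": agg["mean_travel_time"],
            "directionality": agg["mean_directionality"],
            "pause_time": agg["mean_pause_time"],
            "reversing": agg["reversing_percent"],
        }
    return df
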