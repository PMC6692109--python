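"""Shared track containers used by the tracer, I/O and benchmarking."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["RawTrack", "Track"]


@dataclass
class RawTrack:
    """A traced skeleton pixel chain before row consolidation.

    ``pixels`` is the ordered list of (row, col) skeleton pixels visited
    while following a seed; rows are non-decreasing along the chain.
    ``decision_confidences`` holds the mean predicted trackness of each
    continuation chosen at a branch point.
    """

    pixels: list[tuple[int, int]] = field(default_factory=list)
    decision_confidences: list[float] = field(default_factory=list)

    @property
    def mean_confidence(self) -> float:
        if not self.decision_confidences:
            return 1.0  # no contested pixels
        return float(np.mean(self.decision_confidences))

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class Track:
    """An assembled trajectory with at most one (fractional) position per
    frame; frames strictly increasing."""

    id: int
    frames: np.ndarray         # (n,) int
    positions: np.ndarray      # (n,) float
    mean_confidence: float = 1.0

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self):
        return list(zip(self.frames.tolist(), self.positions.tolist()))


def raw_to_track(raw: RawTrack, track_id: int) -> Optional[Track]:
    """Average same-row pixels so the track has one position per frame."""
    if not raw.pixels:
        return None
    px = np.asarray(raw.pixels)
    rows = np.unique(px[:, 0])
    positions = np.array([px[px[:, 0] == r, 1].mean() for r in rows],
                         dtype=float)
    return Track(id=track_id, frames=rows.astype(int), positions=positions,
                 mean_confidence=raw.mean_confidence)
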