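"""Turn per-pixel trackness maps into individual particle tracks.

The bidirectional tracing algorithm:

1. binarize the trackness map (default threshold 0.2 — the pipeline's one
   free parameter; useful range ~0.1–0.3 depending on SNR),
2. thin iteratively to a 1-px skeleton and prune spur branches < 3 px,
3. trim line ends so every track end has its neighbours in a different
   row (time) — required for seed detection,
4. find track starting points ("seeds") with a hit-miss transform whose
   kernel demands an empty previous row,
5. follow each seed forward pixel by pixel; when more than one
   continuation is possible, ask a pluggable *decision* predictor for the
   most likely future path and record its mean trackness as confidence,
6. re-seed on the skeleton minus all found paths until no seeds remain,
7. consolidate: average same-row pixels, drop subset/short tracks, and
   assign long overlaps to the most confident track.

Unidirectional kymographs bypass steps 3–6: the two slope-separated
trackness maps contain no crossings, so connected components of the
pruned skeleton are already individual tracks.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin as _skimage_thin

from .tracks import RawTrack, Track, raw_to_track

__all__ = [
    "binarize", "thin_prune", "trim_ends", "find_seeds",
    "follow_track", "trace_skeleton", "consolidate", "link_gaps",
    "extract_unidirectional_tracks", "run_pipeline",
    "make_oracle_decider", "DecisionResult",
]

DEFAULT_THRESHOLD = 0.2
MIN_BRANCH = 3
MIN_COMPONENT_APPEND = 3   # decision components appended "if longer than 2 px"
MIN_TRACK_PX = 5
OVERLAP_ASSIGN_LEN = 10

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def binarize(trackness: np.ndarray, threshold: float = DEFAULT_THRESHOLD
             ) -> np.ndarray:
    """Pixel on iff trackness >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(trackness) >= threshold


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    return ndi.convolve(skel.astype(int), kernel, mode="constant")


def prune_spurs(skel: np.ndarray, min_branch: int = MIN_BRANCH) -> np.ndarray:
    """Remove spur branches shorter than ``min_branch`` pixels.

    A spur is walked from an endpoint (exactly one neighbour) towards the
    skeleton; if a junction (>2 neighbours) is reached in fewer than
    ``min_branch`` steps, the walked pixels are deleted.  Isolated short
    components are also removed.
    """
    skel = skel.copy().astype(bool)
    changed = True
    while changed:
        changed = False
        counts = _neighbor_count(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        for r0, c0 in endpoints:
            if not skel[r0, c0]:
                continue
            path = [(int(r0), int(c0))]
            prev = None
            cur = (int(r0), int(c0))
            hit_junction = False
            while len(path) < min_branch:
                nbrs = [(cur[0] + dr, cur[1] + dc) for dr, dc in _N8
                        if 0 <= cur[0] + dr < skel.shape[0]
                        and 0 <= cur[1] + dc < skel.shape[1]
                        and skel[cur[0] + dr, cur[1] + dc]
                        and (cur[0] + dr, cur[1] + dc) != prev]
                if len(nbrs) == 0:
                    break
                if len(nbrs) > 1 or counts[nbrs[0]] > 2:
                    hit_junction = True
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if hit_junction and len(path) < min_branch:
                for r, c in path:
                    skel[r, c] = False
                changed = True
    # drop isolated components shorter than min_branch
    lbl, n = ndi.label(skel, structure=np.ones((3, 3), int))
    if n:
        sizes = ndi.sum_labels(skel, lbl, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_branch) + 1
        if len(small):
            skel[np.isin(lbl, small)] = False
    return skel


def _break_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove one pixel from every residual 2x2 block.

    Library thinning can leave 2x2 blocks on very dense masks; the walk
    logic assumes a strictly 1-px skeleton.  The block pixel with the
    fewest neighbours is the most redundant one (usually it only touches
    the block itself), so it is removed first.
    """
    skel = skel.copy()
    while True:
        blocks = (skel[:-1, :-1] & skel[1:, :-1]
                  & skel[:-1, 1:] & skel[1:, 1:])
        if not blocks.any():
            return skel
        counts = _neighbor_count(skel)
        for r, c in np.argwhere(blocks):
            quad = [(r, c), (r + 1, c), (r, c + 1), (r + 1, c + 1)]
            if all(skel[q] for q in quad):
                skel[min(quad, key=lambda q: (counts[q], q))] = False


def thin_prune(binary: np.ndarray, min_branch: int = MIN_BRANCH) -> np.ndarray:
    """Iterative morphological thinning to a 1-px skeleton, then spur
    pruning."""
    skel = _break_blocks(_skimage_thin(np.asarray(binary, bool)))
    return prune_spurs(skel, min_branch)


def trim_ends(skel: np.ndarray) -> np.ndarray:
    """Iteratively remove endpoint pixels whose only neighbours lie in the
    same row, so every remaining track end points into a different frame."""
    skel = skel.copy().astype(bool)
    while True:
        counts = _neighbor_count(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        removed = False
        for r, c in endpoints:
            nbrs = [(r + dr, c + dc) for dr, dc in _N8
                    if 0 <= r + dr < skel.shape[0]
                    and 0 <= c + dc < skel.shape[1]
                    and skel[r + dr, c + dc]]
            if nbrs and all(nr == r for nr, _ in nbrs):
                skel[r, c] = False
                removed = True
        if not removed:
            return skel


def find_seeds(skel: np.ndarray) -> list[tuple[int, int]]:
    """Track starting points via a 3x3 hit-miss transform: the centre pixel
    is on while the whole previous row and both same-row laterals are off;
    the next row is unconstrained."""
    hit = np.zeros((3, 3), int)
    hit[1, 1] = 1
    miss = np.array([[1, 1, 1],
                     [1, 0, 1],
                     [0, 0, 0]], int)
    out = ndi.binary_hit_or_miss(np.asarray(skel, bool),
                                 structure1=hit, structure2=miss)
    return [tuple(p) for p in np.argwhere(out)]


DecisionResult = tuple[Optional[list[tuple[int, int]]], float]
# (ordered component pixels or None for "no future path", confidence)


def _snap_to_skeleton(component, skel, visited):
    """Project a predicted continuation onto the skeleton.

    Predicted components (thinned network output or rounded oracle
    trajectories) can run up to one pixel off the thinned skeleton;
    walking must stay on skeleton pixels or it strands.  Each component
    pixel is kept if on the skeleton, otherwise replaced by an adjacent
    unvisited skeleton pixel when one exists; duplicates and visited
    pixels are dropped while preserving order.
    """
    offsets = [(0, 0), *_N8,
               *[(dr, dc) for dr in (-2, -1, 0, 1, 2)
                 for dc in (-2, -1, 0, 1, 2) if max(abs(dr), abs(dc)) == 2]]
    out = []
    seen = set()
    for p in component:
        q = None
        if (0 <= p[0] < skel.shape[0] and 0 <= p[1] < skel.shape[1]
                and skel[p]):
            q = p
        else:
            for dr, dc in offsets:
                cand = (p[0] + dr, p[1] + dc)
                if (0 <= cand[0] < skel.shape[0]
                        and 0 <= cand[1] < skel.shape[1]
                        and skel[cand] and cand not in visited
                        and cand not in seen):
                    q = cand
                    break
        if q is None or q in visited or q in seen:
            continue
        seen.add(q)
        out.append(q)
    return out


def follow_track(seed: tuple[int, int], skel: np.ndarray,
                 kymo: np.ndarray,
                 decide: Callable[[np.ndarray, np.ndarray, RawTrack],
                                  DecisionResult]) -> RawTrack:
    """Walk the skeleton forward from a seed.

    At each step the candidates are the unvisited 8-neighbours of the
    current pixel, restricted to same-or-later rows when any exist.  A
    single candidate is followed directly; multiple candidates invoke
    ``decide``, whose returned component is appended only if longer than
    2 pixels, with its mean trackness stored as a decision confidence.
    """
    track = RawTrack(pixels=[seed])
    visited = {seed}
    cur = seed
    junctions = _neighbor_count(skel.astype(bool)) >= 3
    while True:
        # time runs down the kymograph: a track never returns to an
        # earlier frame, so only same-or-later rows are candidates
        cands = []
        for dr, dc in _N8:
            if dr < 0:
                continue
            p = (cur[0] + dr, cur[1] + dc)
            if (0 <= p[0] < skel.shape[0] and 0 <= p[1] < skel.shape[1]
                    and skel[p] and p not in visited):
                cands.append(p)
        # a lone candidate away from any junction is followed directly;
        # everything else (branch, merge exit, dead end) is contested
        contested = (len(cands) != 1 or junctions[cur]
                     or junctions[cands[0]])
        if not contested:
            cur = cands[0]
            track.pixels.append(cur)
            visited.add(cur)
            continue
        failed = False
        try:
            component, confidence = decide(kymo, skel, track)
        except Exception:
            component, failed = None, True
        if component is not None:
            component = _snap_to_skeleton(component, skel, visited)
        if component is None or len(component) < MIN_COMPONENT_APPEND:
            if failed and len(cands) == 1:
                # a broken predictor should not truncate an uncontested path
                cur = cands[0]
                track.pixels.append(cur)
                visited.add(cur)
                continue
            return track   # no future path predicted: the track terminates
        track.decision_confidences.append(float(confidence))
        for p in component:
            track.pixels.append(p)
            visited.add(p)
        cur = track.pixels[-1]


def _chain_runs(pixels: Sequence[tuple[int, int]],
                member: set) -> list[list[tuple[int, int]]]:
    """Split a pixel chain into maximal runs whose pixels are in ``member``."""
    runs, cur = [], []
    for p in pixels:
        if p in member:
            cur.append(p)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def consolidate(raw_tracks: Sequence[RawTrack],
                rng: Optional[np.random.Generator] = None,
                min_track_px: int = MIN_TRACK_PX,
                overlap_len: int = OVERLAP_ASSIGN_LEN) -> list[Track]:
    """Resolve duplicates and overlaps, then average rows into tracks.

    Tracks that are strict pixel subsets of another track are deleted, as
    are tracks shorter than ``min_track_px`` pixels.  Overlapping runs
    longer than ``overlap_len`` pixels are assigned to the track with the
    highest mean decision confidence (ties, or confidence-free engines,
    fall back to a seeded random choice via ``rng``); the losing track is
    split at the removed run.  Applying consolidate twice is a no-op.
    """
    chains = [list(dict.fromkeys(rt.pixels)) for rt in raw_tracks]
    confs = [rt.mean_confidence for rt in raw_tracks]
    decision_counts = [len(rt.decision_confidences) for rt in raw_tracks]

    # subset rule
    sets = [set(ch) for ch in chains]
    keep = [True] * len(chains)
    order = sorted(range(len(chains)), key=lambda i: (-len(sets[i]), i))
    for ai, i in enumerate(order):
        if not keep[i]:
            continue
        for j in order[ai + 1:]:
            if keep[j] and sets[j] <= sets[i]:
                keep[j] = False
    chains = [c for c, k in zip(chains, keep) if k]
    confs = [c for c, k in zip(confs, keep) if k]
    decision_counts = [c for c, k in zip(decision_counts, keep) if k]

    # long-overlap assignment
    n = len(chains)
    removed: list[set] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            shared = (set(chains[i]) - removed[i]) & (set(chains[j]) - removed[j])
            if not shared:
                continue
            for run in _chain_runs(chains[i], shared):
                if len(run) <= overlap_len:
                    continue
                if confs[i] > confs[j]:
                    loser = j
                elif confs[j] > confs[i]:
                    loser = i
                elif rng is not None:
                    # confidence-free engines assign overlaps randomly
                    loser = int(rng.choice([i, j]))
                else:
                    continue  # equal confidence: neither track yields
                removed[loser].update(run)

    # the loser keeps its non-overlapping pixels as a single track (the
    # removed run leaves a hole, it does not split the track)
    out_chains: list[tuple[list, float]] = []
    for ch, rem, cf in zip(chains, removed, confs):
        piece = [p for p in ch if p not in rem]
        if len(piece) >= min_track_px:
            out_chains.append((piece, cf))

    tracks = []
    for tid, (piece, cf) in enumerate(out_chains):
        rt = RawTrack(pixels=piece)
        tr = raw_to_track(rt, tid)
        if tr is not None:
            tr.mean_confidence = cf
            tracks.append(tr)
    return tracks


def trace_skeleton(skel: np.ndarray, kymo: np.ndarray,
                   decide: Callable,
                   rng: Optional[np.random.Generator] = None,
                   max_reseed_iters: int = 20) -> list[Track]:
    """Full bidirectional tracing loop: trim, seed, follow, re-seed on the
    residual skeleton, and consolidate."""
    work = trim_ends(skel.astype(bool))
    raw_tracks: list[RawTrack] = []
    full = work.copy()

    def _run_pass(seeds) -> bool:
        found = False
        for seed in seeds:
            if not work[seed]:
                continue
            rt = follow_track(seed, full, kymo, decide)
            if len(rt) >= MIN_BRANCH:
                raw_tracks.append(rt)
                found = True
                for p in rt.pixels:
                    work[p] = False
        return found

    for _ in range(max_reseed_iters):
        seeds = find_seeds(work)
        if not seeds:
            break
        if not _run_pass(seeds):
            break
        work = trim_ends(work)
    # fallback: merged track starts (e.g. two particles appearing side by
    # side) thin into blobs whose apex sits in a horizontal run, which the
    # hit-miss kernel can never match; seed any sizeable unclaimed
    # component at its earliest pixel instead
    for _ in range(max_reseed_iters):
        lbl, n = ndi.label(work, structure=np.ones((3, 3), int))
        if n == 0:
            break
        seeds = []
        for k in range(1, n + 1):
            pix = np.argwhere(lbl == k)
            if len(pix) < MIN_TRACK_PX:
                continue
            top = pix[pix[:, 0] == pix[:, 0].min()]
            seeds.append(tuple(top[top[:, 1].argmin()]))
        if not seeds or not _run_pass(seeds):
            break
        work = trim_ends(work)
    return consolidate(raw_tracks, rng=rng)


def extract_unidirectional_tracks(pos_map: np.ndarray, neg_map: np.ndarray,
                                  threshold: float = DEFAULT_THRESHOLD,
                                  min_frames: int = 3, min_px: int = 3,
                                  link: bool = True) -> list[Track]:
    """Trace slope-separated unidirectional trackness maps.

    Each map is binarized, thinned and pruned independently; connected
    components become candidate tracks, filtered to at least
    ``min_frames`` frames and ``min_px`` skeleton pixels, then same-row
    pixels are averaged to one position per frame.  Fragments of the
    same line (gaps the segmentation failed to bridge) are re-linked by
    extrapolation per slope map when ``link`` is set.
    """
    tracks: list[Track] = []
    tid = 0
    for m in (pos_map, neg_map):
        skel = thin_prune(binarize(m, threshold))
        lbl, ncomp = ndi.label(skel, structure=np.ones((3, 3), int))
        map_tracks: list[Track] = []
        for k in range(1, ncomp + 1):
            pix = np.argwhere(lbl == k)
            if len(pix) < min_px:
                continue
            if pix[:, 0].max() - pix[:, 0].min() + 1 < min_frames:
                continue
            rt = RawTrack(pixels=[tuple(p) for p in pix])
            tr = raw_to_track(rt, 0)
            if tr is not None:
                map_tracks.append(tr)
        if link:
            map_tracks = link_gaps(map_tracks)
        for tr in map_tracks:
            tr.id = tid
            tracks.append(tr)
            tid += 1
    return tracks


# ---------------------------------------------------------------------------
# fragment linking
# ---------------------------------------------------------------------------

def link_gaps(tracks: Sequence[Track], max_frame_gap: int = 8,
              tol: float = 4.0, fit_len: int = 5) -> list[Track]:
    """Merge track fragments separated by short temporal gaps.

    Networks trained at reduced scale under-bridge signal gaps, leaving a
    particle's line as several collinear fragments.  Two fragments are
    linked when one starts 1–``max_frame_gap`` frames after the other
    ends and both extrapolations (the first track's terminal velocity
    carried forward, the second track's initial velocity carried
    backward, each a mean over up to ``fit_len`` displacements) land
    within ``tol`` px of the other fragment.  Links are accepted
    greedily by extrapolation error, each track end/start at most once,
    so chains of fragments merge into one track.  Missing frames are
    filled by linear interpolation, which is what bridges the gap for
    downstream analysis.  Deterministic.
    """
    tracks = list(tracks)
    n = len(tracks)

    def end_velocity(t):
        d = np.diff(np.asarray(t.positions, float))
        return float(d[-fit_len:].mean()) if len(d) else 0.0

    def start_velocity(t):
        d = np.diff(np.asarray(t.positions, float))
        return float(d[:fit_len].mean()) if len(d) else 0.0

    candidates = []
    for i in range(n):
        a = tracks[i]
        for j in range(n):
            if i == j:
                continue
            b = tracks[j]
            df = int(b.frames[0]) - int(a.frames[-1])
            if not (1 <= df <= max_frame_gap):
                continue
            err_f = abs(a.positions[-1] + end_velocity(a) * df
                        - b.positions[0])
            err_b = abs(b.positions[0] - start_velocity(b) * df
                        - a.positions[-1])
            if err_f <= tol and err_b <= tol:
                candidates.append((0.5 * (err_f + err_b), i, j))
    candidates.sort()

    nxt = [None] * n
    prv = [None] * n
    for _, i, j in candidates:
        if nxt[i] is not None or prv[j] is not None:
            continue
        # no cycles: walk j's chain forward and make sure it misses i
        k, cyclic = j, False
        while k is not None:
            if k == i:
                cyclic = True
                break
            k = nxt[k]
        if cyclic:
            continue
        nxt[i] = j
        prv[j] = i

    out = []
    for i in range(n):
        if prv[i] is not None:
            continue
        frames = list(tracks[i].frames)
        positions = list(tracks[i].positions)
        confs = [(tracks[i].mean_confidence, len(tracks[i].frames))]
        k = nxt[i]
        while k is not None:
            b = tracks[k]
            f0, p0 = frames[-1], positions[-1]
            for f in range(int(f0) + 1, int(b.frames[0])):
                w = (f - f0) / (b.frames[0] - f0)
                frames.append(f)
                positions.append(p0 + w * (b.positions[0] - p0))
            frames.extend(b.frames)
            positions.extend(b.positions)
            confs.append((b.mean_confidence, len(b.frames)))
            k = nxt[k]
        tr = Track(id=len(out), frames=np.asarray(frames, int),
                   positions=np.asarray(positions, float))
        total = sum(w for _, w in confs)
        tr.mean_confidence = sum(c * w for c, w in confs) / total
        out.append(tr)
    return out


# ---------------------------------------------------------------------------
# decision predictors
# ---------------------------------------------------------------------------

def make_oracle_decider(gt_tracks, max_step: int = 8) -> Callable:
    """Ground-truth continuation stub for testing the tracing engine.

    On the first branch point of a walk the current track is matched to
    the ground-truth trajectory whose pixel chain best fits the walked
    tail; that identity is then locked for the rest of the walk, and
    every decision returns the next few pixels of that same trajectory
    (confidence 1.0), progressing monotonically along the chain.
    """
    from .nets.data import track_chain  # ordered, line-joined chains

    chains = [track_chain(t) for t in gt_tracks]

    def decide(kymo, skel, current: RawTrack) -> DecisionResult:
        end = np.asarray(current.pixels[-1])
        state = getattr(current, "_oracle_state", None)
        if state is None:
            tail = np.asarray(current.pixels[-min(len(current.pixels), 15):])
            dists = np.array([
                np.mean([np.abs(ch - p).max(axis=1).min() for p in tail])
                for ch in chains])
            best_d = dists.min() if len(dists) else np.inf
            if best_d > 4.0:
                return None, 0.0
            # near-ties (co-running tracks): prefer the trajectory whose
            # start lies closest to where this walk was seeded
            start = np.asarray(current.pixels[0])
            candidates = np.flatnonzero(dists <= best_d + 1.5)
            best_i = int(min(candidates,
                             key=lambda i: np.abs(chains[i] - start)
                             .max(axis=1).min()))
            pos0 = int(np.argmin(
                np.abs(chains[best_i] - end).max(axis=1)))
            state = [best_i, pos0]
            current._oracle_state = state
        ci, pos = state
        ch = chains[ci]
        # advance monotonically: nearest chain pixel to the current end,
        # searched forward of the last matched position
        window = ch[pos:]
        if len(window) == 0:
            return None, 0.0
        idx = pos + int(np.argmin(np.abs(window - end).max(axis=1)))
        nxt = ch[idx + 1: idx + 1 + max_step]
        state[1] = idx
        if len(nxt) == 0:
            return None, 0.0
        return [tuple(map(int, p)) for p in nxt], 1.0

    return decide


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(kymo: np.ndarray, models, threshold: float = DEFAULT_THRESHOLD,
                 mode: str = "auto", min_frames: int = 3, min_px: int = 3,
                 rng: Optional[np.random.Generator] = None) -> list[Track]:
    """Classify, segment and trace one kymograph with trained networks.

    ``models`` is a :class:`kymotrace.nets.modules.ModelBundle`; ``mode``
    may be ``auto`` (classification module decides), ``uni`` or ``bi``.
    """
    from .nets.modules import decide_nn  # local import: nets is heavy

    if mode == "auto":
        mode = "uni" if models.classify(kymo) == 0 else "bi"
    if mode == "uni":
        pos_map, neg_map = models.segment_unidirectional(kymo)
        return extract_unidirectional_tracks(pos_map, neg_map, threshold,
                                             min_frames, min_px)
    if mode == "bi":
        trackness = models.segment_bidirectional(kymo)
        skel = thin_prune(binarize(trackness, threshold))

        def decide(k, s, current):
            return decide_nn(k, s, current, models.decision)

        return link_gaps(trace_skeleton(skel, kymo, decide, rng=rng))
    raise ValueError(f"unknown mode {mode!r}")
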