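import numpy as np
import pytest

from kymotrace.benchmark import (
    DEFAULT_TOL,
    benchmark_sample,
    crossing_score,
    gap_score,
    prefilter_tracks,
    rasterize_track,
    track_f1,
    track_precision,
    track_recall,
)
from kymotrace.simgen import GroundTruthTrack, SyntheticSample
from kymotrace.tracks import Track


def gt(tid, frames, positions, visible=None):
    frames = np.asarray(frames)
    positions = np.asarray(positions, float)
    if visible is None:
        visible = np.ones(len(frames), bool)
    return GroundTruthTrack(id=tid, frames=frames, positions=positions,
                            visible=np.asarray(visible, bool))


def pred(tid, frames, positions):
    return Track(id=tid, frames=np.asarray(frames),
                 positions=np.asarray(positions, float))


def test_recall_perfect_match():
    g = gt(0, range(10), np.linspace(0, 9, 10))
    p = pred(0, range(10), np.linspace(0, 9, 10))
    assert track_recall([g], [p])[0] == 1.0
    assert track_precision([g], [p])[0] == 1.0


def test_recall_single_best_prediction_not_union():
    # track predicted as two halves: best single fragment covers only half
    # (steep slope keeps the fragments outside each other's tolerance)
    g = gt(0, range(10), 4.0 * np.arange(10))
    p1 = pred(0, range(5), 4.0 * np.arange(5))
    p2 = pred(1, range(5, 10), 4.0 * np.arange(5, 10))
    assert track_recall([g], [p1, p2])[0] == pytest.approx(0.5)


def test_recall_no_predictions():
    g = gt(0, range(10), np.zeros(10))
    assert track_recall([g], [])[0] == 0.0
    assert len(track_precision([g], [])) == 0


def test_tolerance_boundary():
    g = gt(0, [0, 1, 2], [0.0, 0.0, 0.0])
    near = pred(0, [0, 1, 2], [DEFAULT_TOL - 0.01] * 3)
    far = pred(0, [0, 1, 2], [DEFAULT_TOL + 0.01] * 3)
    assert track_recall([g], [near])[0] == 1.0
    assert track_recall([g], [far])[0] == 0.0


def test_f1_geometric_mean():
    assert track_f1(1.0, 1.0) == 1.0
    assert track_f1(0.5, 0.5) == pytest.approx(0.5)
    assert track_f1(1.0, 0.25) == pytest.approx(0.5)
    assert track_f1(0.0, 1.0) == 0.0


def test_gap_score_resolved_and_missed():
    vis = np.ones(10, bool)
    vis[4:6] = False
    g = gt(0, range(10), 5.0 * np.arange(10), vis)
    full = pred(0, range(10), 5.0 * np.arange(10))
    holey = pred(0, [0, 1, 2, 3, 8, 9], [0.0, 5, 10, 15, 40, 45])
    assert gap_score([g], [full]) == 1.0
    assert gap_score([g], [holey]) == 0.0
    assert gap_score([g], []) == 0.0


def test_gap_score_none_without_gaps():
    g = gt(0, range(10), np.arange(10.0))
    assert gap_score([g], [pred(0, range(10), np.arange(10.0))]) is None


def test_gap_requires_every_gap_frame():
    vis = np.ones(10, bool)
    vis[3:7] = False
    g = gt(0, range(10), 5.0 * np.arange(10), vis)
    # prediction missing one interior gap frame (no point within the
    # tolerance of frame 5's ground-truth position) -> unresolved
    p = pred(0, [0, 1, 2, 3, 4, 6, 7, 8, 9],
             5.0 * np.array([0, 1, 2, 3, 4, 6, 7, 8, 9]))
    assert gap_score([g], [p]) == 0.0


def test_rasterize_track_connects_points():
    t = pred(0, [0, 4], [0.0, 4.0])
    img = rasterize_track(t, (5, 5))
    assert img[0, 0] and img[4, 4]
    assert img.sum() == 5  # digital diagonal


def test_crossing_score_cases():
    # odd size so the two digital diagonals share the centre pixel
    shape = (41, 41)
    g1 = gt(0, range(41), np.arange(41.0))
    g2 = gt(1, range(41), np.arange(40.0, -1.0, -1.0))
    # crossing resolved by two full predictions
    p1 = pred(0, range(41), np.arange(41.0))
    p2 = pred(1, range(41), np.arange(40.0, -1.0, -1.0))
    assert crossing_score([g1, g2], [p1, p2], shape) == 1.0
    # predictions that stop well before the crossing resolve nothing
    p3 = pred(0, range(10), np.arange(10.0))
    p4 = pred(1, range(10), np.arange(40.0, 30.0, -1.0))
    assert crossing_score([g1, g2], [p3, p4], shape) == 0.0
    # parallel tracks -> no crossings -> None
    g3 = gt(2, range(41), np.full(41, 5.0))
    g4 = gt(3, range(41), np.full(41, 20.0))
    assert crossing_score([g3, g4], [p1], shape) is None


def test_prefilter():
    short = pred(0, [0, 1], [0.0, 1.0])
    flat = pred(1, [0, 0, 0], [0.0, 1.0, 2.0])
    ok = pred(2, [0, 1, 2], [0.0, 1.0, 2.0])
    out = prefilter_tracks([short, flat, ok])
    assert [t.id for t in out] == [2]


def test_benchmark_sample_perfect():
    tracks = [gt(0, range(5, 25), np.linspace(5, 24, 20)),
              gt(1, range(30, 60), np.linspace(50, 21, 30))]
    sample = SyntheticSample(movie=None, kymograph=np.zeros((64, 64)),
                             tracks=tracks, seed=0, measured_snr=None,
                             noise_sigma=0.0)
    preds = [pred(t.id, t.frames, t.positions) for t in tracks]
    sc = benchmark_sample(sample, preds)
    assert sc["f1"] == 1.0
    assert sc["gap"] is None


# ---------------------------------------------------------------------------
# brute-force oracles on random instances (see also test_acceptance)
# ---------------------------------------------------------------------------

def brute_cover(a_pts, b_pts, tol):
    if not len(a_pts) or not len(b_pts):
        return 0.0
    hits = 0
    for (fa, pa) in a_pts:
        if any((fa - fb) ** 2 + (pa - pb) ** 2 <= tol * tol
               for (fb, pb) in b_pts):
            hits += 1
    return hits / len(a_pts)


def test_recall_matches_bruteforce_small():
    rng = np.random.default_rng(7)
    for _ in range(20):
        gts, prs = [], []
        for tid in range(rng.integers(1, 4)):
            n = int(rng.integers(3, 12))
            f0 = int(rng.integers(0, 20))
            gts.append(gt(tid, range(f0, f0 + n),
                          rng.uniform(0, 30, n)))
        for tid in range(rng.integers(0, 4)):
            n = int(rng.integers(3, 12))
            f0 = int(rng.integers(0, 20))
            prs.append(pred(tid, range(f0, f0 + n), rng.uniform(0, 30, n)))
        fast = track_recall(gts, prs)
        for i, g in enumerate(gts):
            slow = max((brute_cover(list(zip(g.frames, g.positions)),
                                    list(zip(p.frames, p.positions)),
                                    DEFAULT_TOL) for p in prs), default=0.0)
            assert fast[i] == pytest.approx(slow)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

def test_metrics_invariant_under_global_translation():
    rng = np.random.default_rng(5)
    for _ in range(10):
        n = int(rng.integers(6, 30))
        frames = np.arange(n)
        gts, preds = [], []
        for tid in range(3):
            pos = np.cumsum(rng.uniform(-2, 2, n)) + rng.uniform(10, 30)
            vis = rng.random(n) > 0.2
            vis[0] = vis[-1] = True
            gts.append(GroundTruthTrack(id=tid, frames=frames.copy(),
                                        positions=pos, visible=vis))
            preds.append(Track(id=tid, frames=frames.copy(),
                               positions=pos + rng.uniform(-2, 2, n)))
        dx = 7.0
        gts2 = [GroundTruthTrack(id=t.id, frames=t.frames,
                                 positions=t.positions + dx,
                                 visible=t.visible) for t in gts]
        preds2 = [Track(id=t.id, frames=t.frames,
                        positions=t.positions + dx) for t in preds]
        assert np.allclose(track_recall(gts, preds),
                           track_recall(gts2, preds2))
        assert np.allclose(track_precision(gts, preds),
                           track_precision(gts2, preds2))
        assert gap_score(gts, preds) == gap_score(gts2, preds2)


def test_merging_fragments_never_decreases_recall():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n = int(rng.integers(8, 40))
        frames = np.arange(n)
        pos = np.cumsum(rng.uniform(-2, 2, n)) + 25.0
        gt = GroundTruthTrack(id=0, frames=frames, positions=pos,
                              visible=np.ones(n, bool))
        h = n // 2
        frag_a = Track(id=0, frames=frames[:h].copy(),
                       positions=pos[:h] + rng.uniform(-2, 2, h))
        frag_b = Track(id=1, frames=frames[h:].copy(),
                       positions=pos[h:] + rng.uniform(-2, 2, n - h))
        merged = Track(id=2,
                       frames=np.concatenate([frag_a.frames, frag_b.frames]),
                       positions=np.concatenate([frag_a.positions,
                                                 frag_b.positions]))
        r_frag = track_recall([gt], [frag_a, frag_b])[0]
        r_merged = track_recall([gt], [merged])[0]
        assert r_merged >= r_frag - 1e-12
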