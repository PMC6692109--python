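import numpy as np
import pytest
from scipy import ndimage as ndi

from kymotrace.benchmark import benchmark_sample
from kymotrace.simgen import BiSimConfig, simulate_bidirectional
from kymotrace.tracer import (
    binarize,
    consolidate,
    extract_unidirectional_tracks,
    find_seeds,
    follow_track,
    link_gaps,
    make_oracle_decider,
    prune_spurs,
    thin_prune,
    trace_skeleton,
    trim_ends,
)
from kymotrace.tracks import RawTrack, Track, raw_to_track
from kymotrace.nets.data import render_tracks_binary


def img(shape, pts):
    out = np.zeros(shape, bool)
    for r, c in pts:
        out[r, c] = True
    return out


# ---------------------------------------------------------------------------
# binarize / thin / prune / trim
# ---------------------------------------------------------------------------

def test_binarize_threshold_inclusive():
    t = np.array([[0.1, 0.2, 0.3]])
    np.testing.assert_array_equal(binarize(t, 0.2), [[False, True, True]])


def test_binarize_rejects_bad_threshold():
    with pytest.raises(ValueError):
        binarize(np.zeros((2, 2)), 0.0)
    with pytest.raises(ValueError):
        binarize(np.zeros((2, 2)), 1.0)


def test_prune_spurs_removes_short_branch():
    # vertical line with a 2-px spur: the spur tip is walked back and
    # removed (the pixel touching the line counts as part of the junction
    # and may remain as a 1-px nub)
    line = [(r, 5) for r in range(10)]
    spur = [(4, 6), (4, 7)]
    skel = img((12, 12), line + spur)
    out = prune_spurs(skel)
    assert not out[4, 7]
    assert all(out[p] for p in line)


def test_prune_spurs_keeps_long_branch():
    line = [(r, 5) for r in range(10)]
    branch = [(4, 6), (5, 7), (6, 8), (7, 9)]
    skel = img((12, 12), line + branch)
    out = prune_spurs(skel)
    assert out.sum() == len(line) + len(branch)


def test_prune_drops_isolated_small_components():
    skel = img((10, 10), [(1, 1), (1, 2)])
    assert prune_spurs(skel).sum() == 0


def test_thin_prune_one_pixel_wide():
    # no 2x2 block of the skeleton is fully on
    s = simulate_bidirectional(BiSimConfig(), 0, render_movie=False)
    binary = render_tracks_binary(s.tracks, s.kymograph.shape)
    skel = thin_prune(binary)
    assert skel.any()
    blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    assert not blocks.any()


def test_prune_spurs_idempotent():
    s = simulate_bidirectional(BiSimConfig(), 0, render_movie=False)
    binary = render_tracks_binary(s.tracks, s.kymograph.shape)
    once = prune_spurs(thin_prune(binary))
    np.testing.assert_array_equal(once, prune_spurs(once))


def test_trim_ends_removes_horizontal_endpoints():
    # an L: the horizontal tail erodes until the remaining end has a
    # neighbour in a different row
    pts = [(0, 2), (1, 2), (2, 2), (2, 3), (2, 4), (2, 5)]
    out = trim_ends(img((5, 7), pts))
    assert not out[2, 5] and not out[2, 4]
    # (2, 3) survives: it touches (1, 2) diagonally, a different row
    assert out[2, 3]
    assert out[0, 2] and out[1, 2] and out[2, 2]


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def test_find_seeds_simple_lines():
    # two diagonal lines starting at rows 0 and 3
    a = [(r, r) for r in range(8)]
    b = [(r, 12 - (r - 3)) for r in range(3, 8)]
    skel = img((10, 16), a + b)
    seeds = set(find_seeds(skel))
    assert (0, 0) in seeds
    assert (3, 12) in seeds
    assert len(seeds) == 2


def test_find_seeds_matches_bruteforce():
    rng = np.random.default_rng(3)
    for _ in range(20):
        skel = rng.random((12, 12)) < 0.25
        seeds = set(find_seeds(skel))
        H, W = skel.shape
        for r in range(H):
            for c in range(W):
                if not skel[r, c]:
                    continue
                def off(rr, cc):
                    return not (0 <= rr < H and 0 <= cc < W) \
                        or not skel[rr, cc]
                expect = (off(r - 1, c - 1) and off(r - 1, c)
                          and off(r - 1, c + 1) and off(r, c - 1)
                          and off(r, c + 1))
                assert ((r, c) in seeds) == expect


# ---------------------------------------------------------------------------
# follow / consolidate
# ---------------------------------------------------------------------------

def test_follow_track_straight_line_no_decisions():
    pts = [(r, r) for r in range(10)]
    skel = img((12, 12), pts)
    calls = []

    def decide(k, s, cur):
        calls.append(1)
        return None, 0.0

    rt = follow_track((0, 0), skel, np.zeros(skel.shape), decide)
    assert rt.pixels[:10] == pts
    # only the dead end at the last pixel consults the decision predictor
    assert len(calls) == 1


def test_follow_track_never_goes_back_in_time():
    # V shape: down then up; walker must stop rather than climb back up
    down = [(r, r) for r in range(6)]
    up = [(10 - r, r) for r in range(6, 11)]
    skel = img((12, 12), down + up)
    rt = follow_track((0, 0), skel, np.zeros(skel.shape),
                      lambda k, s, c: (None, 0.0))
    rows = [p[0] for p in rt.pixels]
    assert all(b >= a for a, b in zip(rows, rows[1:]))


def test_consolidate_deletes_short_tracks():
    short = RawTrack(pixels=[(0, 0), (1, 1), (2, 2), (3, 3)])
    long = RawTrack(pixels=[(r, 10) for r in range(8)])
    out = consolidate([short, long])
    assert len(out) == 1
    assert len(out[0].frames) == 8


def test_consolidate_removes_subsets():
    full = RawTrack(pixels=[(r, r) for r in range(10)])
    sub = RawTrack(pixels=[(r, r) for r in range(2, 9)])
    out = consolidate([full, sub])
    assert len(out) == 1
    assert len(out[0].frames) == 10


def test_consolidate_assigns_long_overlap_to_confident_track():
    shared = [(r, 5) for r in range(12)]
    a = RawTrack(pixels=[(r, 4) for r in range(12, 18)] + shared,
                 decision_confidences=[0.9])
    b = RawTrack(pixels=[(r, 6) for r in range(12, 18)] + shared,
                 decision_confidences=[0.2])
    out = consolidate([a, b])
    by_len = sorted(out, key=lambda t: -len(t.frames))
    assert len(by_len[0].frames) == 18          # confident keeps overlap
    assert len(by_len[1].frames) == 6           # loser keeps the rest


def test_consolidate_short_overlap_untouched():
    shared = [(r, 5) for r in range(8)]          # 8 <= overlap threshold 10
    a = RawTrack(pixels=shared + [(r, 5 + r - 7) for r in range(8, 14)],
                 decision_confidences=[0.9])
    b = RawTrack(pixels=shared + [(r, 5 - r + 7) for r in range(8, 14)],
                 decision_confidences=[0.2])
    out = consolidate([a, b])
    assert sorted(len(t.frames) for t in out) == [14, 14]


def test_consolidate_random_assignment_is_seeded():
    shared = [(r, 5) for r in range(12)]
    def mk():
        return [RawTrack(pixels=shared + [(r, 6) for r in range(12, 18)]),
                RawTrack(pixels=shared + [(r, 4) for r in range(12, 18)])]
    out1 = consolidate(mk(), rng=np.random.default_rng(5))
    out2 = consolidate(mk(), rng=np.random.default_rng(5))
    assert [t.positions.tolist() for t in out1] \
        == [t.positions.tolist() for t in out2]


def test_consolidate_idempotent():
    shared = [(r, 5) for r in range(12)]
    a = RawTrack(pixels=[(r, 4) for r in range(12, 18)] + shared,
                 decision_confidences=[0.9])
    b = RawTrack(pixels=[(r, 6) for r in range(12, 18)] + shared,
                 decision_confidences=[0.2])
    once = consolidate([a, b])
    again = consolidate([RawTrack(pixels=[(int(f), int(round(p)))
                                          for f, p in zip(t.frames,
                                                          t.positions)])
                         for t in once])
    assert sorted(len(t.frames) for t in once) \
        == sorted(len(t.frames) for t in again)


def test_raw_to_track_averages_rows():
    rt = RawTrack(pixels=[(0, 3), (0, 5), (1, 4)])
    t = raw_to_track(rt, 0)
    np.testing.assert_array_equal(t.frames, [0, 1])
    np.testing.assert_allclose(t.positions, [4.0, 4.0])


# ---------------------------------------------------------------------------
# unidirectional extraction
# ---------------------------------------------------------------------------

def test_extract_unidirectional_separates_components():
    pos = np.zeros((30, 30))
    for r in range(20):
        pos[r, 3 + r // 2] = 1.0
    neg = np.zeros((30, 30))
    for r in range(20):
        neg[r, 25 - r // 2] = 1.0
    tracks = extract_unidirectional_tracks(pos, neg, 0.2)
    assert len(tracks) == 2
    slopes = sorted(np.sign(t.positions[-1] - t.positions[0]) for t in tracks)
    assert slopes == [-1.0, 1.0]


def test_extract_unidirectional_filters_short():
    pos = np.zeros((10, 10))
    pos[0, 0] = pos[0, 1] = 1.0   # 2 px, 1 frame
    assert extract_unidirectional_tracks(pos, np.zeros((10, 10)), 0.2) == []


# ---------------------------------------------------------------------------
# end-to-end on a skeleton with the oracle decider
# ---------------------------------------------------------------------------

def test_trace_skeleton_crossing_with_oracle():
    s = simulate_bidirectional(BiSimConfig(), 1, render_movie=False)
    skel = thin_prune(render_tracks_binary(s.tracks, s.kymograph.shape,
                                           dilate=False))
    tracks = trace_skeleton(skel, s.kymograph, make_oracle_decider(s.tracks))
    sc = benchmark_sample(s, tracks)
    assert sc["f1"] > 0.9


# ---------------------------------------------------------------------------
# fragment gap linking
# ---------------------------------------------------------------------------

def _mk(tid, f0, n, p0, v, conf=1.0):
    frames = np.arange(f0, f0 + n)
    return Track(id=tid, frames=frames,
                 positions=p0 + v * np.arange(n, dtype=float),
                 mean_confidence=conf)


def test_link_gaps_merges_collinear_fragments():
    a = _mk(0, 0, 10, 0.0, 2.0)           # ends frame 9 at 18
    b = _mk(1, 13, 10, 26.0, 2.0)         # 3-frame gap, on the same line
    out = link_gaps([a, b])
    assert len(out) == 1
    t = out[0]
    assert t.frames[0] == 0 and t.frames[-1] == 22
    # missing frames interpolated linearly
    assert list(t.frames) == list(range(23))
    k = list(t.frames).index(11)
    assert t.positions[k] == pytest.approx(22.0, abs=0.5)


def test_link_gaps_respects_tolerance_and_gap():
    a = _mk(0, 0, 10, 0.0, 2.0)
    off_line = _mk(1, 13, 10, 50.0, 2.0)      # extrapolation misses by far
    too_late = _mk(2, 30, 10, 60.0, 2.0)      # 21-frame gap
    out = link_gaps([a, off_line, too_late])
    assert len(out) == 3
    assert sorted(len(t) for t in out) == [10, 10, 10]


def test_link_gaps_no_merge_on_frame_overlap():
    a = _mk(0, 0, 10, 0.0, 2.0)
    b = _mk(1, 9, 10, 18.0, 2.0)            # starts at a's last frame
    assert len(link_gaps([a, b])) == 2


def test_link_gaps_chains_three_fragments_deterministically():
    a = _mk(0, 0, 8, 0.0, 1.0)
    b = _mk(1, 10, 8, 10.0, 1.0)
    c = _mk(2, 20, 8, 20.0, 1.0)
    out1 = link_gaps([a, b, c])
    out2 = link_gaps([c, a, b])
    assert len(out1) == len(out2) == 1
    assert np.array_equal(out1[0].frames, np.arange(0, 28))
    assert np.allclose(out1[0].positions, out2[0].positions)
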