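"""Fragmentation scoring: projection, tracing, segmentation, continuity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

import flymotor as fm
from flymotor import fragmentation as fr
from flymotor.errors import (GeometryError, ParameterError, SegmentationError,
                             TraceError)
from flymotor.stacks import ImageStack


# --------------------------------------------------------------------------
# maximum projection
# --------------------------------------------------------------------------

def test_max_project_matches_brute_force_and_identity():
    rng = np.random.default_rng(0)
    vox = rng.uniform(size=(1, 3, 4, 4))
    stack = ImageStack(vox, ["a"], 0.1, 0.2)
    proj, pix = fm.max_project(stack, "a")
    brute = np.zeros((4, 4))
    for y, x in itertools.product(range(4), range(4)):
        brute[y, x] = max(vox[0, z, y, x] for z in range(3))
    assert np.array_equal(proj, brute)
    assert pix == 0.1

    single = ImageStack(vox[:, :1], ["a"], 0.1, 0.2)
    proj1, _ = fm.max_project(single, "a")
    assert np.array_equal(proj1, vox[0, 0])


def test_max_project_unknown_channel_raises():
    stack = ImageStack(np.zeros((1, 2, 3, 3)), ["a"], 0.1, 0.2)
    with pytest.raises(KeyError, match="nope"):
        fm.max_project(stack, "nope")


# --------------------------------------------------------------------------
# centerline tracing
# --------------------------------------------------------------------------

def test_trace_length_within_two_percent(clean_branch):
    _, stack, truth = clean_branch
    proj, pix = fm.max_project(stack, "HRP")
    trace = fm.trace_centerline(proj, pix)
    assert trace.arc_length_um == pytest.approx(truth.branch_length_um, rel=0.02)


def test_trace_rotation_invariance(clean_branch):
    _, stack, _ = clean_branch
    proj, pix = fm.max_project(stack, "HRP")
    t0 = fm.trace_centerline(proj, pix)
    t90 = fm.trace_centerline(np.rot90(proj), pix)
    assert t90.arc_length_um == pytest.approx(t0.arc_length_um, rel=0.02)


def test_trace_empty_foreground_raises():
    with pytest.raises(TraceError):
        fm.trace_centerline(np.zeros((50, 50)), 0.1)


def test_trace_beyond_bridging_restricts_to_largest_fragment():
    """Gaps wider than the bridging distance cannot be crossed: the trace
    covers only the largest fragment (the configured policy)."""
    p = fm.BranchSimParams(seed=1, gap_rate_per_um=0.05, snr=float("inf"))
    stack, truth = fm.generate_branch_image(p)
    assert any(e - s > 1.5 for s, e in truth.gap_intervals_axon)
    proj, pix = fm.max_project(stack, "HRP")
    trace = fm.trace_centerline(proj, pix)
    assert trace.arc_length_um < truth.branch_length_um - 1.5


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def _straight_trace(length_um: float) -> fr.BranchTrace:
    pts = np.column_stack([np.linspace(0, length_um, int(length_um / 0.05) + 1),
                           np.zeros(int(length_um / 0.05) + 1)])
    return fr.BranchTrace.from_points(pts)


@pytest.mark.parametrize("length,expected", [(20.0, 20), (20.7, 20)])
def test_segment_count_floor_rule(length, expected):
    segs = fm.segment_branch(_straight_trace(length))
    assert len(segs) == expected
    assert segs[0] == (0.0, 1.0)
    assert segs[-1] == (expected - 1.0, float(expected))


def test_segment_too_short_branch_raises():
    with pytest.raises(SegmentationError):
        fm.segment_branch(_straight_trace(0.8))


# --------------------------------------------------------------------------
# continuity profile
# --------------------------------------------------------------------------

def test_profile_uniform_tube_present_everywhere(clean_branch):
    _, stack, truth = clean_branch
    proj, pix = fm.max_project(stack, "HRP")
    trace = fm.trace_from_ground_truth(truth)
    prof = fm.continuity_profile(proj, pix, trace)
    assert prof.present.all()


def test_profile_blank_image_absent_everywhere():
    trace = _straight_trace(10.0)
    shifted = fr.BranchTrace(trace.points_um + [1.0, 2.0],
                             trace.cumulative_arclength_um)
    prof = fm.continuity_profile(np.zeros((40, 130)), 0.1, shifted)
    assert not prof.present.any()


def test_profile_localizes_known_gap():
    """A branch with one gap: measured absence matches the true interval
    within a couple of resampling steps at each edge."""
    gap = (10.0, 10.8)
    stack2, truth2 = _branch_with_gaps([gap], seed=42)
    proj, pix = fm.max_project(stack2, "HRP")
    trace = fm.trace_from_ground_truth(truth2)
    prof = fm.continuity_profile(proj, pix, trace)
    runs = fr._absence_runs(prof)
    assert len(runs) == 1
    s, e = runs[0]
    assert s == pytest.approx(gap[0], abs=0.15)
    assert e == pytest.approx(gap[1], abs=0.15)


def _branch_with_gaps(gaps, seed=42):
    """Render a branch then impose exact gap intervals via a re-simulation
    with a gap process replaced by the wanted intervals."""
    p = fm.BranchSimParams(seed=seed, gap_rate_per_um=0.0, snr=float("inf"))
    stack, truth = fm.generate_branch_image(p)
    from flymotor.synthetic import _in_intervals
    # carve the gaps out of the rendered axon channel along the centerline
    pts = truth.centerline_points_um
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts[:, :2], axis=0).T))])
    ch = stack.channel_index("HRP")
    vol = stack.voxels[ch]
    nz, ny, nx = vol.shape
    zz, yy, xx = np.meshgrid(np.arange(nz) * stack.z_step_um,
                             np.arange(ny) * stack.pixel_size_um,
                             np.arange(nx) * stack.pixel_size_um, indexing="ij")
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    d, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]))
    in_gap = _in_intervals(arc[idx], gaps).reshape(vol.shape)
    vol[in_gap & (d.reshape(vol.shape) < 1.2)] = 0.0
    truth.gap_intervals_axon = list(gaps)
    return stack, truth


def test_profile_trace_outside_image_raises():
    trace = _straight_trace(30.0)
    with pytest.raises(GeometryError):
        fm.continuity_profile(np.zeros((10, 10)), 0.1, trace)


# --------------------------------------------------------------------------
# continuity scoring
# --------------------------------------------------------------------------

def _profile_from_runs(runs, length_um=20.0, step=0.01):
    s = np.arange(0.0, length_um, step) + step / 2.0
    present = np.ones(len(s), dtype=bool)
    for a, b in runs:
        present[(s >= a) & (s < b)] = False
    return fr.ContinuityProfile(present=present, step_um=step)


def _segments(n, seg=1.0):
    return [(k * seg, (k + 1) * seg) for k in range(n)]


def test_single_segment_gap():
    ser = fm.score_continuity(_profile_from_runs([(5.1, 5.9)]), _segments(20))
    assert list(np.flatnonzero(~ser.continuous_flags)) == [5]
    assert fm.percent_continuous(ser) == pytest.approx(95.0)


def test_straddling_gap_whole_run_rule_invalidates_both():
    ser = fm.score_continuity(_profile_from_runs([(4.7, 5.5)]), _segments(20),
                              straddle_rule="whole-run")
    assert list(np.flatnonzero(~ser.continuous_flags)) == [4, 5]
    assert fm.percent_continuous(ser) == pytest.approx(90.0)


def test_straddling_gap_within_segment_rule_spares_subthreshold_portions():
    ser = fm.score_continuity(_profile_from_runs([(4.7, 5.5)]), _segments(20),
                              straddle_rule="within-segment")
    # portions are 0.3 and 0.5 µm; neither exceeds 0.5 µm
    assert ser.continuous_flags.all()


def test_subthreshold_run_ignored():
    ser = fm.score_continuity(_profile_from_runs([(3.2, 3.6)]), _segments(20))
    assert ser.continuous_flags.all()


def test_threshold_limit_everything_continuous():
    ser = fm.score_continuity(_profile_from_runs([(2.0, 9.0)]), _segments(20),
                              gap_threshold_um=100.0)
    assert fm.percent_continuous(ser) == 100.0


@settings(derandomize=True, max_examples=60)
@given(seed=stn.integers(0, 100_000),
       rule=stn.sampled_from(["whole-run", "within-segment"]))
def test_score_continuity_matches_grid_oracle(seed, rule):
    """Independent fine-grid oracle: derive maximal absence runs by scanning
    a 0.01 µm grid and apply the discontinuity rule segment by segment."""
    rng = np.random.default_rng(seed)
    n_seg = int(rng.integers(5, 25))
    runs = []
    pos = 0.0
    while True:
        pos += rng.uniform(0.2, 3.0)
        width = rng.uniform(0.05, 2.0)
        if pos + width >= n_seg:
            break
        runs.append((round(pos, 2), round(pos + width, 2)))
        pos += width + 0.02
    prof = _profile_from_runs(runs, length_um=float(n_seg))
    ser = fm.score_continuity(prof, _segments(n_seg), straddle_rule=rule)

    step = prof.step_um
    grid = prof.present
    expected = np.ones(n_seg, dtype=bool)
    i = 0
    while i < len(grid):
        if grid[i]:
            i += 1
            continue
        j = i
        while j < len(grid) and not grid[j]:
            j += 1
        s, e = i * step, j * step
        if e - s > 0.5:
            for k in range(n_seg):
                ov = min(e, k + 1.0) - max(s, float(k))
                if ov > 0 and (rule == "whole-run" or ov > 0.5):
                    expected[k] = False
        i = j
    assert np.array_equal(ser.continuous_flags, expected)


def test_profile_must_cover_segments():
    prof = _profile_from_runs([], length_um=5.0)
    with pytest.raises(ParameterError):
        fm.score_continuity(prof, _segments(10))


def test_percent_continuous_arithmetic():
    ser = fr.SegmentSeries(1.0, 0.5, [True] * 18 + [False] * 2)
    assert fm.percent_continuous(ser) == pytest.approx(90.0)
    assert fm.percent_continuous(
        fr.SegmentSeries(1.0, 0.5, [True] * 5)) == 100.0
    assert fm.percent_continuous(
        fr.SegmentSeries(1.0, 0.5, [False] * 5)) == 0.0


# --------------------------------------------------------------------------
# group level
# --------------------------------------------------------------------------

def test_score_preparation_closed_form():
    results = [fr.FragmentationResult("b", 20, v, v) for v in (80.0, 90.0, 100.0)]
    summary = fm.score_preparation(results)["axon"]
    assert summary.mean == pytest.approx(90.0)
    assert summary.sem == pytest.approx(10.0 / np.sqrt(3))
    assert summary.n == 3

    same = [fr.FragmentationResult("b", 20, 90.0, 90.0)] * 30
    s = fm.score_preparation(same)["axon"]
    assert (s.mean, s.sem, s.n) == (90.0, 0.0, 30)


def test_select_central_branches():
    rng = np.random.default_rng(0)
    pos = rng.uniform(0, 200, size=(14, 2))
    idx = fm.select_central_branches(pos, k=10)
    assert len(idx) == 10
    center = pos.mean(axis=0)
    chosen = np.hypot(*(pos[idx] - center).T)
    others = np.hypot(*(np.delete(pos, idx, axis=0) - center).T)
    assert chosen.max() <= others.min()


def test_monotonicity_in_gap_rate():
    """Mean percent-continuous is non-increasing in the gap rate (geometric
    scoring over 60 seeds per rate)."""
    means = []
    for rate in (0.0, 0.05, 0.1, 0.2):
        vals = []
        for seed in range(60):
            truth = fm.generate_branch_ground_truth(
                fm.BranchSimParams(seed=seed, gap_rate_per_um=rate))
            vals.append(fm.percent_continuous(
                fm.series_from_ground_truth(truth, "axon")))
        means.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


def test_percent_bounds_across_random_branches():
    for seed in range(20):
        truth = fm.generate_branch_ground_truth(
            fm.BranchSimParams(seed=seed, gap_rate_per_um=0.3))
        for ch in ("axon", "glia"):
            pct = fm.percent_continuous(fm.series_from_ground_truth(truth, ch))
            assert 0.0 <= pct <= 100.0
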