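"""Slope segmentation against a brute-force oracle, plus profile reconstruction."""

import math

import numpy as np
import pytest

from ebiketrainer import compute_grades, reconstruct_profile, segment_route, synthesize_route
from ebiketrainer.route_io import EARTH_RADIUS_M, Route, TrackPoint


def _route_from_step_grades(step_grades, step=100.0):
    """Build a route whose raw step grades are exactly the given list."""
    d = math.degrees(step / EARTH_RADIUS_M)
    pts = [TrackPoint(45.0, 6.0, 500.0)]
    ele = 500.0
    for k, g in enumerate(step_grades, start=1):
        ele += g * step
        pts.append(TrackPoint(45.0 + k * d, 6.0, ele))
    return Route(points=pts)


# --- independent oracle -----------------------------------------------------

def _oracle_bin(g, w):
    if g == 0.0:
        return 0
    k = math.ceil(abs(g) / w - 1e-6)
    return k if g > 0 else -k


def brute_force_segments(grades, lengths, bin_width, min_length):
    """Naive reference: bin steps, merge zero runs to the flatter neighbour,
    then repeatedly absorb the shortest under-length run into the neighbour
    with the nearer length-weighted mean grade.  Returns (start, end) step spans."""
    runs = []
    for i, g in enumerate(grades):
        key = _oracle_bin(g, bin_width)
        if runs and runs[-1][2] == key:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, key])

    def wmean(r):
        sl = slice(r[0], r[1])
        return np.average(grades[sl], weights=lengths[sl])

    # zero runs -> neighbour with smaller |mean grade|, ties to the left
    merged = []
    i = 0
    while i < len(runs):
        r = runs[i]
        if r[2] != 0:
            if merged and merged[-1][2] == r[2]:
                merged[-1][1] = r[1]
            else:
                merged.append(list(r))
            i += 1
            continue
        left = merged[-1] if merged else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is not None and (right is None or abs(wmean(left)) <= abs(wmean(right))):
            left[1] = r[1]
            i += 1
        elif right is not None:
            nxt = [r[0], right[1], right[2]]
            if merged and merged[-1][2] == nxt[2]:
                merged[-1][1] = nxt[1]
            else:
                merged.append(nxt)
            i += 2
        else:
            merged.append(list(r))
            i += 1

    def rlen(r):
        return float(lengths[r[0]:r[1]].sum())

    while len(merged) > 1:
        short = [(rlen(r), j) for j, r in enumerate(merged) if rlen(r) < min_length]
        if not short:
            break
        _, j = min(short)
        g = wmean(merged[j])
        left = merged[j - 1] if j > 0 else None
        right = merged[j + 1] if j + 1 < len(merged) else None
        if left is not None and (right is None or abs(wmean(left) - g) <= abs(wmean(right) - g)):
            left[1] = merged[j][1]
        else:
            right[0] = merged[j][0]
        del merged[j]
    return [(r[0], r[1]) for r in merged]


# --- tests ------------------------------------------------------------------

class TestSegmentRoute:
    def test_constant_climb_is_one_segment(self):
        route = _route_from_step_grades([0.05] * 12)
        segs = segment_route(route, 0.02, 50.0)
        assert len(segs) == 1
        assert segs[0].grade == pytest.approx(0.05, abs=1e-9)
        assert segs[0].length == pytest.approx(1200.0, rel=1e-3)

    def test_v_profile_two_segments(self):
        """500 m at -3% then 500 m at +3% split exactly at the valley."""
        route = _route_from_step_grades([-0.03] * 5 + [0.03] * 5)
        segs = segment_route(route, 0.02, 50.0)
        assert len(segs) == 2
        assert segs[0].grade == pytest.approx(-0.03, abs=1e-6)
        assert segs[1].grade == pytest.approx(0.03, abs=1e-6)
        assert [s.sign for s in segs] == ["-", "+"]

    def test_three_magnitude_bins_three_segments(self):
        route = _route_from_step_grades([0.02] * 5 + [0.06] * 5 + [-0.03] * 5)
        segs = segment_route(route, 0.02, 50.0)
        assert len(segs) == 3

    def test_short_route_is_single_segment(self):
        route = _route_from_step_grades([0.01, 0.05], step=10.0)
        segs = segment_route(route, 0.02, 50.0)
        assert len(segs) == 1

    def test_zero_grade_run_joins_flatter_neighbour(self):
        # flat stretch between a 1% and a 5% leg belongs with the 1% side
        route = _route_from_step_grades([0.01] * 4 + [0.0] * 4 + [0.05] * 4)
        segs = segment_route(route, 0.02, 50.0)
        assert len(segs) == 2
        assert segs[0].length == pytest.approx(800.0, rel=1e-3)

    def test_partition_covers_route_exactly(self):
        route = synthesize_route([(600, 0.03), (400, -0.02), (500, 0.0)], step=10,
                                 noise_sd=0.8, seed=3)
        route = compute_grades(route, 30.0)
        segs = segment_route(route)
        assert sum(s.length for s in segs) == pytest.approx(route.length_m, abs=1e-6)
        spans = [(s.start_index, s.end_index) for s in segs]
        assert spans[0][0] == 0
        assert spans[-1][1] == len(route.points)
        # adjacent segments share their boundary track point
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b - 1 == c

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_routes(self, seed):
        """Segment boundaries equal the naive scan on seeded random grade profiles."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        grades = rng.choice([-0.06, -0.03, -0.01, 0.0, 0.01, 0.03, 0.06], size=n)
        route = _route_from_step_grades(grades, step=30.0)
        lengths = np.diff(route.cumulative_distance)
        got = [(s.start_index, s.end_index - 1) for s in segment_route(route, 0.02, 50.0)]
        expected = brute_force_segments(np.asarray(route.grade), lengths, 0.02, 50.0)
        assert got == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_halving_bin_width_never_coarsens(self, seed):
        """Finer bins can only add boundaries (checked with absorption disabled)."""
        rng = np.random.default_rng(seed + 100)
        grades = rng.uniform(-0.1, 0.1, size=60)
        route = _route_from_step_grades(grades, step=100.0)
        tiny = 1e-9  # min_length small enough that absorption never fires
        coarse = segment_route(route, 0.04, tiny)
        fine = segment_route(route, 0.02, tiny)
        assert len(fine) >= len(coarse)
        coarse_bounds = {s.start_index for s in coarse}
        fine_bounds = {s.start_index for s in fine}
        assert coarse_bounds <= fine_bounds


class TestReconstructProfile:
    def test_single_segment_endpoint(self):
        route = _route_from_step_grades([0.05] * 10)
        segs = segment_route(route, 0.02, 50.0)
        profile = reconstruct_profile(segs, start_elevation=500.0)
        assert profile[-1][1] - profile[0][1] == pytest.approx(50.0, rel=1e-3)

    def test_noise_free_route_reconstructs_true_elevations(self):
        spec = [(600, 0.03), (400, -0.02), (500, 0.015)]
        route = synthesize_route(spec, step=10, noise_sd=0.0, seed=0)
        route = compute_grades(route, 0.0)
        segs = segment_route(route, 0.02, 50.0)
        profile = reconstruct_profile(segs, start_elevation=route.points[0].elevation)
        # reconstruction endpoint matches the true final elevation
        true_end = route.points[-1].elevation
        assert profile[-1][1] == pytest.approx(true_end, abs=0.1)

    def test_empty_segments_empty_profile(self):
        assert reconstruct_profile([]) == []
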