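"""Partition a route into contiguous constant-assist segments by slope.

Adjacent steps whose grades fall in the same signed magnitude bin are
merged; zero-grade runs inherit the sign of the flatter neighbour; runs
shorter than a minimum length are absorbed into the neighbouring segment
with the nearer mean grade.  Each segment later receives one assist level,
so over-segmentation costs battery switching and under-segmentation costs
fit to the terrain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .route_io import Route

DEFAULT_BIN_WIDTH = 0.02
DEFAULT_MIN_LENGTH = 50.0


@dataclass
class Segment:
    """A contiguous slice of a route with one representative grade.

    ``[start_index, end_index)`` are point indices (half-open), ``length``
    is metres, ``grade`` is the length-weighted mean step grade, ``sign``
    is '+' or '-'.
    """

    start_index: int
    end_index: int
    length: float
    grade: float
    sign: str

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("segment must cover at least one step")
        if self.length <= 0:
            raise ValueError("segment length must be positive")


def _bin_key(grade: float, bin_width: float) -> int:
    """Signed magnitude-bin index; bins are half-open toward zero.

    Bin k covers magnitudes (k*w, (k+1)*w], so a grade exactly on an edge
    falls in the lower-magnitude bin.  The edge test tolerates ~1e-6
    relative jitter so grades that are on an edge up to floating-point
    noise do not flip bins.  Zero grade gets key 0 and is resolved by the
    adjacency rule afterwards.
    """
    if grade == 0.0:
        return 0
    mag = abs(grade)
    k = int(math.ceil(mag / bin_width - 1e-6))
    return k if grade > 0 else -k


@dataclass
class _Run:
    start: int  # step index
    end: int    # step index, exclusive
    key: int


def _initial_runs(grades: np.ndarray, bin_width: float) -> list[_Run]:
    keys = [_bin_key(g, bin_width) for g in grades]
    runs: list[_Run] = []
    for i, key in enumerate(keys):
        if runs and runs[-1].key == key:
            runs[-1].end = i + 1
        else:
            runs.append(_Run(i, i + 1, key))
    return runs


def _merge_zero_runs(runs: list[_Run], grades: np.ndarray, lengths: np.ndarray) -> list[_Run]:
    """Attach zero-grade runs to the adjacent run with smaller mean |grade|.

    Ties (including a lone neighbour) go to the preceding run.  A route
    that is entirely flat stays a single zero run.
    """
    def mean_abs(run: _Run) -> float:
        w = lengths[run.start:run.end]
        return float(np.abs(np.average(grades[run.start:run.end], weights=w)))

    out: list[_Run] = []
    pending_zero: list[_Run] = []
    for run in runs:
        if run.key == 0:
            pending_zero.append(run)
            continue
        if pending_zero:
            for z in pending_zero:
                if out and mean_abs(out[-1]) <= mean_abs(run):
                    out[-1].end = z.end
                else:
                    run = _Run(z.start, run.end, run.key)
            pending_zero = []
        if out and out[-1].key == run.key:
            out[-1].end = run.end
        else:
            out.append(run)
    for z in pending_zero:  # trailing zeros (or all-flat route)
        if out:
            out[-1].end = z.end
        else:
            out.append(z)
    return out


def _absorb_short_runs(
    runs: list[_Run], grades: np.ndarray, lengths: np.ndarray, min_length: float
) -> list[_Run]:
    """Repeatedly fold the shortest under-length run into its nearer-grade neighbour."""
    def run_length(run: _Run) -> float:
        return float(lengths[run.start:run.end].sum())

    def run_grade(run: _Run) -> float:
        w = lengths[run.start:run.end]
        return float(np.average(grades[run.start:run.end], weights=w))

    runs = [_Run(r.start, r.end, r.key) for r in runs]
    while len(runs) > 1:
        short = [(run_length(r), i) for i, r in enumerate(runs) if run_length(r) < min_length]
        if not short:
            break
        _, i = min(short)
        g = run_grade(runs[i])
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is not None and (
            right is None or abs(run_grade(left) - g) <= abs(run_grade(right) - g)
        ):
            left.end = runs[i].end
        else:
            assert right is not None
            right.start = runs[i].start
        del runs[i]
    return runs


def segment_route(
    route: Route,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_length: float = DEFAULT_MIN_LENGTH,
) -> list[Segment]:
    """Split a route into contiguous segments of similar slope magnitude.

    Two passes: (1) group adjacent steps sharing a signed magnitude bin of
    width ``bin_width`` (zero-grade runs join the flatter neighbour);
    (2) absorb runs shorter than ``min_length`` metres into the neighbour
    with the nearer mean grade.  Segments partition the route's steps
    exactly; each carries the length-weighted mean grade of its steps.
    """
    if bin_width <= 0 or min_length <= 0:
        raise ValueError("bin_width and min_length must be positive")
    grades = np.asarray(route.grade, dtype=float)
    lengths = np.diff(route.cumulative_distance)
    runs = _initial_runs(grades, bin_width)
    runs = _merge_zero_runs(runs, grades, lengths)
    runs = _absorb_short_runs(runs, grades, lengths, min_length)
    segments = []
    for run in runs:
        w = lengths[run.start:run.end]
        g = float(np.average(grades[run.start:run.end], weights=w))
        segments.append(
            Segment(
                start_index=run.start,
                end_index=run.end + 1,
                length=float(w.sum()),
                grade=g,
                sign="+" if g >= 0 else "-",
            )
        )
    return segments


def reconstruct_profile(
    segments: Sequence[Segment], start_elevation: float = 0.0
) -> list[tuple[float, float]]:
    """Piecewise-linear (distance, elevation) profile implied by the segments."""
    if not segments:
        return []
    profile = [(0.0, start_elevation)]
    d, e = 0.0, start_elevation
    for seg in segments:
        d += seg.length
        e += seg.length * seg.grade
        profile.append((d, e))
    return profile


def segments_to_tsv(segments: Sequence[Segment], route_id: str = "route") -> str:
    """Render segments as a BED-like TSV: route_id, start_m, end_m, grade, sign."""
    lines = ["route_id\tstart_m\tend_m\tgrade\tsign"]
    pos = 0.0
    for seg in segments:
        lines.append(f"{route_id}\t{pos:.1f}\t{pos + seg.length:.1f}\t{seg.grade:.4f}\t{seg.sign}")
        pos += seg.length
    return "\n".join(lines) + "\n"


def write_segments_tsv(segments: Sequence[Segment], path: str | Path, route_id: str = "route") -> None:
    Path(path).write_text(segments_to_tsv(segments, route_id), encoding="utf-8")
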