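"""Heart-rate zones, age-predicted HRmax, and the assist safety override.

HRmax is the age-predicted maximum 205.8 - 0.685*age (bpm).  Training
zones are fractions of HRmax: Z1 "light" [50%, 70%), Z2 "moderate"
[70%, 80%), Z3 "hard" [80%, 90%), Z4 "maximum" [90%, 100%+).  The
published zone table leaves 60-70% unassigned; this implementation folds
that band into Z1 so the scale partitions, and the report flags it.

The safety override bumps the assist level one rung when the pulse
exceeds a threshold, with a hysteresis window so a sustained spike climbs
the ladder gradually rather than instantly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .profiles import BikeProfile

ZONE_EDGES = {"Z1": (0.50, 0.70), "Z2": (0.70, 0.80), "Z3": (0.80, 0.90), "Z4": (0.90, math.inf)}
ZONE_LABELS = ("below", "Z1", "Z2", "Z3", "Z4")

#: fraction of HRmax used as the default safety threshold
DEFAULT_THRESHOLD_FRACTION = 0.90
#: seconds between successive automatic level increases
OVERRIDE_HYSTERESIS_S = 30.0


@dataclass(frozen=True)
class HRSample:
    time: float  # seconds from ride start
    bpm: float

    def __post_init__(self) -> None:
        if not 25.0 < self.bpm < 250.0:
            raise ValueError(f"bpm {self.bpm} outside (25, 250)")


@dataclass(frozen=True)
class HRZoneReport:
    """Time-in-zone fractions for a ride; fractions sum to 1."""

    hr_max: float
    fractions: dict  # {"below": f, "Z1": f, ..., "Z4": f}
    note: str = "Z1 extended to cover the 60-70% band"

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"zone fractions sum to {total}, expected 1")


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate in bpm: 205.8 - 0.685*age."""
    if not 10.0 <= age <= 100.0:
        raise ValueError(f"age {age} outside [10, 100]")
    return 205.8 - 0.685 * age


def zone_of(bpm: float, hr_max_bpm: float) -> str:
    """Training-zone label ('below', 'Z1'..'Z4') for a pulse."""
    if hr_max_bpm <= 0:
        raise ValueError("hr_max must be positive")
    ratio = bpm / hr_max_bpm
    if ratio < 0.50:
        return "below"
    for label, (lo, hi) in ZONE_EDGES.items():
        if lo <= ratio < hi:
            return label
    return "Z4"


def time_in_zones(series: Sequence[HRSample], hr_max_bpm: float) -> HRZoneReport:
    """Time-weighted fraction of a ride spent in each training zone.

    Each inter-sample interval counts toward the zone of its left sample.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 HR samples")
    times = np.array([s.time for s in series])
    if np.any(np.diff(times) < 0):
        raise ValueError("HR sample times must be non-decreasing")
    total = times[-1] - times[0]
    if total <= 0:
        raise ValueError("HR series spans zero time")
    acc = {label: 0.0 for label in ZONE_LABELS}
    for left, dt in zip(series[:-1], np.diff(times)):
        acc[zone_of(left.bpm, hr_max_bpm)] += float(dt)
    fractions = {label: acc[label] / total for label in ZONE_LABELS}
    return HRZoneReport(hr_max=hr_max_bpm, fractions=fractions)


def safety_override(
    bpm: float,
    threshold: float,
    current_level: int,
    bike: BikeProfile,
    seconds_since_increase: float = math.inf,
    hysteresis_s: float = OVERRIDE_HYSTERESIS_S,
) -> int:
    """One step of the pulse-triggered assist increase.

    Returns the new assist level: one rung up (capped at the bike's top
    level) when the pulse exceeds the threshold and the last automatic
    increase was at least ``hysteresis_s`` seconds ago; otherwise the level
    is unchanged.  Never decreases the level.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if bpm > threshold and seconds_since_increase >= hysteresis_s:
        return min(current_level + 1, bike.n_levels)
    return current_level


def default_threshold(age: float, fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    """Default safety threshold: a fraction (default 90%) of age-predicted HRmax."""
    return fraction * hr_max(age)


def read_hr_csv(path) -> list[HRSample]:
    """Read an HR series from CSV with header ``time_s,bpm``."""
    import csv

    samples = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"time_s", "bpm"} <= set(reader.fieldnames):
            raise ValueError("HR CSV must have header time_s,bpm")
        for row in reader:
            samples.append(HRSample(time=float(row["time_s"]), bpm=float(row["bpm"])))
    return samples
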