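"""Ride telemetry simulation.

Plays an assist plan forward at a fixed sample interval: the rider tracks
the planned speed with Gaussian noise, the motor supplies its level power
(but never more than the instantaneous requirement — pedal-assist motors
do not push the bike beyond what the terrain asks), the rider covers the
rest, and heart rate relaxes first-order toward a workload-dependent
target.  Everything is seeded, so fixtures are reproducible bit for bit.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .assist_planner import AssistPlan
from .heart_rate import OVERRIDE_HYSTERESIS_S, safety_override
from .power_model import PowerModelParams, required_power
from .profiles import BikeProfile


@dataclass(frozen=True)
class BehaviorModel:
    """How the simulated rider deviates from the plan.

    ``speed_tracking_sd`` is the m/s standard deviation of speed around the
    planned value; heart rate relaxes toward ``hr_rest + hr_gain * rider
    power`` with time constant ``hr_time_constant`` seconds.
    """

    speed_tracking_sd: float = 0.3
    hr_rest: float = 65.0
    hr_gain: float = 0.45   # bpm per W of rider output
    hr_time_constant: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_tracking_sd < 0:
            raise ValueError("speed_tracking_sd must be >= 0")
        if self.hr_time_constant <= 0:
            raise ValueError("hr_time_constant must be positive")


@dataclass
class RideTelemetry:
    """Fixed-interval samples of a (simulated or recorded) ride."""

    time: np.ndarray        # s
    distance: np.ndarray    # m along route
    speed: np.ndarray       # m/s
    motor_power: np.ndarray # W
    rider_power: np.ndarray # W
    bpm: Optional[np.ndarray]
    level: np.ndarray       # active assist level per sample

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("distance", "speed", "motor_power", "rider_power", "level"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"telemetry channel {name} length mismatch")
        if np.any(np.diff(self.distance) < 0):
            raise ValueError("distance must be non-decreasing")
        if np.any(self.speed < 0) or np.any(self.motor_power < 0) or np.any(self.rider_power < 0):
            raise ValueError("speeds and powers must be >= 0")

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.time)


def simulate_ride(
    plan: AssistPlan,
    bike: BikeProfile,
    params: PowerModelParams,
    behavior: BehaviorModel,
    dt: float = 1.0,
    hr_threshold: Optional[float] = None,
) -> RideTelemetry:
    """Simulate riding an assist plan sample by sample.

    Per sample the realized speed is the segment's planned speed plus
    truncated Gaussian noise; the motor delivers the active level's power
    clamped so rider + motor equals the power the realized speed requires
    (rider never below zero); heart rate follows a first-order response to
    rider workload; if ``hr_threshold`` is set the safety override may
    raise the active level above the planned one, with hysteresis.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not plan.segments:
        raise ValueError("cannot simulate an empty plan")
    rng = np.random.default_rng(behavior.seed)

    boundaries = np.cumsum([sp.segment.length for sp in plan.segments])
    total_length = boundaries[-1]

    t, x = 0.0, 0.0
    bpm = behavior.hr_rest
    seg_idx = 0
    override_bump = 0
    last_increase = -math.inf

    rows = []
    while x < total_length:
        while seg_idx < len(plan.segments) - 1 and x >= boundaries[seg_idx]:
            seg_idx += 1
        sp = plan.segments[seg_idx]
        level = min(sp.assist_level + override_bump, bike.n_levels)

        v = sp.planned_speed
        if behavior.speed_tracking_sd > 0:
            v = max(0.0, v + rng.normal(0.0, behavior.speed_tracking_sd))
        p_req = required_power(v, sp.segment.grade, params)
        motor = min(bike.power_of_level(level), max(p_req, 0.0))
        rider = max(p_req - motor, 0.0)

        target = behavior.hr_rest + behavior.hr_gain * rider
        bpm += (dt / behavior.hr_time_constant) * (target - bpm)

        if hr_threshold is not None:
            new_level = safety_override(
                bpm, hr_threshold, level, bike,
                seconds_since_increase=t - last_increase,
                hysteresis_s=OVERRIDE_HYSTERESIS_S,
            )
            if new_level > level:
                override_bump += new_level - level
                last_increase = t

        rows.append((t, x, v, motor, rider, bpm, level))
        x += v * dt
        t += dt
        if v <= 0 and behavior.speed_tracking_sd == 0:
            raise ValueError("simulated rider stalled (planned speed 0)")

    arr = np.array(rows)
    return RideTelemetry(
        time=arr[:, 0], distance=arr[:, 1], speed=arr[:, 2],
        motor_power=arr[:, 3], rider_power=arr[:, 4],
        bpm=arr[:, 5], level=arr[:, 6].astype(int),
    )


@dataclass(frozen=True)
class RideSummary:
    distance_km: float
    duration_s: float
    mean_speed_kmh: float
    rider_energy_wh: float
    motor_energy_wh: float


def summarize_ride(telemetry: RideTelemetry) -> RideSummary:
    """Distance, duration, mean speed and energies of a telemetry trace.

    Energies are left-rectangle integrals on the sample grid, matching the
    scoring module's convention.
    """
    if len(telemetry.time) < 2:
        raise ValueError("need at least 2 telemetry samples")
    dt = telemetry.dt
    duration = float(telemetry.time[-1] - telemetry.time[0]) + float(dt[-1])
    distance = float(telemetry.distance[-1] - telemetry.distance[0]) \
        + float(telemetry.speed[-1] * dt[-1])
    rider_wh = float(np.sum(telemetry.rider_power[:-1] * dt) + telemetry.rider_power[-1] * dt[-1]) / 3600.0
    motor_wh = float(np.sum(telemetry.motor_power[:-1] * dt) + telemetry.motor_power[-1] * dt[-1]) / 3600.0
    return RideSummary(
        distance_km=distance / 1000.0,
        duration_s=duration,
        mean_speed_kmh=(distance / duration) * 3.6,
        rider_energy_wh=rider_wh,
        motor_energy_wh=motor_wh,
    )


TELEMETRY_HEADER = ["time_s", "dist_m", "speed_ms", "motor_w", "rider_w", "bpm", "level"]


def write_telemetry_csv(telemetry: RideTelemetry, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TELEMETRY_HEADER)
        for k in range(len(telemetry.time)):
            bpm = "" if telemetry.bpm is None else f"{telemetry.bpm[k]:.2f}"
            writer.writerow([
                f"{telemetry.time[k]:.3f}", f"{telemetry.distance[k]:.2f}",
                f"{telemetry.speed[k]:.4f}", f"{telemetry.motor_power[k]:.3f}",
                f"{telemetry.rider_power[k]:.3f}", bpm, int(telemetry.level[k]),
            ])


def read_telemetry_csv(path: str | Path) -> RideTelemetry:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(TELEMETRY_HEADER[:5]) <= set(reader.fieldnames):
            raise ValueError(f"telemetry CSV must have header {','.join(TELEMETRY_HEADER)}")
        for row in reader:
            rows.append(row)
    if not rows:
        raise ValueError("empty telemetry CSV")
    has_bpm = any(r.get("bpm") for r in rows)
    return RideTelemetry(
        time=np.array([float(r["time_s"]) for r in rows]),
        distance=np.array([float(r["dist_m"]) for r in rows]),
        speed=np.array([float(r["speed_ms"]) for r in rows]),
        motor_power=np.array([float(r["motor_w"]) for r in rows]),
        rider_power=np.array([float(r["rider_w"]) for r in rows]),
        bpm=np.array([float(r["bpm"]) for r in rows]) if has_bpm else None,
        level=np.array([int(r.get("level") or 0) for r in rows]),
    )
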