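"""Ride evaluation: rider energy, the capped route score, and progression.

The scored quantity is the energy the rider supplied over the route, in
watt-hours: at each telemetry sample the power the terrain demanded at the
realized speed, minus what the motor delivered, floored at zero (coasting
earns nothing and costs nothing), integrated over time.  The score equals
that energy, capped at 600 per route — roughly the energy of holding
50 km/h on the flat for an hour, taken as the ceiling of human output.
Scores accumulate and move the rider up the ability ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ability import DEFAULT_ABILITY_TABLE, AbilityTable
from .assist_planner import AssistPlan
from .power_model import PowerModelParams, required_power
from .profiles import RiderProfile
from .simulator import RideTelemetry

SCORE_CAP = 600.0


@dataclass(frozen=True)
class RouteScore:
    """The outcome of one ride: energies, score, and the updated standing."""

    rider_energy_wh: float
    motor_energy_wh: float
    total_energy_wh: float
    score: float
    new_total_points: float
    new_level: int

    def __post_init__(self) -> None:
        if min(self.rider_energy_wh, self.motor_energy_wh, self.score) < 0:
            raise ValueError("energies and score must be >= 0")
        if abs(self.rider_energy_wh + self.motor_energy_wh - self.total_energy_wh) > 0.5:
            raise ValueError("rider + motor energy must equal total within 0.5 Wh")


def rider_energy(
    telemetry: RideTelemetry, plan: AssistPlan, params: PowerModelParams
) -> float:
    """Rider-supplied energy (Wh) over a ride.

    At each sample the demanded power is the power equation evaluated at
    the sampled speed and the grade of the segment the sample lies in; the
    rider's share is the demand minus the motor channel, floored at zero.
    Left-rectangle integration on the sample grid.
    """
    if telemetry.motor_power is None:
        raise ValueError("telemetry is missing the motor-power channel")
    boundaries = np.cumsum([sp.segment.length for sp in plan.segments])
    grades = np.array([sp.segment.grade for sp in plan.segments])
    seg_of = np.minimum(
        np.searchsorted(boundaries, telemetry.distance, side="right"), len(grades) - 1
    )
    n = len(telemetry.time)
    dts = np.empty(n)
    dts[:-1] = np.diff(telemetry.time)
    dts[-1] = dts[-2] if n > 1 else 0.0
    energy_ws = 0.0
    for k in range(n):
        demand = required_power(float(telemetry.speed[k]), float(grades[seg_of[k]]), params)
        energy_ws += max(demand - float(telemetry.motor_power[k]), 0.0) * dts[k]
    return energy_ws / 3600.0


def motor_energy(telemetry: RideTelemetry) -> float:
    """Motor-supplied energy (Wh), left-rectangle on the sample grid."""
    n = len(telemetry.time)
    dts = np.empty(n)
    dts[:-1] = np.diff(telemetry.time)
    dts[-1] = dts[-2] if n > 1 else 0.0
    return float(np.sum(telemetry.motor_power * dts)) / 3600.0


def score_route(rider_energy_wh: float) -> float:
    """Route score in points: the rider energy in Wh, capped at 600."""
    if rider_energy_wh < 0:
        raise ValueError("rider energy must be >= 0")
    return min(rider_energy_wh, SCORE_CAP)


def accrue(
    profile: RiderProfile, score: float, ability: AbilityTable = DEFAULT_ABILITY_TABLE
) -> RiderProfile:
    """Add a route score to the rider's total; the level follows the ladder."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return replace(profile, total_points=profile.total_points + score)


def evaluate_ride(
    telemetry: RideTelemetry,
    plan: AssistPlan,
    rider: RiderProfile,
    params: PowerModelParams,
    ability: AbilityTable = DEFAULT_ABILITY_TABLE,
) -> RouteScore:
    """Score a completed ride and compute the rider's updated standing."""
    e_rider = rider_energy(telemetry, plan, params)
    e_motor = motor_energy(telemetry)
    score = score_route(e_rider)
    new_points = rider.total_points + score
    new_level = ability.row_for_points(new_points).level
    return RouteScore(
        rider_energy_wh=e_rider,
        motor_energy_wh=e_motor,
        total_energy_wh=e_rider + e_motor,
        score=score,
        new_total_points=new_points,
        new_level=new_level,
    )
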