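"""Per-segment assist planning.

For each slope segment the planner asks: at the rider's target speed v',
how much power does the segment cost, how much of it does the rider's
constant power p cover, and which discrete assist level best supplies the
remainder?  Motor power quantizes to the nearest rung of the bike's
assist-level ladder via half-open midpoint intervals; downhill surpluses
coast (no regeneration), shortfalls beyond the motor's maximum sag the
speed to what rider + full motor can sustain, and assistance is cut on
segments planned faster than the legal cutoff.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .ability import DEFAULT_ABILITY_TABLE, AbilityTable, ability_for_points
from .power_model import (
    KMH,
    PowerModelParams,
    required_power,
    speed_at_power,
)
from .profiles import BikeProfile, RiderProfile
from .route_io import GPX_NS, Route
from .segmentation import Segment


def quantize_to_level(motor_power: float, bike: BikeProfile) -> int:
    """Map a continuous motor power to the assist-level index (0 = off).

    Level j wins when the power lies in [(p_{j-1}+p_j)/2, (p_j+p_{j+1})/2);
    below half the first rung maps to 0, at or above the top midpoint maps
    to the top level.  Equivalent to nearest-rung assignment with exact
    midpoints rounding up.  Non-positive power is level 0.
    """
    if motor_power <= 0:
        return 0
    powers = bike.level_powers
    prev = 0.0
    for j, p in enumerate(powers, start=1):
        upper = (p + powers[j]) / 2 if j < len(powers) else float("inf")
        lower = (prev + p) / 2
        if lower <= motor_power < upper:
            return j
        prev = p
    return 0 if motor_power < powers[0] / 2 else len(powers)


@dataclass
class SegmentPlan:
    """The plan for one segment: speeds, power split, and the chosen level."""

    segment: Segment
    target_speed: float        # m/s, the ability-ladder speed v'
    planned_speed: float       # m/s, what the ride will actually aim for
    required_power: float      # W at the planned speed (may be < 0 downhill)
    rider_power: float         # W, >= 0 (continuous split)
    motor_power: float         # W before quantization, clamped to [0, motor_max]
    assist_level: int
    waypoint: tuple[float, float]  # (lat, lon) of the segment start
    delivered_motor_power: float = 0.0  # what the quantized level will supply
    predicted_rider_power: float = 0.0  # the rider's share after quantization
    coasting: bool = False     # downhill, required power <= 0
    speed_sagged: bool = False # rider + full motor cannot hold v'
    cutoff_applied: bool = False  # assistance cut above the legal speed

    @property
    def duration_s(self) -> float:
        return self.segment.length / self.planned_speed


@dataclass
class AssistPlan:
    """A whole-route plan plus predicted totals.

    Predicted energies use the quantized per-level delivery (what the bike
    will actually supply), so a noise-free ride of the plan reproduces
    them.
    """

    segments: list[SegmentPlan]
    rider_energy_wh: float = field(init=False)
    motor_energy_wh: float = field(init=False)
    duration_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.duration_s = sum(s.duration_s for s in self.segments)
        self.rider_energy_wh = sum(
            s.predicted_rider_power * s.duration_s for s in self.segments
        ) / 3600.0
        self.motor_energy_wh = sum(
            s.delivered_motor_power * s.duration_s for s in self.segments
        ) / 3600.0

    def to_records(self) -> list[dict]:
        recs = []
        pos = 0.0
        for sp in self.segments:
            recs.append(
                {
                    "start_m": round(pos, 1),
                    "end_m": round(pos + sp.segment.length, 1),
                    "grade": round(sp.segment.grade, 4),
                    "target_speed_kmh": round(sp.target_speed / KMH, 2),
                    "planned_speed_kmh": round(sp.planned_speed / KMH, 2),
                    "required_power_w": round(sp.required_power, 2),
                    "rider_power_w": round(sp.rider_power, 2),
                    "motor_power_w": round(sp.motor_power, 2),
                    "delivered_motor_w": round(sp.delivered_motor_power, 2),
                    "assist_level": sp.assist_level,
                    "coasting": sp.coasting,
                    "speed_sagged": sp.speed_sagged,
                    "cutoff_applied": sp.cutoff_applied,
                }
            )
            pos += sp.segment.length
        return recs


def plan_assist(
    segments: Sequence[Segment],
    rider: RiderProfile,
    bike: BikeProfile,
    params: PowerModelParams,
    ability: AbilityTable = DEFAULT_ABILITY_TABLE,
    route: Optional[Route] = None,
) -> AssistPlan:
    """Build the per-segment assist plan for a rider on a bike.

    The rider holds the constant power p of their ability rung and aims for
    its target speed v'.  Per segment the motor covers the excess of the
    segment's required power over p, quantized to the bike's level ladder;
    see the module docstring for the clamp rules.
    """
    if not segments:
        raise ValueError("cannot plan an empty segment list")
    level, speed_kmh, p_rider = ability_for_points(rider.total_points, ability)
    v_target = speed_kmh * KMH
    cutoff_ms = bike.legal_speed_cutoff * KMH

    plans = []
    for seg in segments:
        wp = (0.0, 0.0)
        if route is not None:
            pt = route.points[seg.start_index]
            wp = (pt.latitude, pt.longitude)
        p_req = required_power(v_target, seg.grade, params)
        planned = v_target
        rider_w, motor_w = p_rider, p_req - p_rider
        coasting = sagged = cutoff = False
        if p_req <= 0:
            rider_w, motor_w, coasting = 0.0, 0.0, True
        elif p_req < p_rider:
            rider_w, motor_w = p_req, 0.0
        elif motor_w > bike.motor_max:
            motor_w = bike.motor_max
            planned = speed_at_power(p_rider + bike.motor_max, seg.grade, params)
            sagged = True
        if planned > cutoff_ms and motor_w > 0:
            motor_w, cutoff = 0.0, True
        lvl = quantize_to_level(motor_w, bike)
        # a pedal-assist motor supplies its level power but never pushes
        # beyond the instantaneous demand
        delivered = min(bike.power_of_level(lvl), max(p_req, 0.0))
        plans.append(
            SegmentPlan(
                segment=seg,
                target_speed=v_target,
                planned_speed=planned,
                required_power=p_req,
                rider_power=rider_w,
                motor_power=motor_w,
                assist_level=lvl,
                waypoint=wp,
                delivered_motor_power=delivered,
                predicted_rider_power=max(p_req - delivered, 0.0),
                coasting=coasting,
                speed_sagged=sagged,
                cutoff_applied=cutoff,
            )
        )
    return AssistPlan(segments=plans)


def plan_waypoints(plan: AssistPlan, route: Route) -> list[dict]:
    """One waypoint per segment start, annotated with its assist level."""
    wps = []
    for sp in plan.segments:
        pt = route.points[sp.segment.start_index]
        wps.append(
            {
                "lat": pt.latitude,
                "lon": pt.longitude,
                "ele": pt.elevation,
                "name": f"assist level {sp.assist_level}",
                "level": sp.assist_level,
            }
        )
    return wps


def write_waypoints_gpx(waypoints: Sequence[dict], path: str | Path) -> None:
    """Write planner waypoints as GPX 1.1 ``<wpt>`` elements."""
    ET.register_namespace("", GPX_NS)
    gpx = ET.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator="ebiketrainer")
    for wp in waypoints:
        el = ET.SubElement(gpx, f"{{{GPX_NS}}}wpt",
                           lat=f"{wp['lat']:.7f}", lon=f"{wp['lon']:.7f}")
        ET.SubElement(el, f"{{{GPX_NS}}}ele").text = f"{wp.get('ele', 0.0):.3f}"
        ET.SubElement(el, f"{{{GPX_NS}}}name").text = wp["name"]
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="UTF-8")


def read_waypoints_gpx(path: str | Path) -> list[dict]:
    root = ET.parse(path).getroot()
    out = []
    for el in root.findall(f"{{{GPX_NS}}}wpt") or root.findall("wpt"):
        name_el = el.find(f"{{{GPX_NS}}}name")
        if name_el is None:
            name_el = el.find("name")
        name = name_el.text if name_el is not None else ""
        level = int(name.rsplit(" ", 1)[-1]) if name and name.rsplit(" ", 1)[-1].isdigit() else 0
        out.append({"lat": float(el.get("lat")), "lon": float(el.get("lon")),
                    "name": name, "level": level})
    return out
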