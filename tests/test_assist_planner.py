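"""Ability mapping, assist-level quantization and per-segment planning."""


import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ebiketrainer import (
    DEFAULT_ABILITY_TABLE,
    BikeProfile,
    RiderProfile,
    ability_for_points,
    plan_assist,
    plan_waypoints,
    quantize_to_level,
    required_power,
)
from ebiketrainer.assist_planner import read_waypoints_gpx, write_waypoints_gpx
from ebiketrainer.segmentation import Segment

KMH = 1 / 3.6


def _segment(length, grade, start=0, end=None):
    return Segment(start_index=start, end_index=end or start + 1,
                   length=length, grade=grade, sign="+" if grade >= 0 else "-")


class TestAbilityMapping:
    def test_170_points_is_level4_at_19kmh(self):
        level, speed, power = ability_for_points(170)
        assert (level, speed) == (4, 19)
        assert power == pytest.approx(53.27)

    def test_zero_points_is_level1(self):
        level, speed, _ = ability_for_points(0)
        assert (level, speed) == (1, 15)

    def test_beyond_ladder_clamps_to_top(self):
        level, speed, _ = ability_for_points(10_000)
        assert (level, speed) == (10, 28)

    def test_negative_points_rejected(self):
        with pytest.raises(ValueError):
            ability_for_points(-1)

    def test_interval_edges(self):
        assert ability_for_points(301)[0] == 7
        assert ability_for_points(300)[0] == 6


class TestQuantizeToLevel:
    BIKE = BikeProfile(level_powers=[100.0, 200.0, 300.0], motor_max=300.0)

    @pytest.mark.parametrize(
        "power,expected",
        [
            (140.0, 1),    # nearest rung is 100
            (150.0, 2),    # exact midpoint rounds up
            (49.9, 0),     # below half the first rung: off
            (50.0, 1),     # bottom midpoint is left-closed
            (-20.0, 0),
            (1e6, 3),
        ],
    )
    def test_interval_rule(self, power, expected):
        assert quantize_to_level(power, self.BIKE) == expected

    @given(
        powers=st.lists(st.floats(20, 800), min_size=1, max_size=8, unique=True),
        demand=st.floats(-50, 1000),
    )
    @settings(max_examples=300, deadline=None)
    def test_equivalent_to_nearest_rung_assignment(self, powers, demand):
        """Midpoint intervals == nearest-level assignment (exact ties checked separately)."""
        ladder = sorted(powers)
        assume(min(b - a for a, b in zip([0.0] + ladder, ladder)) > 0.5)
        mids = [ladder[0] / 2] + [(a + b) / 2 for a, b in zip(ladder, ladder[1:])]
        assume(all(abs(demand - m) > 1e-6 for m in mids))
        bike = BikeProfile(level_powers=ladder, motor_max=ladder[-1])
        got = quantize_to_level(demand, bike)
        if demand <= 0:
            assert got == 0
            return
        candidates = [0.0] + ladder  # level 0 is motor off
        dists = [abs(demand - c) for c in candidates]
        expected = int(np.argmin(dists))
        assert got == expected


class TestPlanAssist:
    def test_flat_segment_level5_rider_needs_no_assist(self, calibrated_params, bike):
        """At the rider's own rung the flat target speed costs exactly their power."""
        rider = RiderProfile(mass=75, height=1.75, age=30, total_points=220)  # level 5
        plan = plan_assist([_segment(1000.0, 0.0)], rider, bike, calibrated_params)
        sp = plan.segments[0]
        assert sp.required_power == pytest.approx(59.46, abs=0.05)
        assert sp.motor_power == 0.0
        assert sp.assist_level == 0

    def test_climb_quantizes_to_nearest_rung(self, calibrated_params):
        """A 270 W climb for a 59.46 W rider leaves ~210.5 W to the motor: level 4 of {50..300}."""
        rider = RiderProfile(mass=75, height=1.75, age=30, total_points=220)
        bike = BikeProfile(level_powers=[50, 100, 150, 200, 250, 300], motor_max=300)
        # grade chosen so required power at 20 km/h is ~270 W
        grade = (270.0 - 59.46) / (
            calibrated_params.g * calibrated_params.mass * (20 * KMH)
        )
        plan = plan_assist([_segment(800.0, grade)], rider, bike, calibrated_params)
        sp = plan.segments[0]
        assert sp.motor_power == pytest.approx(210.5, abs=0.1)
        assert sp.assist_level == 4

    def test_descent_coasts(self, calibrated_params, bike, rider):
        plan = plan_assist([_segment(500.0, -0.08)], rider, bike, calibrated_params)
        sp = plan.segments[0]
        assert sp.coasting
        assert sp.rider_power == 0.0
        assert sp.motor_power == 0.0
        assert sp.assist_level == 0

    def test_easy_segment_reduces_rider_power(self, calibrated_params, bike, rider):
        """Gentle downhill costing less than p: rider covers it alone, motor off."""
        plan = plan_assist([_segment(500.0, -0.005)], rider, bike, calibrated_params)
        sp = plan.segments[0]
        assert 0 < sp.required_power < 59.46
        assert sp.rider_power == pytest.approx(sp.required_power)
        assert sp.motor_power == 0.0

    def test_unachievable_climb_sags_speed(self, calibrated_params, rider):
        bike = BikeProfile(level_powers=[50, 100, 150], motor_max=150)
        plan = plan_assist([_segment(400.0, 0.12)], rider, bike, calibrated_params)
        sp = plan.segments[0]
        assert sp.speed_sagged
        assert sp.motor_power == 150.0
        assert sp.planned_speed < sp.target_speed
        # at the sagged speed, rider p + full motor covers the demand
        demand = required_power(sp.planned_speed, 0.12, calibrated_params)
        assert demand == pytest.approx(sp.rider_power + sp.motor_power, abs=1e-6)

    def test_legal_cutoff_disables_motor(self, calibrated_params):
        """Above the 25 km/h assistance cutoff the motor must stay off."""
        rider = RiderProfile(mass=75, height=1.75, age=30, total_points=550)  # level 10, 28 km/h
        bike = BikeProfile(motor_max=750)
        plan = plan_assist([_segment(600.0, 0.05)], rider, bike, calibrated_params)
        sp = plan.segments[0]
        assert sp.cutoff_applied
        assert sp.motor_power == 0.0
        assert sp.assist_level == 0

    def test_power_conservation_unclamped(self, calibrated_params, bike, rider):
        plan = plan_assist(
            [_segment(500.0, 0.03), _segment(300.0, 0.05)], rider, bike, calibrated_params
        )
        for sp in plan.segments:
            if not (sp.coasting or sp.speed_sagged or sp.cutoff_applied):
                assert sp.rider_power + sp.motor_power == pytest.approx(sp.required_power)

    def test_steeper_grade_never_lower_level(self, calibrated_params, bike, rider):
        grades = np.linspace(0.0, 0.10, 21)
        plans = [
            plan_assist([_segment(500.0, g)], rider, bike, calibrated_params).segments[0]
            for g in grades
        ]
        levels = [sp.assist_level for sp in plans]
        assert levels == sorted(levels)

    def test_motor_share_non_increasing_up_the_ladder(self, calibrated_params, bike):
        """Climbing the ability ladder never increases the motor's share of the work."""
        segs = [_segment(1000.0, 0.02), _segment(1000.0, 0.05), _segment(500.0, -0.01)]
        shares = []
        for row in DEFAULT_ABILITY_TABLE.rows:
            rider = RiderProfile(mass=75, height=1.75, age=30, total_points=row.points_lo)
            plan = plan_assist(segs, rider, bike, calibrated_params)
            # continuous split, before level quantization
            motor = sum(sp.motor_power * sp.duration_s for sp in plan.segments)
            rider_w = sum(sp.rider_power * sp.duration_s for sp in plan.segments)
            shares.append(motor / (motor + rider_w))
        assert all(b <= a + 1e-9 for a, b in zip(shares, shares[1:]))


class TestWaypoints:
    def _plan_and_route(self, calibrated_params, bike, rider):
        from ebiketrainer import compute_grades, segment_route, synthesize_route

        route = synthesize_route([(600, 0.0), (600, 0.04), (600, -0.03)], step=10,
                                 noise_sd=0.0, seed=2)
        route = compute_grades(route, 0.0)
        segs = segment_route(route)
        plan = plan_assist(segs, rider, bike, calibrated_params, route=route)
        return plan, route

    def test_one_waypoint_per_segment_at_segment_start(self, calibrated_params, bike, rider):
        plan, route = self._plan_and_route(calibrated_params, bike, rider)
        wps = plan_waypoints(plan, route)
        assert len(wps) == len(plan.segments)
        for wp, sp in zip(wps, plan.segments):
            pt = route.points[sp.segment.start_index]
            assert wp["lat"] == pt.latitude and wp["lon"] == pt.longitude
        assert wps[0]["lat"] == route.points[0].latitude

    def test_gpx_round_trip_preserves_levels(self, calibrated_params, bike, rider, tmp_path):
        plan, route = self._plan_and_route(calibrated_params, bike, rider)
        wps = plan_waypoints(plan, route)
        path = tmp_path / "wpts.gpx"
        write_waypoints_gpx(wps, path)
        back = read_waypoints_gpx(path)
        assert [w["level"] for w in back] == [w["level"] for w in wps]
        for a, b in zip(wps, back):
            assert b["lat"] == pytest.approx(a["lat"], abs=1e-6)
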