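"""Segment a hilly route and plan per-segment assist levels.

Builds a synthetic 4 km route (flat, climb, descent), splits it into
constant-slope segments, and plans the motor assist a level-4 rider
(target 19 km/h, constant 53.27 W) needs on each one.
"""

from ebiketrainer import (
    BikeProfile,
    PowerModelParams,
    RiderProfile,
    calibrate_flat_coefficients,
    compute_grades,
    plan_assist,
    segment_route,
    synthesize_route,
)

route = synthesize_route(
    [(1500, 0.0), (1200, 0.05), (1300, -0.035)], step=10, noise_sd=0.5, seed=7
)
route = compute_grades(route, smoothing_window=30.0)
segments = segment_route(route, bin_width=0.02, min_length=50.0)
print(f"route {route.length_m / 1000:.1f} km -> {len(segments)} segments")

coeffs = calibrate_flat_coefficients([(15, 33.19), (28, 129.95)])
params = PowerModelParams.from_flat_coefficients(coeffs)
rider = RiderProfile(mass=75, height=1.75, age=35, total_points=170)  # level 4
bike = BikeProfile(motor_max=750.0)  # six levels: 125, 250, ..., 750 W

plan = plan_assist(segments, rider, bike, params, route=route)
print("\n grade  need W  rider W  motor W  level")
for sp in plan.segments:
    note = "coasting" if sp.coasting else ""
    print(
        f"{sp.segment.grade:+.3f}  {sp.required_power:6.1f}  {sp.rider_power:7.1f}"
        f"  {sp.motor_power:7.1f}  {sp.assist_level:5d}  {note}"
    )
print(
    f"\npredicted: rider {plan.rider_energy_wh:.1f} Wh, motor {plan.motor_energy_wh:.1f} Wh,"
    f" duration {plan.duration_s / 60:.1f} min"
)
# The rider holds ~53 W everywhere; the motor absorbs the climb, stays off
# on the flat, and the descent is coasted (no regeneration).
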