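"""Ride a planned route in simulation and score it.

Full pipeline: synthetic route -> grades -> segments -> assist plan ->
seeded telemetry simulation -> rider-energy scoring -> points accrual.
The score is the rider's integrated energy in Wh (capped at 600), and it
moves them up the ten-level ability ladder.
"""

from ebiketrainer import (
    BehaviorModel,
    BikeProfile,
    PowerModelParams,
    RiderProfile,
    calibrate_flat_coefficients,
    compute_grades,
    evaluate_ride,
    plan_assist,
    segment_route,
    simulate_ride,
    summarize_ride,
    synthesize_route,
)

coeffs = calibrate_flat_coefficients([(15, 33.19), (28, 129.95)])
params = PowerModelParams.from_flat_coefficients(coeffs)
rider = RiderProfile(mass=75, height=1.75, age=35, total_points=140)
bike = BikeProfile(motor_max=750.0)

route = synthesize_route(
    [(3000, 0.0), (2500, 0.04), (2000, -0.03), (2500, 0.02)], step=10, noise_sd=0.5, seed=11
)
route = compute_grades(route, 30.0)
plan = plan_assist(segment_route(route), rider, bike, params, route=route)

behavior = BehaviorModel(speed_tracking_sd=0.25, hr_rest=68, hr_gain=0.45,
                         hr_time_constant=40, seed=42)
telemetry = simulate_ride(plan, bike, params, behavior)
summary = summarize_ride(telemetry)
print(
    f"rode {summary.distance_km:.1f} km in {summary.duration_s / 60:.1f} min"
    f" at {summary.mean_speed_kmh:.1f} km/h"
)
print(f"rider {summary.rider_energy_wh:.1f} Wh, motor {summary.motor_energy_wh:.1f} Wh")

result = evaluate_ride(telemetry, plan, rider, params)
print(
    f"score {result.score:.1f} points -> total {result.new_total_points:.1f},"
    f" ability level {result.new_level}"
)
# Every watt-hour the rider supplied is a point; the motor's share earns
# nothing.  Crossing 151 cumulative points promotes the rider to level 4.
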