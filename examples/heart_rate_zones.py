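"""Heart-rate zones and the safety override on a simulated climb.

Simulates a hard climb for a 42-year-old rider with the pulse-triggered
assist override armed, then reports the time spent in each training zone
(fractions of the age-predicted maximum 205.8 - 0.685*age).
"""

from ebiketrainer import (
    BehaviorModel,
    BikeProfile,
    HRSample,
    PowerModelParams,
    RiderProfile,
    calibrate_flat_coefficients,
    default_threshold,
    hr_max,
    plan_assist,
    simulate_ride,
    time_in_zones,
)
from ebiketrainer.segmentation import Segment

age = 42
hrm = hr_max(age)
threshold = default_threshold(age)
print(f"HRmax {hrm:.2f} bpm, safety threshold {threshold:.1f} bpm (90% of HRmax)")

coeffs = calibrate_flat_coefficients([(15, 33.19), (28, 129.95)])
params = PowerModelParams.from_flat_coefficients(coeffs)
rider = RiderProfile(mass=80, height=1.80, age=age, total_points=320)  # level 7
bike = BikeProfile(motor_max=250.0)  # small city motor, six levels

segs = [Segment(0, 1, 2000.0, 0.0, "+"), Segment(1, 2, 3000.0, 0.06, "+")]
plan = plan_assist(segs, rider, bike, params)
# an unfit rider: a steep heart-rate response to workload
behavior = BehaviorModel(speed_tracking_sd=0.0, hr_rest=70, hr_gain=1.2,
                         hr_time_constant=45, seed=3)
telemetry = simulate_ride(plan, bike, params, behavior, hr_threshold=threshold)

series = [HRSample(float(t), float(b)) for t, b in zip(telemetry.time, telemetry.bpm)]
report = time_in_zones(series, hrm)
print("\nzone fractions:")
for zone, frac in report.fractions.items():
    print(f"  {zone:>5}: {100 * frac:5.1f} %")
print(f"\nassist level over the ride: {telemetry.level.min()} -> {telemetry.level.max()}")
# On the climb the pulse crosses the threshold and the override steps the
# assist level up (one rung per 30 s), trading rider effort for motor power.
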