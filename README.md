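# ebiketrainer

Personalized training on pedal-assist e-bikes. The idea: instead of the
rider picking an assist level, the system picks it for them, segment by
segment, so that the rider's own effort stays constant over any terrain —
the motor absorbs the hills. Completed rides are scored by the energy the
rider (not the motor) supplied, scores accumulate, and a ten-level ability
ladder raises the target speed (and lowers the assistance) as the rider
progresses. The package is for exercise-physiology and digital-health work
that needs this pipeline reproducible end to end without hardware: route
analysis, assist planning, heart-rate zone accounting, ride simulation and
scoring.

## The model

Power to hold ground speed *s* (m/s) on grade *i*:

```
P = kr·M·g·s + ka·A·d·s·v² + g·i·M·s        v = s + headwind
```

with rolling coefficient `kr = 0.005`, total mass `M` (rider + bike),
wind-resistance coefficient `ka = 0.5`, frontal area `A`, air density
`d = 1.226 kg/m³`. On flat, windless ground this is `P = c1·s + c2·s³`
with `c1 = kr·M·g`, `c2 = ka·A·d`; fitting (c1, c2) to the first and last
rungs of the ability ladder reproduces every intermediate rung's printed
flat-road power to within 0.05 W.

Per slope segment the planner computes the power `p_i` that the rider's
target speed `v'` costs, subtracts the rider's constant power `p` (their
ladder rung's flat-road power), and quantizes the remainder `p'_i = p_i − p`
to the bike's discrete assist-level ladder by half-open midpoint intervals
(ties round up). Downhill surpluses coast; demands beyond rider + full
motor sag the speed; assistance is cut above the legal 25 km/h.

A completed ride scores `s_r = min(p_u, 600)` points, where `p_u` is the
rider-supplied energy in Wh, integrated from telemetry as
`Σ max(P(speed, grade) − motor, 0)·Δt`. Heart-rate zones are fractions of
the age-predicted maximum `HRmax = 205.8 − 0.685·age`, and a safety
override raises the assist level one rung (30 s hysteresis) when the pulse
exceeds a threshold (default 90% HRmax).

## Worked example

```python
from ebiketrainer import (calibrate_flat_coefficients, PowerModelParams,
                          RiderProfile, BikeProfile, synthesize_route,
                          compute_grades, segment_route, plan_assist)

coeffs = calibrate_flat_coefficients([(15, 33.19), (28, 129.95)])
print(coeffs.c1, coeffs.c2)        # 4.4468  0.20268
params = PowerModelParams.from_flat_coefficients(coeffs)

route = synthesize_route([(1500, 0.0), (1200, 0.05), (1300, -0.035)],
                         step=10, noise_sd=0.5, seed=7)
route = compute_grades(route, smoothing_window=30.0)
rider = RiderProfile(mass=75, height=1.75, age=35, total_points=170)  # level 4
bike = BikeProfile(motor_max=750.0)    # six levels: 125 ... 750 W
plan = plan_assist(segment_route(route), rider, bike, params, route=route)
```

Running `python examples/plan_a_route.py` prints the per-segment table; on
the 5% climb it reads

```
 grade  need W  rider W  motor W  level
+0.055   309.3     53.3    256.0      2
```

— holding 19 km/h on that pitch costs ≈309 W, the level-4 rider supplies
their constant 53.27 W, and the remaining ≈256 W quantizes to assist
level 2 (250 W). On the flat the motor is off; the descent is coasted.
`examples/simulate_and_score.py` rides a 10 km plan in simulation and
prints `score 25.3 points -> total 165.3, ability level 4`: each
rider-supplied watt-hour is one point.

The same pipeline is scriptable from the shell:

```
ebiketrainer plan  --route route.gpx --config config.yaml --waypoints wpts.gpx
ebiketrainer ride  --route route.gpx --config config.yaml --seed 5
ebiketrainer score --telemetry telemetry.csv --route route.gpx --config config.yaml
ebiketrainer zones --hr hr.csv --config config.yaml
ebiketrainer calibrate --table ladder.tsv
```

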