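# Methods

## The power model and its two calibrations

The steady-state power to hold ground speed *s* on grade *i* is

    P(s, i) = kr·M·g·s + ka·A·d·s·(s + w)² + g·i·M·s

(rolling, aerodynamic, gravitational terms; *w* a signed headwind,
default 0). The rolling term includes the gravitational acceleration *g*:
`kr·M·s` alone is not a power, and only the `kr·M·g·s` form, together with
a cubic aerodynamic term, reproduces the ability ladder's flat-road power
column. Constants: `kr = 0.005`, `ka = 0.5`, `d = 1.226 kg/m³`,
`g = 9.8 m/s²`.

The package exposes two ways to set the remaining parameters:

- **physical mode** — the caller supplies total mass `M` (rider + bike)
  and frontal area `A` (or lets `estimate_frontal_area` derive it from
  height and body mass via a body-surface-area power law anchored at
  0.3307 m² for a 1.75 m / 75 kg rider);
- **table-calibrated mode** — `calibrate_flat_coefficients` fits
  `P = c1·s + c2·s³` to (speed, power) rows of an ability ladder
  (exact 2×2 solve for two rows, least squares otherwise) and
  `PowerModelParams.from_flat_coefficients` back-solves the effective
  `M = c1/(kr·g)` and `A = c2/(ka·d)` so the grade term stays consistent
  with the fitted flat behaviour.

The two modes disagree for the default ladder: the fitted coefficients
imply M ≈ 90.75 kg and A ≈ 0.331 m², not the nominal 83 kg reference
rider. Both modes are kept; the calibrated mode is the default because it
reproduces the ladder's printed powers to < 0.05 W (the level-3 entry is
read as 47.57 W; its source prints the digits without the decimal point).

**Inversion.** `speed_at_power` solves `P(s, i) = P` for the unique
positive root by bracketed root-finding (Brent on [1e-6, 30] m/s, the
bracket doubled upward if ever needed, converged far below 1e-6 W).
Uniqueness: with a = (kr + i)·M·g and b = ka·A·d > 0, a·s + b·s³ is
negative on (0, √(−a/b)) when a < 0 and strictly increasing past the
inflection, so a horizontal line at P > 0 crosses once. For P ≤ 0 the
steady-state model assigns no speed and the function returns a NaN
coasting sentinel; callers treat such segments as coasting.

## Route handling

Tracks are read from GPX 1.1 (`<trkpt lat lon><ele><time>`) or a CSV
dialect `lat,lon,ele[,time]` (ISO-8601 or epoch seconds). Consecutive
points closer than 0.1 m are collapsed; a missing elevation is a hard
error naming the point index. Distances are haversine on a sphere of
radius 6371008.8 m — sub-metre geodesic corrections are irrelevant at
10–100 m step lengths. Grades are rise over run per inter-point step,
computed after a centred moving-average smoothing of elevations over a
30 m window (default): consumer GPS elevation noise of ~1 m per point
otherwise dominates 10 m-step grades. A window of 0 disables smoothing.
Grades are clipped to ±0.35; steeper values on a rideable route are
artefacts.

## Segmentation

Two passes over the step grades:

1. **Signed magnitude binning.** Each step falls in bin
   sign(g)·⌈|g|/w⌉ with width w (default 0.02); bins are half-open toward
   zero, so a grade exactly on an edge joins the lower-magnitude bin (with
   ~1e-6 relative tolerance so floating-point jitter cannot flip a step
   sitting on an edge). Adjacent same-bin steps merge. Zero-grade runs
   attach to the neighbouring run with the smaller mean |grade|, ties to
   the preceding run.
2. **Short-run absorption.** Runs shorter than `min_length` (default
   50 m) are folded, shortest first, into the neighbour whose mean grade
   is nearer; repeated until all runs qualify or one remains.

Each segment carries the length-weighted mean of its step grades and a
sign. Segments partition the route's steps exactly; adjacent segments
share their boundary track point. The procedure is deliberately
transparent — a greedy scan, no penalized changepoint machinery — and the
test suite holds it equal to an independent brute-force implementation on
randomized profiles. Defaults give mean segment lengths of roughly
50–100 m on noisy rolling terrain.

## Assist planning

The rider's cumulative points select an ability rung: target speed v'
(15–28 km/h) and constant rider power p (33.19–129.95 W). Per segment:

- required power `p_i = P(v', g_i)`;
- motor share `p'_i = p_i − p`, clamped to [0, motor_max];
- `p_i ≤ 0` → coasting (rider 0, motor 0; no regeneration — these are
  pedal-assist drivetrains);
- `0 < p_i < p` → the rider alone covers it (`rider = p_i`, motor 0);
- `p'_i > motor_max` → speed sags to `speed_at_power(p + motor_max, g_i)`;
  both the target and the achievable speed are recorded;
- any segment planned faster than the legal cutoff (default 25 km/h)
  gets motor 0.

The continuous motor share quantizes to the bike's level ladder by
half-open midpoint intervals — level j wins on
[(p_{j−1}+p_j)/2, (p_j+p_{j+1})/2), below p_1/2 the motor is off, exact
midpoints round up — which is equivalent to nearest-rung assignment with
ties up. The plan's predicted energies use the *quantized* delivery
(level power, but never more than the instantaneous demand), so a
noise-free simulation of the plan reproduces the predicted rider energy;
the continuous split is kept alongside for the power-conservation
invariant. Per-level powers default to six rungs evenly spaced up to
motor_max, matching a common 750 W six-level configuration, and are
overridable per bike since real level/power maps vary by battery and
controller.

## Heart rate

`HRmax = 205.8 − 0.685·age` (bpm), valid for ages 10–100; an approximate
population formula, not an individual measurement. Zones as fractions of
HRmax: Z1 [50%, 70%), Z2 [70%, 80%), Z3 [80%, 90%), Z4 [90%, ∞), plus a
"below" bucket. The conventional zone table leaves 60–70% unassigned;
here Z1 covers it so the scale partitions, and the zone report carries a
note saying so. Time in zone weights each inter-sample interval by the
zone of its left sample, so reported fractions are exact up to one sample
interval per transition and always sum to 1.

The safety override raises the assist level one rung when the pulse
exceeds a threshold (default 0.9·HRmax, user-overridable), never lowers
it, caps at the bike's top level, and enforces a 30 s hysteresis between
automatic increases. The step size and hysteresis are design choices: the
underlying requirement fixes only the direction (more assistance when the
pulse is too high), and a one-rung step per 30 s bounds the rate of
workload change without oscillation.

## Scoring

Rider energy over a ride integrates
`max(P(speed_k, grade_k) − motor_k, 0)·Δt` on the telemetry grid
(left-rectangle; at 1 s sampling the rectangle-vs-trapezoid difference is
far below the 0.5 Wh bookkeeping tolerance), where `grade_k` is the grade
of the plan segment containing the sample. The score is that energy in
Wh capped at 600 per route. Scoring energy (Wh) rather than power (W)
follows the system's own worked accounting (a 30 Wh rider share scores 30
points); the 600 figure corresponds to roughly an hour at 50 km/h on the
flat — an upper bound on human output per ride. The cap is per route.
Negative instantaneous rider power contributes zero — coasting is never
penalized. Scores accrue to `total_points`; the ability level is always
re-derived from the ladder, so it is monotone non-decreasing.

## Simulator

The simulator is first-class, tested code: it exists so planning, zone
accounting, the override and scoring can be exercised end to end, with
known ground truth, without hardware. Per sample (default Δt = 1 s):

- realized speed = segment's planned speed + Gaussian noise
  (`speed_tracking_sd`, default 0.3 m/s, truncated at 0; a rider holds a
  target within about ±1 km/h);
- motor = active level's power, but never more than the instantaneous
  demand `max(P(v, g), 0)` (pedal assist does not accelerate the bike
  beyond the terrain's requirement); rider = demand − motor, floored at 0;
- heart rate relaxes first-order toward `hr_rest + hr_gain·rider_power`
  (defaults 65 bpm, 0.45 bpm/W, τ = 40 s — resting-to-hard ranges typical
  of a moderately fit adult; the first-order shape captures the
  exponential on/off kinetics of exercise HR, not individual variability);
- with a threshold set, the override may bump the active level above the
  planned one.

All randomness comes from one seeded generator; identical seeds give
byte-identical telemetry. What the simulator does *not* model: stops and
traffic, cadence-gated assist engagement, fatigue drift, battery
depletion, GPS position error on the realized track. Passing end-to-end
tests therefore demonstrate internal consistency of planner + scorer
under the stated behaviour model, not fidelity to any particular human
rider.

## Sizes and tolerances

Synthetic test routes are 1–15 km at 10–100 m point spacing; simulations
run minutes-to-an-hour of ride time at 1 s sampling; property suites use
10⁴ quantizer cases and 100 random segmentation profiles. Root-finding
converges to machine precision; inverse-model round trips are asserted to
1e-9 m/s; energy recoveries to 1%; zone bookkeeping to one sample
interval. The acceptance script's capped-score fixture is a 3 h constant
300 W telemetry trace (900 Wh), comfortably beyond the 600 cap.

## Known limitations

- The power model is steady-state: no inertia, so short segments under a
  rider changing speed are approximated by their plateau cost.
- Drivetrain and motor efficiency are not modelled; "motor power" is
  power at the wheel.
- The segmentation is greedy and local; a penalized least-squares
  changepoint method would be more principled but is deliberately out of
  scope.
- The ability ladder's printed flat powers embed an effective rider
  (≈91 kg, 0.331 m²) that differs from the nominal 83 kg reference; both
  calibrations are available and the discrepancy is surfaced, not hidden.
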