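"""Steady-state cycling power model and its calibration.

The power needed to hold a ground speed s (m/s) on a grade i is

    P = k_r * M * g * s  +  k_a * A * d * s * (s + w)**2  +  g * i * M * s

with rolling coefficient k_r, total mass M (rider + bike), aerodynamic
coefficient k_a, frontal area A, air density d and signed headwind w.
On flat ground with no wind this collapses to P = c1*s + c2*s**3 with
c1 = k_r*M*g and c2 = k_a*A*d, which is how the model is calibrated
against an ability table's speed/power column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

GRAVITY = 9.8
DEFAULT_ROLLING_COEFF = 0.005
DEFAULT_WIND_COEFF = 0.5
DEFAULT_AIR_DENSITY = 1.226

#: returned by speed_at_power when the model assigns no speed (power <= 0,
#: i.e. coasting on a descent); callers decide what a coasting rider does
COASTING = float("nan")

KMH = 1 / 3.6  # m/s per km/h


@dataclass(frozen=True)
class FlatRoadCoefficients:
    """Flat-road regrouping: P = c1*s + c2*s^3, c1 in W/(m/s), c2 in W/(m/s)^3."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("flat-road coefficients must be positive")

    def power(self, speed: float) -> float:
        return self.c1 * speed + self.c2 * speed**3


@dataclass(frozen=True)
class PowerModelParams:
    """Physical parameters of the power equation.

    ``headwind`` is signed in m/s, positive opposing motion.  ``mass`` is
    rider plus bike.  ``frontal_area`` covers rider plus bike, typically
    0.3-0.6 m^2 for an upright cyclist.
    """

    mass: float
    frontal_area: float
    k_r: float = DEFAULT_ROLLING_COEFF
    k_a: float = DEFAULT_WIND_COEFF
    air_density: float = DEFAULT_AIR_DENSITY
    g: float = GRAVITY
    headwind: float = 0.0

    def __post_init__(self) -> None:
        if not 40.0 <= self.mass <= 200.0:
            raise ValueError(f"total mass {self.mass} kg outside [40, 200]")
        if not 0.2 <= self.frontal_area <= 1.0:
            raise ValueError(f"frontal area {self.frontal_area} m^2 outside [0.2, 1.0]")
        for name in ("k_r", "k_a", "air_density", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def c1(self) -> float:
        return self.k_r * self.mass * self.g

    @property
    def c2(self) -> float:
        return self.k_a * self.frontal_area * self.air_density

    @classmethod
    def from_flat_coefficients(cls, coeffs: FlatRoadCoefficients, **kwargs) -> "PowerModelParams":
        """Build params whose flat-road behaviour matches fitted (c1, c2).

        Mass and frontal area are back-solved from the coefficients, so the
        grade term uses the effective mass the calibration implies rather
        than a separately stated rider weight.
        """
        k_r = kwargs.pop("k_r", DEFAULT_ROLLING_COEFF)
        k_a = kwargs.pop("k_a", DEFAULT_WIND_COEFF)
        d = kwargs.pop("air_density", DEFAULT_AIR_DENSITY)
        g = kwargs.pop("g", GRAVITY)
        return cls(
            mass=coeffs.c1 / (k_r * g),
            frontal_area=coeffs.c2 / (k_a * d),
            k_r=k_r, k_a=k_a, air_density=d, g=g, **kwargs,
        )


def required_power(speed: float, grade: float, params: PowerModelParams) -> float:
    """Total power (W) to hold ``speed`` m/s on ``grade``; negative on descents."""
    if speed < 0:
        raise ValueError("speed must be >= 0")
    s = speed
    v = s + params.headwind
    rolling = params.k_r * params.mass * params.g * s
    aero = params.k_a * params.frontal_area * params.air_density * s * v**2
    climb = params.g * grade * params.mass * s
    return rolling + aero + climb


_SPEED_HI = 30.0  # m/s; above any legal e-bike speed


def speed_at_power(power: float, grade: float, params: PowerModelParams) -> float:
    """Invert the power equation: the positive speed at which ``power`` is absorbed.

    For positive power the root is unique: with a = (k_r + grade)*M*g and
    b = k_a*A*d (no wind) the curve a*s + b*s^3 is strictly increasing past
    sqrt(-a/(3b)) and below zero before its positive zero when a < 0, so a
    horizontal line at P > 0 crosses it exactly once.  Solved by bracketed
    root-finding to |dP| well below 1e-6 W.  ``power <= 0`` returns the
    COASTING sentinel (the steady-state model assigns no speed).
    """
    if power <= 0:
        return COASTING
    lo = 1e-6
    hi = _SPEED_HI
    f = lambda s: required_power(s, grade, params) - power
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("no finite speed absorbs this power")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def calibrate_flat_coefficients(
    rows: Sequence[tuple[float, float]]
) -> FlatRoadCoefficients:
    """Least-squares fit of P = c1*s + c2*s^3 to (speed km/h, power W) rows.

    With exactly two rows this is the exact 2x2 solve.  Speeds must be
    distinct or the system is singular.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 (speed, power) rows")
    speeds = np.array([r[0] for r in rows]) * KMH
    powers = np.array([r[1] for r in rows])
    if len(set(np.round(speeds, 12))) < 2:
        raise ValueError("calibration rows must have at least 2 distinct speeds")
    X = np.column_stack([speeds, speeds**3])
    coef, *_ = np.linalg.lstsq(X, powers, rcond=None)
    return FlatRoadCoefficients(c1=float(coef[0]), c2=float(coef[1]))


def estimate_frontal_area(height: float, mass: float) -> float:
    """Frontal area (m^2) of rider + bike from height (m) and body mass (kg).

    A body-surface-area style power law anchored so a 1.75 m, 75 kg rider
    has the 0.3307 m^2 area the flat-road calibration implies.
    """
    if not 1.2 <= height <= 2.2:
        raise ValueError(f"height {height} m outside [1.2, 2.2]")
    if not 35.0 <= mass <= 150.0:
        raise ValueError(f"mass {mass} kg outside [35, 150]")
    return 0.3307 * (height / 1.75) ** 0.725 * (mass / 75.0) ** 0.425
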