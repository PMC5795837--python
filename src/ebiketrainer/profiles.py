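"""Rider and bike profiles."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence


@dataclass(frozen=True)
class RiderProfile:
    """A rider: body parameters plus the cumulative training score.

    ``total_points`` drives the ability ladder; ``hr_threshold`` (bpm), if
    set, arms the heart-rate safety override during simulated rides.
    """

    mass: float
    height: float
    age: float
    total_points: float = 0.0
    hr_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 35.0 <= self.mass <= 150.0:
            raise ValueError(f"rider mass {self.mass} kg outside [35, 150]")
        if not 1.2 <= self.height <= 2.2:
            raise ValueError(f"rider height {self.height} m outside [1.2, 2.2]")
        if not 10.0 <= self.age <= 100.0:
            raise ValueError(f"rider age {self.age} outside [10, 100]")
        if self.total_points < 0:
            raise ValueError("total points must be >= 0")


def default_level_powers(motor_max: float, n_levels: int = 6) -> tuple[float, ...]:
    """Evenly spaced per-level motor powers up to the motor maximum."""
    return tuple(motor_max * (j + 1) / n_levels for j in range(n_levels))


@dataclass(frozen=True)
class BikeProfile:
    """An e-bike: mass, the assist-level power ladder, and the legal cutoff.

    ``level_powers[j-1]`` is the motor power of assist level j (level 0 is
    motor off); assistance is cut above ``legal_speed_cutoff`` km/h.
    """

    bike_mass: float = 8.0
    level_powers: Optional[Sequence[float]] = None
    motor_max: float = 750.0
    legal_speed_cutoff: float = 25.0

    def __post_init__(self) -> None:
        if self.level_powers is None:
            object.__setattr__(self, "level_powers", default_level_powers(self.motor_max))
        powers = tuple(float(p) for p in self.level_powers)
        object.__setattr__(self, "level_powers", powers)
        if not powers:
            raise ValueError("bike must have at least one assist level")
        if any(b <= a for a, b in zip(powers, powers[1:])):
            raise ValueError("level powers must be strictly increasing")
        if powers[-1] > self.motor_max:
            raise ValueError("level powers cannot exceed motor_max")
        if self.bike_mass <= 0:
            raise ValueError("bike mass must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.level_powers)

    def power_of_level(self, level: int) -> float:
        """Motor power of an assist level; level 0 is off."""
        if level == 0:
            return 0.0
        return self.level_powers[level - 1]
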