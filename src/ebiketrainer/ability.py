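"""The ten-rung ability ladder: points -> target speed and flat-road power.

Each rung maps a cumulative-points interval to the average speed the rider
is asked to hold and the constant power they are expected to supply (the
power that exact speed costs on flat ground for the reference rider).  As
points accrue, both rise, so the motor's share of any given route shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .power_model import KMH


@dataclass(frozen=True)
class AbilityRow:
    level: int
    target_speed_kmh: float
    points_lo: float
    points_hi: float
    flat_power_w: float

    @property
    def target_speed_ms(self) -> float:
        return self.target_speed_kmh * KMH


@dataclass(frozen=True)
class AbilityTable:
    """Ordered ability rungs with contiguous, non-overlapping point intervals."""

    rows: tuple[AbilityRow, ...]

    def __post_init__(self) -> None:
        speeds = [r.target_speed_kmh for r in self.rows]
        if sorted(speeds) != speeds or len(set(speeds)) != len(speeds):
            raise ValueError("target speeds must be strictly increasing")
        for a, b in zip(self.rows, self.rows[1:]):
            if b.points_lo != a.points_hi + 1:
                raise ValueError("point intervals must be contiguous")

    @property
    def top_level(self) -> int:
        return self.rows[-1].level

    def row_for_points(self, total_points: float) -> AbilityRow:
        if total_points < 0:
            raise ValueError("total points must be >= 0")
        for row in self.rows:
            if row.points_lo <= total_points <= row.points_hi:
                return row
        return self.rows[-1]  # beyond the ladder: clamp to the top rung

    def row_for_level(self, level: int) -> AbilityRow:
        for row in self.rows:
            if row.level == level:
                return row
        raise KeyError(f"no ability level {level}")


# level, target speed km/h, points interval, flat-road power W
_DEFAULT_ROWS: Sequence[tuple[int, float, float, float, float]] = [
    (1, 15, 0, 50, 33.19),
    (2, 17, 51, 100, 42.35),
    (3, 18, 101, 150, 47.57),
    (4, 19, 151, 200, 53.27),
    (5, 20, 201, 250, 59.46),
    (6, 21, 251, 300, 66.17),
    (7, 23, 301, 350, 81.27),
    (8, 25, 351, 400, 98.76),
    (9, 26, 401, 500, 108.47),
    (10, 28, 501, 600, 129.95),
]

DEFAULT_ABILITY_TABLE = AbilityTable(
    rows=tuple(AbilityRow(lvl, v, lo, hi, p) for lvl, v, lo, hi, p in _DEFAULT_ROWS)
)


def ability_for_points(
    total_points: float, table: AbilityTable = DEFAULT_ABILITY_TABLE
) -> tuple[int, float, float]:
    """(level, target speed km/h, constant rider power W) for a points total."""
    row = table.row_for_points(total_points)
    return row.level, row.target_speed_kmh, row.flat_power_w
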