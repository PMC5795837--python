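"""YAML run configuration, validated strictly (unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .ability import DEFAULT_ABILITY_TABLE, AbilityTable
from .power_model import (
    DEFAULT_AIR_DENSITY,
    DEFAULT_ROLLING_COEFF,
    DEFAULT_WIND_COEFF,
    FlatRoadCoefficients,
    PowerModelParams,
    calibrate_flat_coefficients,
    estimate_frontal_area,
)
from .profiles import BikeProfile, RiderProfile
from .simulator import BehaviorModel


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RiderConfig(_Strict):
    mass: float
    height: float
    age: float
    total_points: float = 0.0
    hr_threshold: Optional[float] = None


class BikeConfig(_Strict):
    bike_mass: float = 8.0
    level_powers: Optional[list[float]] = None
    motor_max: float = 750.0
    legal_speed_cutoff: float = 25.0


class PowerModelConfig(_Strict):
    # "table" calibrates (c1, c2) on the ability ladder's flat-power column;
    # "physical" builds the equation from rider mass and frontal area
    mode: str = "table"
    k_r: float = DEFAULT_ROLLING_COEFF
    k_a: float = DEFAULT_WIND_COEFF
    air_density: float = DEFAULT_AIR_DENSITY
    headwind: float = 0.0
    frontal_area: Optional[float] = None


class SegmentationConfig(_Strict):
    bin_width: float = 0.02
    min_length: float = 50.0
    smoothing_window: float = 30.0


class SimulatorConfig(_Strict):
    speed_tracking_sd: float = 0.3
    hr_rest: float = 65.0
    hr_gain: float = 0.45
    hr_time_constant: float = 40.0
    seed: int = 0
    dt: float = 1.0


class RunConfig(_Strict):
    rider: RiderConfig
    bike: BikeConfig = BikeConfig()
    power_model: PowerModelConfig = PowerModelConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    simulator: SimulatorConfig = SimulatorConfig()


def load_config(path: str | Path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def build_rider(cfg: RunConfig) -> RiderProfile:
    r = cfg.rider
    return RiderProfile(mass=r.mass, height=r.height, age=r.age,
                        total_points=r.total_points, hr_threshold=r.hr_threshold)


def build_bike(cfg: RunConfig) -> BikeProfile:
    b = cfg.bike
    kwargs = dict(bike_mass=b.bike_mass, motor_max=b.motor_max,
                  legal_speed_cutoff=b.legal_speed_cutoff)
    if b.level_powers is not None:
        kwargs["level_powers"] = b.level_powers
    return BikeProfile(**kwargs)


def build_power_params(
    cfg: RunConfig, ability: AbilityTable = DEFAULT_ABILITY_TABLE
) -> PowerModelParams:
    pm = cfg.power_model
    if pm.mode == "table":
        rows = [(r.target_speed_kmh, r.flat_power_w) for r in ability.rows]
        coeffs = calibrate_flat_coefficients(rows)
        return PowerModelParams.from_flat_coefficients(
            coeffs, k_r=pm.k_r, k_a=pm.k_a, air_density=pm.air_density,
            headwind=pm.headwind,
        )
    if pm.mode == "physical":
        area = pm.frontal_area
        if area is None:
            area = estimate_frontal_area(cfg.rider.height, cfg.rider.mass)
        return PowerModelParams(
            mass=cfg.rider.mass + cfg.bike.bike_mass, frontal_area=area,
            k_r=pm.k_r, k_a=pm.k_a, air_density=pm.air_density,
            headwind=pm.headwind,
        )
    raise ConfigError(f"power_model.mode must be 'table' or 'physical', got {pm.mode!r}")


def build_behavior(cfg: RunConfig, seed: Optional[int] = None) -> BehaviorModel:
    s = cfg.simulator
    return BehaviorModel(
        speed_tracking_sd=s.speed_tracking_sd, hr_rest=s.hr_rest,
        hr_gain=s.hr_gain, hr_time_constant=s.hr_time_constant,
        seed=s.seed if seed is None else seed,
    )
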