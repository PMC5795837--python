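import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from ebiketrainer import (
    DEFAULT_ABILITY_TABLE,
    BikeProfile,
    PowerModelParams,
    RiderProfile,
    calibrate_flat_coefficients,
)

#: the ability ladder's (speed km/h, flat power W) column
ABILITY_ROWS = [(r.target_speed_kmh, r.flat_power_w) for r in DEFAULT_ABILITY_TABLE.rows]


@pytest.fixture(scope="session")
def calibrated_coeffs():
    """Flat-road coefficients fitted exactly to the first and last ladder rows."""
    return calibrate_flat_coefficients([ABILITY_ROWS[0], ABILITY_ROWS[-1]])


@pytest.fixture(scope="session")
def calibrated_params(calibrated_coeffs):
    """Power-model parameters whose flat-road behaviour matches the ladder."""
    return PowerModelParams.from_flat_coefficients(calibrated_coeffs)


@pytest.fixture
def rider():
    return RiderProfile(mass=75.0, height=1.75, age=30.0, total_points=220.0)


@pytest.fixture
def bike():
    # six evenly spaced levels on a 750 W motor
    return BikeProfile(bike_mass=8.0, motor_max=750.0)
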