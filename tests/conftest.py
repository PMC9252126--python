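import numpy as np
import pytest

from streambem import (
    AirWaterModel,
    SimulationSettings,
    SyntheticConfig,
    fixture_params,
)


@pytest.fixture(scope="session")
def params():
    return fixture_params()


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings()


@pytest.fixture(scope="session")
def air_water():
    return AirWaterModel(
        lower_asymptote=0.8, upper_asymptote=32.0, inflection=15.0, steepness=0.14
    )


@pytest.fixture(scope="session")
def small_synth_config():
    """A 20-reach world small enough for per-test projection."""
    return SyntheticConfig(n_reaches=20, seed=7, validation_n_reaches=3,
                           validation_n_years=2)


@pytest.fixture
def sine_temps():
    """A plausible annual water-temperature cycle (winter ~8, summer ~23)."""
    d = np.arange(1, 366)
    return 15.5 + 7.5 * np.sin(2 * np.pi * (d - 105) / 365)
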