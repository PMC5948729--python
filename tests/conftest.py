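import numpy as np
import pytest

from ricekey import default_crop_parameters, run_simulation
from ricekey.synthetic import (REFERENCE_F, STRESSED_F, generate_weather)

SEASON_START = 170
SEASON_DAYS = 100


@pytest.fixture(scope="session")
def weather():
    return generate_weather(SEASON_DAYS, SEASON_START, seed=0)


@pytest.fixture(scope="session")
def params():
    return default_crop_parameters()


@pytest.fixture(scope="session")
def sim_reference(weather, params):
    """Season run of the near-clean reference zone."""
    return run_simulation(weather, params, REFERENCE_F, SEASON_START, SEASON_DAYS)


@pytest.fixture(scope="session")
def sim_stressed(weather, params):
    """Season run of the polluted zone."""
    return run_simulation(weather, params, STRESSED_F, SEASON_START, SEASON_DAYS)


@pytest.fixture(scope="session")
def sim_unstressed(weather, params):
    return run_simulation(weather, params, 1.0, SEASON_START, SEASON_DAYS)
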