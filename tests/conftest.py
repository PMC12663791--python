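from datetime import datetime, timezone

import pytest

from osmolimit.diffusion import ModelConfig, NutrientField
from osmolimit.physchem import SeawaterState
from osmolimit.synthetic import CruiseScenario, simulate_cruise


@pytest.fixture(scope="session")
def scenario():
    return CruiseScenario(seed=7)


@pytest.fixture(scope="session")
def cruise(scenario):
    """One synthetic cruise shared across tests (deterministic under seed 7)."""
    return simulate_cruise(scenario)


@pytest.fixture
def warm_state():
    return SeawaterState(temperature=20.0, salinity=35.0)


@pytest.fixture
def model_config():
    return ModelConfig()


def make_field(nh4=0.0, no2=0.0, no3=0.0, dip=0.0, urea=None):
    return NutrientField(ammonium=nh4, nitrite=no2, nitrate=no3, phosphate=dip, urea=urea)


@pytest.fixture
def utc_now():
    return datetime(2021, 2, 1, tzinfo=timezone.utc)
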