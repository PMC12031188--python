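import pytest

from dustrisk import (
    PM10,
    PM25,
    AtmosphericState,
    StockpileScenario,
)
from dustrisk.dispersion import CLASS_D_SCHEME


@pytest.fixture(scope="session")
def scenario():
    """Default study scenario: U=2 m/s, M=30 %, eta=0.5, V=500 m^3/h, h=15 m."""
    return StockpileScenario()


@pytest.fixture(scope="session")
def atm():
    return AtmosphericState()


@pytest.fixture(scope="session")
def scheme():
    return CLASS_D_SCHEME


@pytest.fixture(scope="session")
def pm25():
    return PM25


@pytest.fixture(scope="session")
def pm10():
    return PM10
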