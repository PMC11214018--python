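import numpy as np
import pytest

from brantsim import EelgrassParams, EnergeticsParams, YearScenario
from brantsim.synthetic_data import SynthConfig, gen_bay


@pytest.fixture(scope="session")
def small_bay():
    """A 12-patch bay spanning the intertidal range."""
    return gen_bay(SynthConfig(seed=11, n_patches=12))


@pytest.fixture(scope="session")
def default_bay():
    return gen_bay(SynthConfig(seed=7))


@pytest.fixture
def small_params():
    """Default energetics scaled down to a handful of flocks for fast runs."""
    return EnergeticsParams(fall_population=1000, spring_population=1000)


@pytest.fixture
def eelgrass():
    return EelgrassParams()


def make_scenario(jan_biomass=80.0, winter_population=2000.0, **kw):
    return YearScenario(year=2000, jan_biomass=jan_biomass,
                        winter_population=winter_population, **kw)


@pytest.fixture
def rich_scenario():
    """Food-sufficient conditions: biomass well above any limitation."""
    return make_scenario(jan_biomass=300.0)
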