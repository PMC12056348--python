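import numpy as np
import pytest

from ectogradient.config import SiteSpec, StudyConfig
from ectogradient.microclimate import WeatherGenParams, generate_site_weather
from ectogradient.species import default_species


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def muralis(species):
    return species["P. muralis"]


@pytest.fixture(scope="session")
def horvathi(species):
    return species["I. horvathi"]


@pytest.fixture()
def small_cfg():
    """Short (2-year) study configuration for fast lifecycle tests."""
    return StudyConfig(n_years=2, rng_seed=7)


@pytest.fixture()
def nonoise_gp():
    return WeatherGenParams(ar1_sigma=0.0)


@pytest.fixture(scope="session")
def lowland_site():
    return SiteSpec("testsite", 45.75, 14.5, 300.0, "syntopy")


@pytest.fixture(scope="session")
def lowland_weather(lowland_site):
    """Two noisy years of hourly weather at a lowland test site."""
    cfg = StudyConfig(n_years=2, rng_seed=7)
    return generate_site_weather(lowland_site, WeatherGenParams(), cfg, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
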