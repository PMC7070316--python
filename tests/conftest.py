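import numpy as np
import pytest
from hypothesis import settings

from dsmtools.projection import Projection

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from dsmtools.synthetic import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def proj() -> Projection:
    return Projection.for_bounds(35.0, 39.0, 10.0, 15.0)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A reduced survey (~1/3 the reference effort) for fast unit tests."""
    return SimulationConfig(
        seed=42,
        region_km=(200.0, 200.0),
        zigzag_spacing_km=25.0,
        log_density0=-2.6,
    )


@pytest.fixture(scope="session")
def small_survey(small_sim_config):
    return simulate_survey(small_sim_config)


@pytest.fixture(scope="session")
def survey_dir(small_survey, tmp_path_factory):
    """The small survey written out in the on-disk exchange formats."""
    d = tmp_path_factory.mktemp("survey")
    small_survey.write(d)
    return d


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
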