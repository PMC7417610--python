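import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from anisokin.pipeline import GenotypeInput, analyse_genotype
from anisokin.profiles import SmoothedProfile
from anisokin.simdata import SimConfig, SteadyStateModel, simulate_growth_zone


@pytest.fixture(scope="session")
def study_config():
    """Simulator defaults at the reference seed used throughout the suite."""
    return dataclasses.replace(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def study_model(study_config):
    return SteadyStateModel(study_config)


@pytest.fixture(scope="session")
def study_truth(study_model):
    return study_model.ground_truth()


@pytest.fixture(scope="session")
def study_dataset(study_config):
    return simulate_growth_zone(study_config)


@pytest.fixture(scope="session")
def study_result(study_config):
    """Full pipeline analysis of the default synthetic wild type."""
    return analyse_genotype(GenotypeInput(name="wt", sim=study_config))


@pytest.fixture
def ramp_profile():
    """Linear ramp 0 -> 100 over [0, 20] mm, then flat at 100 out to 40 mm."""
    grid = np.arange(0.0, 41.0)
    return SmoothedProfile(
        grid=grid, mean=np.minimum(grid * 5.0, 100.0), se=np.zeros_like(grid)
    )
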