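import numpy as np
import pytest

from taclss.cohort_sim import SimulationConfig, simulate_cohort
from taclss.pk_exposure import exposure_table


@pytest.fixture(scope="session")
def default_cohort():
    """One default 51-patient cohort (seed 0) shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_exposure(default_cohort):
    return exposure_table(default_cohort.metadata, default_cohort.concentrations)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
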