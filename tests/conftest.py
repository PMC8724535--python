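import numpy as np
import pytest

from ppdprs.ppd import LikelihoodRatioTable
from ppdprs.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def lr_table() -> LikelihoodRatioTable:
    return LikelihoodRatioTable.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300 x 800 synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_individuals=300, n_variants=800, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
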