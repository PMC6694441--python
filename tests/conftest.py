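import numpy as np
import pytest

from taunet import load_aal90
from taunet.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return load_aal90()


def small_config(**overrides) -> SimulationConfig:
    """A 4-group config small enough for fast end-to-end tests."""
    sizes = {"A4-T-": 20, "A4+T+": 15, "A4+T-": 15, "A4-T+": 15}
    base = dict(group_sizes=sizes)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(small_config(), seed=42)
    return cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(SimulationConfig(), seed=7)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)
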