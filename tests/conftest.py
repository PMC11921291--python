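import numpy as np
import pytest

from dhmeta.model import ParameterState, StudyTable
from dhmeta.simulate import SimulationScenario, simulate_dataset


def random_table(rng: np.random.Generator, n: int = 8) -> StudyTable:
    """A valid random study table for property tests."""
    return StudyTable.from_arrays(
        theta_hat=rng.normal(0, 2, n),
        gamma_hat=rng.normal(0, 2, n),
        sigma=rng.uniform(0.2, 1.5, n),
        delta=rng.uniform(0.2, 1.5, n),
        rho=rng.uniform(-0.9, 0.9, n),
    )


def random_params(rng: np.random.Generator, n: int) -> ParameterState:
    return ParameterState(
        alpha=rng.normal(),
        beta=rng.normal(),
        tau2=rng.uniform(0, 2),
        gammas=rng.normal(0, 2, n),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


@pytest.fixture
def scenario_table():
    """One n=20 data set from the tau2=1, beta=0.8, rho=0 scenario."""
    scenario = SimulationScenario(beta=0.8, rho=0.0, tau2=1.0, alpha=0.0, base_seed=42)
    return simulate_dataset(scenario, 0)
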