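import numpy as np
import pytest

from effortpain.inference.fit import SamplerConfig, fit_model
from effortpain.synthetic_data import (
    AgentPopulationConfig,
    sample_population,
    simulate_dataset,
)
from effortpain.task_design import generate_schedule
from effortpain.value_models import ModelSpec


@pytest.fixture(scope="session")
def schedule150():
    return generate_schedule(75, seed=101)


@pytest.fixture(scope="session")
def schedule50():
    return generate_schedule(25, seed=7)


@pytest.fixture(scope="session")
def small_population():
    """12 agents from the default parabolic 2-kappa/1-beta population."""
    config = AgentPopulationConfig(
        n_subjects=12, model=ModelSpec.from_name("parabolic_2k1b"), seed=7
    )
    return config, sample_population(config)


@pytest.fixture(scope="session")
def small_data(small_population, schedule150):
    config, agents = small_population
    return simulate_dataset(agents, schedule150, config, seed=13)


@pytest.fixture(scope="session")
def small_fit(small_data):
    """A reduced-scale but real NUTS fit shared across test modules."""
    return fit_model(
        small_data,
        ModelSpec.from_name("parabolic_2k1b"),
        sampler=SamplerConfig(n_chains=2, n_warmup=300, n_samples=300, seed=99),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
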