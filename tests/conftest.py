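import numpy as np
import pytest

from culturesim import PayoffPool, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_pool():
    return PayoffPool(np.array([3, 1, 10, 6, 4]))


def make_config(**overrides) -> SimulationConfig:
    defaults = dict(
        payoff_bias=0.2,
        learner_type="maintainer",
        error_rate=0.02,
        pool_size=100,
        population_size=10,
        n_steps=200,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def config_factory():
    return make_config
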