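import numpy as np
import pytest

from bofs import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_linear_dataset():
    """A modest linear-model dataset with strong, known signals."""
    return simulate_dataset(
        SimulationConfig(n=200, p=100, p0=10, effect_model="linear", seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
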