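import numpy as np
import pytest

from lgtratchet import FitnessModel, PopulationState, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return SimulationParams(N=10, g=5, mu=0.01, lambda_lgt=0.2, L=2,
                            generations=50, seed=7)


@pytest.fixture
def uniform_fm():
    return FitnessModel.uniform(5, 1e-3)


def make_state(counts, generation=0):
    return PopulationState(np.asarray(counts, dtype=np.int64), generation)
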