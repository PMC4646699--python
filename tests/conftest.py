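import numpy as np
import pytest

from agape import Recording, validation_params
from agape.likelihood import Workspace
from agape.simulator import simulate


@pytest.fixture(scope="session")
def truth():
    return validation_params()


@pytest.fixture(scope="session")
def small_sim(truth):
    """20 s simulated recording at the validation parameters."""
    return simulate(truth, 20_000, 1.0, seed=101)


@pytest.fixture(scope="session")
def small_rec(small_sim) -> Recording:
    return small_sim.recording


@pytest.fixture(scope="session")
def small_ws(small_rec):
    return Workspace(small_rec, 60)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
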