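import numpy as np
import pytest

from metaniche import ModelParams, MutationParams, TumorState, published_defaults


@pytest.fixture
def published():
    """The published default parameter set (competition structure I)."""
    return published_defaults()


@pytest.fixture
def no_dispersal(published):
    return published.replace(alpha=0.0)


@pytest.fixture
def mutation_defaults():
    return MutationParams()


@pytest.fixture
def cheater_start():
    """Nascent tumor: cheaters only, trace resource."""
    return TumorState(n=[1e3, 0, 0, 0], R=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20180529 % 2**16)
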