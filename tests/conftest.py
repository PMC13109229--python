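import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from microsyntax import (
    MicrostateSequence,
    fit_transition_model,
    random_jump_matrix,
)
from microsyntax.surrogates import sample_chain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_model():
    """Hand-countable model from [0, 0, 1, 1]."""
    return fit_transition_model(MicrostateSequence([0, 0, 1, 1], 2))


@pytest.fixture(scope="session")
def jump_chain_long():
    """One long (n = 1e5) zero-diagonal first-order chain, K = 4."""
    T = random_jump_matrix(4, seed=3)
    labels = sample_chain(np.full(4, 0.25), T, 100_000, np.random.default_rng(99))
    return MicrostateSequence(labels, 4, kind="jump"), T


def random_sequence(rng, n=None, K=None):
    n = n if n is not None else int(rng.integers(10, 500))
    K = K if K is not None else int(rng.integers(2, 5))
    return MicrostateSequence(rng.integers(0, K, size=n), K)
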