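import numpy as np
import pytest

from localtrend import ThreeStateParams, TwoStateParams


def simulate_chain(params, m: int, rng) -> np.ndarray:
    """Simulate a stationary trend chain of length m from its transition matrix."""
    T = params.transition_matrix
    pi = params.stationary
    states = np.array([-1, 1]) if T.shape[0] == 2 else np.array([-1, 0, 1])
    cum = np.cumsum(T, axis=1)
    idx = np.searchsorted(np.cumsum(pi), rng.random())
    out = np.empty(m, dtype=np.int8)
    u = rng.random(m)
    for i in range(m):
        out[i] = states[idx]
        idx = np.searchsorted(cum[idx], u[i])
    return out


def simulate_chains(params, n_chains: int, m: int, rng) -> np.ndarray:
    """(n_chains, m) batch of independent stationary trend chains."""
    T = params.transition_matrix
    pi = params.stationary
    states = np.array([-1, 1]) if T.shape[0] == 2 else np.array([-1, 0, 1])
    cum = np.cumsum(T, axis=1)
    idx = np.searchsorted(np.cumsum(pi), rng.random(n_chains))
    out = np.empty((n_chains, m), dtype=np.int8)
    u = rng.random((n_chains, m))
    for i in range(m):
        out[:, i] = states[idx]
        # row-wise inverse-cdf step
        idx = (u[:, i, None] > cum[idx]).sum(axis=1)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_state():
    return TwoStateParams(0.75)


@pytest.fixture
def three_state():
    return ThreeStateParams(0.5, 0.1, 0.2)
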