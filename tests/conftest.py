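import itertools

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from pupilvol.markov import build_source_model
from pupilvol.schedule import build_block, expand_to_events


@pytest.fixture(scope="session")
def model():
    return build_source_model()


@pytest.fixture(scope="session")
def block(model):
    return build_block(model, rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def events(block):
    return expand_to_events(block)


def enumerate_smoothing(A: np.ndarray, B: np.ndarray, outcomes) -> np.ndarray:
    """Exact smoothing posteriors by brute-force enumeration of all paths.

    Uniform prior over the initial state; ``B[i, j] = P(next=i | current=j)``.
    Deliberately naive — this is the independent oracle for state inference.
    """
    n = B.shape[0]
    T = len(outcomes)
    post = np.zeros((T, n))
    for path in itertools.product(range(n), repeat=T):
        p = 1.0 / n
        for t, s in enumerate(path):
            if t > 0:
                p *= B[s, path[t - 1]]
            p *= A[outcomes[t], s]
        for t, s in enumerate(path):
            post[t, s] += p
    return post / post.sum(axis=1, keepdims=True)


def random_hmm(rng, max_states=4, max_steps=5):
    """A random small HMM instance with column-stochastic A and B."""
    n = int(rng.integers(2, max_states + 1))
    T = int(rng.integers(2, max_steps + 1))
    n_out = int(rng.integers(2, 4))
    A = rng.random((n_out, n)) + 0.1
    A /= A.sum(axis=0)
    B = rng.random((n, n)) + 0.1
    B /= B.sum(axis=0)
    obs = rng.integers(0, n_out, T)
    return A, B, obs
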