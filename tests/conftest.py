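import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_binary_graph(rng, n, p=0.3):
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return (upper | upper.T).astype(float)


def random_weighted_graph(rng, n, p=0.3):
    mask = np.triu(rng.random((n, n)) < p, k=1)
    w = np.triu(rng.lognormal(0, 0.5, (n, n)), k=1) * mask
    return w + w.T


@pytest.fixture
def graph_factory(rng):
    return lambda n, p=0.3, weighted=False: (
        random_weighted_graph(rng, n, p) if weighted else random_binary_graph(rng, n, p)
    )
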