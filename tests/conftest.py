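import numpy as np
import pytest

from netanova import LabeledGraph


def graph_from_adj(a, weighted=False, name=None):
    a = np.asarray(a, dtype=float)
    return LabeledGraph([str(i) for i in range(a.shape[0])], a,
                        weighted=weighted, name=name)


@pytest.fixture
def triangle():
    return graph_from_adj([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def path3():
    return graph_from_adj([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_graph(rng, n=8, p=0.4, name=None):
    iu = np.triu_indices(n, k=1)
    a = np.zeros((n, n))
    a[iu] = (rng.random(iu[0].size) < p).astype(float)
    a += a.T
    return graph_from_adj(a, name=name)
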