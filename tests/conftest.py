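import numpy as np
import pytest

from wgnn_dta import ContactMap, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cmap(n: int, entries: dict[tuple[int, int], float]) -> ContactMap:
    """Hand-written contact map: identity plus the given symmetric entries."""
    m = np.eye(n)
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return ContactMap(m)


def random_weighted_graph(rng, n_nodes: int, p_edge: float = 0.5):
    """Random undirected weighted graph with self-loops, as an edge list of
    (i, j, w) triples emitted in both directions."""
    edges = [(i, i, 1.0) for i in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = rng.uniform(0.1, 1.0)
                edges += [(i, j, w), (j, i, w)]
    return edges


@pytest.fixture(scope="session")
def small_dta_dataset():
    """30-pair regression dataset with short proteins (fast to train on)."""
    ds, signal = generate_synthetic_dataset(
        30, task="dta", seed=11, max_seq_len=250
    )
    return ds, signal
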