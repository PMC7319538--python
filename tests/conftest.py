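import numpy as np
import pandas as pd
import pytest

from causalmix.dataset import from_dataframe
from causalmix.graph import EndpointGraph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_gaussian_dataset(n=200, p=4, seed=0, names=None):
    """Independent standard-normal columns."""
    r = np.random.default_rng(seed)
    names = names or [f"V{i}" for i in range(p)]
    return from_dataframe(pd.DataFrame(
        {name: r.normal(size=n) for name in names}
    ))


def random_endpoint_graph(seed=0, n_nodes=6, edge_prob=0.4):
    """Random graph with a mix of undirected/directed/conflicted edges and
    possibly isolated nodes."""
    r = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(n_nodes)]
    g = EndpointGraph(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if r.random() >= edge_prob:
                continue
            kind = r.integers(0, 4)
            if kind == 0:
                g.add_edge(nodes[i], nodes[j])
            elif kind == 1:
                g.add_directed(nodes[i], nodes[j])
            elif kind == 2:
                g.add_directed(nodes[j], nodes[i])
            else:
                g.add_edge(nodes[i], nodes[j], "arrow", "arrow")
    return g
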