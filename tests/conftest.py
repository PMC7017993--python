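import numpy as np
import networkx as nx
import pytest

from fractalconn.graphs import RoiTimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """10 ROIs x 40 time points of correlated noise."""
    base = rng.standard_normal((40, 1))
    x = 0.6 * base + rng.standard_normal((40, 10))
    return RoiTimeSeriesSet(
        subject_id="s01",
        condition="test",
        samples=x,
        roi_labels=[f"roi{i}" for i in range(10)],
    )


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    nodes = list(g.nodes)
    rng = np.random.default_rng(seed)
    for comp in list(nx.connected_components(g))[1:]:
        g.add_edge(next(iter(comp)), nodes[int(rng.integers(n))])
    return g
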