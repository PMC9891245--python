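import networkx as nx
import numpy as np
import pytest

from n2vplus.graph import WeightedGraph


@pytest.fixture
def toy_graph() -> WeightedGraph:
    """Triangle with one loose edge: A-B (1.0), B-C (1.0), A-C (0.1)."""
    return WeightedGraph.from_edges(
        [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 0.1)]
    )


@pytest.fixture
def path_graph() -> WeightedGraph:
    """Unweighted path A - B - C (no A-C edge)."""
    return WeightedGraph.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])


def random_weighted_graph(n: int, p: float, rng: np.random.Generator, weighted=True):
    """Connected Erdos-Renyi graph with U(0.1, 2) weights, as a WeightedGraph."""
    while True:
        gnx = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if gnx.number_of_edges() and nx.is_connected(gnx):
            break
    edges = [
        (f"v{u}", f"v{v}", float(rng.uniform(0.1, 2.0)) if weighted else 1.0)
        for u, v in gnx.edges()
    ]
    return WeightedGraph.from_edges(edges)


def graph_edge_dict(g: WeightedGraph) -> dict[tuple[str, str], float]:
    """Both-direction edge dict for the brute-force oracle."""
    out = {}
    for v in g.node_ids:
        idx, w = g.neighbors(v)
        for i, wt in zip(idx, w):
            out[(v, g.node_ids[i])] = float(wt)
    return out
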