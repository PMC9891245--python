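"""Walk biases, exact transition distributions and walk simulation.

The implementation is checked against an independent brute-force oracle
(tests/_oracle.py) that evaluates the bias definitions literally on dict
structures, and against Monte-Carlo frequencies from the simulator.
"""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n2vplus.graph import WeightedGraph, compute_node_stats
from n2vplus.walk import (
    WalkConfig,
    WalkCorpus,
    bias_node2vec,
    bias_node2vecplus,
    generate_walks,
    transition_distribution,
)

from _oracle import oracle_transition
from conftest import graph_edge_dict, random_weighted_graph


def cfg(**kw):
    return WalkConfig(**kw)


class TestBiasNode2vec:
    def test_return_edge(self, toy_graph):
        c = cfg(p=4.0, q=2.0, mode="node2vec")
        assert bias_node2vec(toy_graph, c, "A", "B", "A") == 0.25

    def test_in_edge_ignores_weight(self, toy_graph):
        # (C, A) exists with weight 0.1 only, yet the transition counts as "in"
        c = cfg(p=1.0, q=100.0, mode="node2vec")
        assert bias_node2vec(toy_graph, c, "A", "B", "C") == 1.0

    def test_out_edge(self, path_graph):
        c = cfg(p=1.0, q=2.0, mode="node2vec")
        assert bias_node2vec(path_graph, c, "A", "B", "C") == 0.5

    def test_non_edge_transition_rejected(self, path_graph):
        with pytest.raises(ValueError, match="not a stored edge"):
            bias_node2vec(path_graph, cfg(mode="node2vec"), "B", "A", "C")


class TestBiasNode2vecPlus:
    def test_toy_out_edge_interpolation(self, toy_graph):
        # a = w~0(C,A) = 0.1/0.55, b = w~0(B,C) = 1 >= 1: out edge
        s = compute_node_stats(toy_graph)
        c = cfg(p=1.0, q=2.0, gamma=0.0)
        expected = 0.5 + 0.5 * (0.1 / 0.55)
        assert bias_node2vecplus(toy_graph, s, c, "A", "B", "C") == pytest.approx(
            expected
        )

    def test_noisy_edge_never_amplified(self):
        # both (vc,vn) and (vn,vp) loose, q < 1 would amplify an out edge,
        # but a noisy edge is capped at min{1, 1/q} = 1
        g = WeightedGraph.from_edges(
            [("A", "B", 1.0), ("B", "C", 0.1), ("C", "A", 0.1), ("B", "D", 1.0),
             ("C", "D", 1.0)]
        )
        s = compute_node_stats(g)
        c = cfg(p=1.0, q=0.01)
        # vp=A, vc=B, vn=C: w~(C,A)=0.1/mu(C)<1 and w~(B,C)=0.1/mu(B)<1
        assert bias_node2vecplus(g, s, c, "A", "B", "C") == 1.0

    def test_out_edge_reduces_to_node2vec_when_unconnected(self, path_graph):
        # w(vn, vp) = 0: the out-edge bias must equal 1/q exactly
        s = compute_node_stats(path_graph)
        c = cfg(p=1.0, q=7.0)
        assert bias_node2vecplus(path_graph, s, c, "A", "B", "C") == 1.0 / 7.0

    def test_return_takes_precedence(self, toy_graph):
        s = compute_node_stats(toy_graph)
        c = cfg(p=10.0, q=2.0)
        assert bias_node2vecplus(toy_graph, s, c, "A", "B", "A") == 0.1

    @pytest.mark.parametrize("seed", range(10))
    def test_unweighted_equivalence(self, seed):
        """On any unweighted graph node2vec+ equals node2vec exactly."""
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(10, 0.35, rng, weighted=False)
        s = compute_node_stats(g)
        c2 = cfg(p=2.0, q=0.5, mode="node2vec")
        cp = cfg(p=2.0, q=0.5, mode="node2vecplus")
        for vc in g.node_ids:
            nbrs, _ = g.neighbors(vc)
            for ip in nbrs:
                vp = g.node_ids[ip]
                for into in nbrs:
                    vn = g.node_ids[into]
                    assert bias_node2vecplus(g, s, cp, vp, vc, vn) == bias_node2vec(
                        g, c2, vp, vc, vn
                    )


class TestTransitionDistribution:
    def test_normalization_and_nonnegativity(self, toy_graph):
        for mode in ("first_order", "node2vec", "node2vecplus"):
            _, pr = transition_distribution(
                toy_graph, None, cfg(p=3.0, q=0.2, mode=mode), "A", "B"
            )
            assert pr.min() >= 0
            assert abs(pr.sum() - 1.0) < 1e-12

    def test_neutral_parameters_recover_first_order(self):
        rng = np.random.default_rng(11)
        g = random_weighted_graph(12, 0.4, rng)
        for mode in ("node2vec", "node2vecplus"):
            c = cfg(p=1.0, q=1.0, mode=mode)
            for vc in g.node_ids:
                nbrs, w = g.neighbors(vc)
                first_order = w / w.sum()
                for ip in nbrs:
                    vp = g.node_ids[ip]
                    _, pr = transition_distribution(g, None, c, vp, vc)
                    np.testing.assert_allclose(pr, first_order, atol=1e-12)

    def test_toy_hand_computed_probabilities(self, toy_graph):
        # vp=A, vc=B, node2vec+ p=1 q=2 gamma=0: P(A) = 1/(1+0.59091)
        _, pr = transition_distribution(
            toy_graph, None, cfg(p=1.0, q=2.0, gamma=0.0), "A", "B"
        )
        nbrs, _ = transition_distribution(
            toy_graph, None, cfg(p=1.0, q=2.0, gamma=0.0), "A", "B"
        )
        dist = dict(zip(nbrs, pr))
        assert dist["A"] == pytest.approx(0.6285714285714286, abs=1e-4)
        assert dist["C"] == pytest.approx(0.37142857142857144, abs=1e-4)

    def test_first_step_is_weight_proportional(self, toy_graph):
        nbrs, pr = transition_distribution(
            toy_graph, None, cfg(p=9.0, q=9.0), None, "A"
        )
        dist = dict(zip(nbrs, pr))
        assert dist["B"] == pytest.approx(1.0 / 1.1)
        assert dist["C"] == pytest.approx(0.1 / 1.1)

    def test_isolated_current_node_errors(self):
        g = WeightedGraph.from_edges([("A", "B", 1.0)], extra_nodes=["Z"])
        with pytest.raises(ValueError, match="isolated"):
            transition_distribution(g, None, cfg(), None, "Z")

    @pytest.mark.parametrize("params", [(1.0, 1.0, 0.0), (4.0, 0.25, 0.0),
                                        (0.5, 10.0, 1.0), (2.0, 2.0, 2.0)])
    def test_matches_brute_force_on_random_graphs(self, params):
        """Full second-order transition matrices vs the literal oracle."""
        p, q, gamma = params
        rng = np.random.default_rng(int(p * 100 + q * 10 + gamma))
        for _ in range(5):
            g = random_weighted_graph(8, 0.4, rng)
            edges = graph_edge_dict(g)
            for mode in ("node2vec", "node2vecplus"):
                c = cfg(p=p, q=q, gamma=gamma, mode=mode)
                for vc in g.node_ids:
                    nbrs, _ = g.neighbors(vc)
                    for ip in nbrs:
                        vp = g.node_ids[ip]
                        ids, pr = transition_distribution(g, None, c, vp, vc)
                        ref = oracle_transition(edges, vp, vc, mode, p, q, gamma)
                        for vn, prob in zip(ids, pr):
                            assert prob == pytest.approx(ref[vn], abs=1e-12)


class TestGenerateWalks:
    def test_two_node_graph_alternates(self):
        g = WeightedGraph.from_edges([("X", "Y", 2.0)])
        corpus = generate_walks(g, cfg(walk_length=10, num_walks=2, seed=1))
        assert len(corpus) == 4
        for walk in corpus.walks:
            assert len(walk) == 10
            assert all(a != b for a, b in zip(walk, walk[1:]))

    def test_walk_length_one(self, toy_graph):
        corpus = generate_walks(toy_graph, cfg(walk_length=1, num_walks=3, seed=0))
        assert all(len(w) == 1 for w in corpus.walks)

    def test_every_step_is_an_edge_and_start_counts(self, toy_graph):
        c = cfg(p=0.5, q=4.0, walk_length=20, num_walks=5, seed=3)
        corpus = generate_walks(toy_graph, c)
        starts = {}
        for walk in corpus.walks:
            starts[walk[0]] = starts.get(walk[0], 0) + 1
            for a, b in zip(walk, walk[1:]):
                assert toy_graph.has_edge(a, b)
        assert starts == {v: 5 for v in toy_graph.node_ids}

    def test_bitwise_reproducibility(self, toy_graph):
        c = cfg(p=2.0, q=0.5, walk_length=15, num_walks=4, seed=42)
        w1 = generate_walks(toy_graph, c).walks
        w2 = generate_walks(toy_graph, c).walks
        assert w1 == w2
        w3 = generate_walks(toy_graph, cfg(p=2.0, q=0.5, walk_length=15,
                                           num_walks=4, seed=43)).walks
        assert w1 != w3

    def test_isolated_nodes_start_no_walks(self):
        g = WeightedGraph.from_edges([("A", "B", 1.0)], extra_nodes=["Z"])
        corpus = generate_walks(g, cfg(walk_length=5, num_walks=2, seed=0))
        assert all(w[0] != "Z" for w in corpus.walks)

    def test_empirical_frequencies_match_exact_distribution(self, toy_graph):
        """Conditional step frequencies from the simulator vs the exact law."""
        c = cfg(p=2.0, q=0.5, mode="node2vecplus", walk_length=2000,
                num_walks=10, seed=5)
        corpus = generate_walks(toy_graph, c)
        counts: dict[tuple[str, str], dict[str, int]] = {}
        for walk in corpus.walks:
            for vp, vc, vn in zip(walk, walk[1:], walk[2:]):
                counts.setdefault((vp, vc), {}).setdefault(vn, 0)
                counts[(vp, vc)][vn] += 1
        for (vp, vc), obs in counts.items():
            n = sum(obs.values())
            if n < 2000:
                continue
            ids, pr = transition_distribution(toy_graph, None, c, vp, vc)
            for vn, prob in zip(ids, pr):
                se = np.sqrt(prob * (1 - prob) / n)
                assert abs(obs.get(vn, 0) / n - prob) < 4 * se + 1e-9

    def test_corpus_roundtrip(self, toy_graph, tmp_path):
        corpus = generate_walks(toy_graph, cfg(walk_length=5, num_walks=2, seed=0))
        path = tmp_path / "walks.txt"
        corpus.save(path)
        assert WalkCorpus.load(path).walks == corpus.walks


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    g1=st.floats(-1.0, 3.0, allow_nan=False),
    delta=st.floats(0.01, 2.0, allow_nan=False),
)
def test_gamma_monotonicity_shrinks_tight_set(seed, g1, delta):
    """For gamma1 < gamma2 the normalized weights can only shrink, so the
    set of tight edges shrinks weakly as gamma grows."""
    from n2vplus.graph import compute_node_stats, normalized_weight

    rng = np.random.default_rng(seed)
    g = random_weighted_graph(8, 0.4, rng)
    s = compute_node_stats(g)
    g2 = g1 + delta
    tight1, tight2 = set(), set()
    for v in g.node_ids:
        nbrs, _ = g.neighbors(v)
        for iu in nbrs:
            u = g.node_ids[iu]
            w1 = normalized_weight(g, s, v, u, g1)
            w2 = normalized_weight(g, s, v, u, g2)
            assert w1 >= w2 - 1e-12
            if w1 >= 1.0:
                tight1.add((v, u))
            if w2 >= 1.0:
                tight2.add((v, u))
    assert tight2 <= tight1


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        WalkConfig(p=0.0)
    with pytest.raises(ValueError):
        WalkConfig(q=-1.0)
    with pytest.raises(ValueError):
        WalkConfig(walk_length=0)
    with pytest.raises(ValueError):
        WalkConfig(mode="nope")
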