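"""Walk biases on a 3-node toy graph with one loose edge.

Builds the triangle A-B (1.0), B-C (1.0), A-C (0.1) and shows how node2vec
and node2vec+ treat the step B -> C after arriving from A: node2vec calls
it an "in" edge (C and A are connected, weight ignored), while node2vec+
sees that the C-A edge is loose and down-weights the move.
"""

from n2vplus import WeightedGraph, compute_node_stats, normalized_weight
from n2vplus.walk import WalkConfig, bias_node2vec, bias_node2vecplus, transition_distribution

g = WeightedGraph.from_edges([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 0.1)])
s = compute_node_stats(g)

print("incident-weight stats:")
for v in g.node_ids:
    i = g.index(v)
    print(f"  mu({v}) = {s.mu[i]:.3f}   sigma({v}) = {s.sigma[i]:.3f}")

print(f"\nnormalized weight w~0(C, A) = {normalized_weight(g, s, 'C', 'A'):.5f}"
      "   (< 1: the C-A edge is loose from C's point of view)")

cfg = WalkConfig(p=1.0, q=2.0, gamma=0.0)
b_n2v = bias_node2vec(g, WalkConfig(p=1.0, q=2.0, mode="node2vec"), "A", "B", "C")
b_plus = bias_node2vecplus(g, s, cfg, "A", "B", "C")
print(f"\nbias for step B->C given previous A:  node2vec = {b_n2v:.3f},"
      f"  node2vec+ = {b_plus:.5f}")

ids, pr = transition_distribution(g, s, cfg, "A", "B")
print("\nnode2vec+ transition from B (previous A), p=1 q=2:")
for v, p in zip(ids, pr):
    print(f"  P({v}) = {p:.4f}")
print("The walk prefers returning to A over following the nominally 'in' "
      "edge to C, because C is only loosely tied back to A.")
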