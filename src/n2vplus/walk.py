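"""Second-order biased random walks: node2vec and node2vec+ bias factors,
exact transition distributions, and seeded walk simulation.

A second-order walk chooses the next vertex ``vn`` given both the current
vertex ``vc`` and the previous vertex ``vp``, with probability proportional
to ``alpha(vp, vc, vn) * w(vc, vn)``.  node2vec classifies the candidate
transition by the topological relation between ``vn`` and ``vp`` (return /
in / out); node2vec+ additionally inspects the *weight* of the edge
``(vn, vp)`` relative to ``vn``'s incident-weight statistics, which lets it
recognise loosely connected candidates as out edges on weighted (even fully
connected) graphs, and introduces a fourth *noisy* category that is never
amplified.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from . import _kernels
from .graph import (
    DEFAULT_EPSILON,
    NodeWeightStats,
    WeightedGraph,
    compute_node_stats,
    normalized_weight,
)

__all__ = [
    "WalkConfig",
    "WalkCorpus",
    "bias_node2vec",
    "bias_node2vecplus",
    "transition_distribution",
    "generate_walks",
]

_MODES = {
    "first_order": _kernels.MODE_FIRST_ORDER,
    "node2vec": _kernels.MODE_NODE2VEC,
    "node2vecplus": _kernels.MODE_NODE2VECPLUS,
}

# Margin for the tight-edge test w~ >= 1.  Edges that are exactly on the
# boundary in real arithmetic (e.g. the larger incident edge of a degree-2
# node at gamma=1, where w = mu + sigma identically) must classify as tight
# regardless of floating-point rounding in the stats.
TIGHT_TOL = 1e-9


@dataclass(frozen=True)
class WalkConfig:
    """Parameters that fully determine the walk sampling law.

    p : return parameter (> 0); bias 1/p on stepping back to ``vp``.
    q : in-out parameter (> 0); q > 1 keeps walks local (BFS-like),
        q < 1 pushes them outward (DFS-like).
    gamma : loose-edge threshold shift for node2vec+; an edge (v, u) is
        gamma-loose when w(v,u) < mu(v) + gamma*sigma(v).
    epsilon : denominator clip for the normalized weight.
    walk_length : number of vertices per walk (default 80).
    num_walks : walks started per node (default 10).
    mode : "first_order", "node2vec" or "node2vecplus".
    """

    p: float = 1.0
    q: float = 1.0
    gamma: float = 0.0
    epsilon: float = DEFAULT_EPSILON
    walk_length: int = 80
    num_walks: int = 10
    seed: int = 0
    mode: str = "node2vecplus"

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be strictly positive")
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if self.num_walks < 1:
            raise ValueError("num_walks must be >= 1")
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {sorted(_MODES)}")


@dataclass
class WalkCorpus:
    """A bag of walks (node-ID sequences) plus the provenance that produced it."""

    walks: list[list[str]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.walks)

    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.walks:
            for v in w:
                seen.setdefault(v)
        return list(seen)

    def save(self, path: str | Path) -> None:
        """One walk per line, node IDs space-separated (word2vec sentence format)."""
        with open(path, "w") as fh:
            for w in self.walks:
                fh.write(" ".join(w) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WalkCorpus":
        walks = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    walks.append(parts)
        return cls(walks=walks, provenance={"source": str(path)})


def _require_edge(g: WeightedGraph, vc: str, vn: str) -> None:
    if not g.has_edge(vc, vn):
        raise ValueError(f"({vc!r}, {vn!r}) is not a stored edge")


def bias_node2vec(
    g: WeightedGraph, cfg: WalkConfig, vp: Optional[str], vc: str, vn: str
) -> float:
    """node2vec bias factor alpha_pq(vn, vp) for candidate transition (vc, vn).

    1/p for a return edge (vn == vp), 1 for an in edge ((vn, vp) stored),
    1/q for an out edge.  ``vp=None`` (first step of a walk) is neutral.
    """
    _require_edge(g, vc, vn)
    if vp is None:
        return 1.0
    if vn == vp:
        return 1.0 / cfg.p
    if g.has_edge(vn, vp):
        return 1.0
    return 1.0 / cfg.q


def bias_node2vecplus(
    g: WeightedGraph,
    s: NodeWeightStats,
    cfg: WalkConfig,
    vp: Optional[str],
    vc: str,
    vn: str,
) -> float:
    """node2vec+ bias factor, aware of the weight of the candidate-previous edge.

    With ``a = w~_gamma(vn, vp)`` and ``b = w~_gamma(vc, vn)``:

    * return edge (vn == vp): 1/p (takes precedence over the weight cases);
    * in edge (a >= 1): 1;
    * noisy edge (a < 1 and b < 1): min(1, 1/q) — suppressed, never amplified;
    * out edge (a < 1, b >= 1): 1/q + (1 - 1/q) * a, a linear interpolation
      between the node2vec out-edge bias (a = 0, i.e. no (vn, vp) edge) and
      the in-edge bias as (vn, vp) tightens.

    On an unweighted graph this reduces exactly to :func:`bias_node2vec`.
    """
    _require_edge(g, vc, vn)
    if vp is None:
        return 1.0
    if vn == vp:
        return 1.0 / cfg.p
    a = normalized_weight(g, s, vn, vp, cfg.gamma)
    if a >= 1.0 - TIGHT_TOL:
        return 1.0
    b = normalized_weight(g, s, vc, vn, cfg.gamma)
    if b < 1.0 - TIGHT_TOL:
        return min(1.0, 1.0 / cfg.q)
    return 1.0 / cfg.q + (1.0 - 1.0 / cfg.q) * a


def transition_distribution(
    g: WeightedGraph,
    s: Optional[NodeWeightStats],
    cfg: WalkConfig,
    vp: Optional[str],
    vc: str,
) -> tuple[list[str], np.ndarray]:
    """Exact next-step distribution over the neighbors of ``vc``.

    Returns ``(neighbor_ids, probabilities)`` with probabilities summing to 1.
    ``vp=None`` yields the first-order (weight-proportional) distribution
    used for the first step of every walk.
    """
    nbr_idx, weights = g.neighbors(vc)
    if nbr_idx.size == 0:
        raise ValueError(f"node {vc!r} is isolated; no transition distribution")
    neighbors = [g.node_ids[i] for i in nbr_idx]
    if vp is None or cfg.mode == "first_order":
        scores = weights.astype(float)
    elif cfg.mode == "node2vec":
        scores = np.array(
            [bias_node2vec(g, cfg, vp, vc, vn) * w for vn, w in zip(neighbors, weights)]
        )
    else:
        if s is None:
            s = compute_node_stats(g, epsilon=cfg.epsilon)
        scores = np.array(
            [
                bias_node2vecplus(g, s, cfg, vp, vc, vn) * w
                for vn, w in zip(neighbors, weights)
            ]
        )
    return neighbors, scores / scores.sum()


def _walk_seeds(master: int, num_walks: int, n: int) -> np.ndarray:
    """Per-walk RNG streams derived from (master, epoch, start index).

    Keyed on epoch and start-node index (not on position in the shuffled
    order), so the corpus is reproducible irrespective of scheduling.
    """
    seeds = np.empty((num_walks, n), dtype=np.uint32)
    for epoch in range(num_walks):
        ss = np.random.SeedSequence(entropy=master, spawn_key=(epoch,))
        seeds[epoch] = ss.generate_state(n, dtype=np.uint32)
    return seeds


def generate_walks(g: WeightedGraph, cfg: WalkConfig) -> WalkCorpus:
    """Simulate the full walk corpus for a graph under a config.

    For each of ``num_walks`` epochs every non-isolated node (in a seeded
    shuffled order) starts one walk of ``walk_length`` vertices.  The biased
    distribution of the current vertex is computed on the fly at every step;
    no second-order alias tables are precomputed, so dense weighted graphs
    stay memory-safe.  Identical (graph, config, seed) gives an identical
    corpus.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot walk on an empty graph")
    adj = g.adj
    deg = np.diff(adj.indptr)
    active = np.flatnonzero(deg > 0)
    if active.size == 0:
        return WalkCorpus(walks=[], provenance=_provenance(g, cfg))
    mode = _MODES[cfg.mode]
    if cfg.mode == "node2vecplus":
        stats = compute_node_stats(g, epsilon=cfg.epsilon)
        den = stats.denominators(cfg.gamma)
        den = np.where(np.isnan(den), 1.0, den)
    else:
        den = np.ones(g.n_nodes)
    order_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    all_seeds = _walk_seeds(cfg.seed, cfg.num_walks, g.n_nodes)
    walks: list[list[str]] = []
    indptr = adj.indptr.astype(np.int64)
    indices = adj.indices.astype(np.int64)
    data = adj.data.astype(np.float64)
    for epoch in range(cfg.num_walks):
        starts = active[order_rng.permutation(active.size)].astype(np.int64)
        seeds = all_seeds[epoch][starts]
        mat = _kernels._simulate_walks(
            indptr, indices, data, den, mode, float(cfg.p), float(cfg.q),
            starts, seeds, cfg.walk_length,
        )
        for row in mat:
            walks.append([g.node_ids[i] for i in row if i >= 0])
    return WalkCorpus(walks=walks, provenance=_provenance(g, cfg))


def _provenance(g: WeightedGraph, cfg: WalkConfig) -> dict:
    return {"config": asdict(cfg), "graph_checksum": g.checksum()}
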