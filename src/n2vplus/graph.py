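"""Weighted graph container, edge-list I/O and per-node weight statistics.

The central object is :class:`WeightedGraph`, a node-indexed sparse (CSR)
adjacency over opaque string node identifiers.  All random-walk machinery
operates on it.  :class:`NodeWeightStats` holds the per-node mean and
population standard deviation of incident edge weights used to normalize
weights when classifying walk transitions on weighted graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "WeightedGraph",
    "NodeWeightStats",
    "load_edgelist",
    "save_edgelist",
    "load_dense",
    "save_dense",
    "compute_node_stats",
    "normalized_weight",
    "sparsify_by_threshold",
    "is_connected",
]

DEFAULT_EPSILON = 1e-6


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid graph."""


@dataclass
class WeightedGraph:
    """Undirected (by default) weighted graph stored as a CSR adjacency.

    Invariants enforced at construction:

    * every stored edge has weight > 0 (zero-weight pairs are simply absent);
    * for undirected graphs the adjacency is exactly symmetric;
    * no self-loops;
    * ``node_ids`` are unique; internal integer indices are positions in
      ``node_ids``.
    """

    node_ids: list[str]
    adj: sp.csr_matrix
    directed: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        if self.adj.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match node list")
        if self.adj.nnz and self.adj.data.min() < 0:
            raise ValueError("negative edge weight")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        directed: bool = False,
        extra_nodes: Sequence[str] = (),
    ) -> "WeightedGraph":
        """Build a graph from ``(u, v, w)`` triples.

        Self-loops are dropped with a warning.  Duplicate edges keep the
        last weight seen (warned).  For undirected graphs the edge is
        stored in both directions.
        """
        order: list[str] = []
        index: dict[str, int] = {}

        def _idx(v: str) -> int:
            if v not in index:
                index[v] = len(order)
                order.append(v)
            return index[v]

        weights: dict[tuple[int, int], float] = {}
        n_dup = n_loop = 0
        for u, v, w in edges:
            w = float(w)
            if w < 0:
                raise ValueError(f"negative weight on edge ({u}, {v}): {w}")
            iu, iv = _idx(u), _idx(v)
            if iu == iv:
                n_loop += 1
                continue
            key = (iu, iv) if directed or iu < iv else (iv, iu)
            if key in weights:
                n_dup += 1
            if w > 0:
                weights[key] = w
            else:
                weights.pop(key, None)
        for v in extra_nodes:
            _idx(v)
        if n_loop:
            warnings.warn(f"dropped {n_loop} self-loop(s)", stacklevel=2)
        if n_dup:
            warnings.warn(
                f"{n_dup} duplicate edge(s); kept the last weight seen", stacklevel=2
            )
        n = len(order)
        if weights:
            rows, cols, vals = [], [], []
            for (i, j), w in weights.items():
                rows.append(i)
                cols.append(j)
                vals.append(w)
                if not directed:
                    rows.append(j)
                    cols.append(i)
                    vals.append(w)
            adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        else:
            adj = sp.csr_matrix((n, n))
        adj.sort_indices()
        return cls(order, adj, directed)

    @classmethod
    def from_dense(
        cls, matrix: np.ndarray, node_ids: Sequence[str], directed: bool = False
    ) -> "WeightedGraph":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("adjacency must be square")
        if matrix.shape[0] != len(node_ids):
            raise ValueError("node id list does not match matrix size")
        if not directed and not np.allclose(matrix, matrix.T):
            raise ValueError("undirected graph requires a symmetric matrix")
        m = matrix.copy()
        np.fill_diagonal(m, 0.0)
        adj = sp.csr_matrix(m)
        adj.eliminate_zeros()
        adj.sort_indices()
        return cls(list(node_ids), adj, directed)

    # -- queries ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        """Number of stored edges (undirected pairs counted once)."""
        return self.adj.nnz if self.directed else self.adj.nnz // 2

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    def degree(self, node: str) -> int:
        i = self.index(node)
        return self.adj.indptr[i + 1] - self.adj.indptr[i]

    def neighbors(self, node: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(neighbor_indices, weights)`` for a node."""
        i = self.index(node)
        lo, hi = self.adj.indptr[i], self.adj.indptr[i + 1]
        return self.adj.indices[lo:hi], self.adj.data[lo:hi]

    def weight(self, u: str, v: str) -> float:
        """Stored weight of edge (u, v); 0.0 if the pair is not an edge."""
        iu, iv = self.index(u), self.index(v)
        lo, hi = self.adj.indptr[iu], self.adj.indptr[iu + 1]
        pos = np.searchsorted(self.adj.indices[lo:hi], iv)
        if pos < hi - lo and self.adj.indices[lo + pos] == iv:
            return float(self.adj.data[lo + pos])
        return 0.0

    def has_edge(self, u: str, v: str) -> bool:
        return self.weight(u, v) > 0.0

    def to_dense(self) -> np.ndarray:
        return self.adj.toarray()

    def checksum(self) -> str:
        """Stable hex digest of the node list and adjacency (provenance)."""
        import hashlib

        h = hashlib.sha256()
        h.update("\n".join(self.node_ids).encode())
        h.update(self.adj.indptr.tobytes())
        h.update(self.adj.indices.tobytes())
        h.update(np.asarray(self.adj.data, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]


@dataclass
class NodeWeightStats:
    """Per-node mean and population std of incident edge weights.

    ``mu[v]`` is the mean of ``{w(v, v') : v' in N(v)}`` and ``sigma[v]``
    the population standard deviation of the same multiset (the divisor is
    ``|N(v)|``, not ``|N(v)| - 1``).  Isolated nodes have undefined stats;
    querying one raises.  ``epsilon`` clips the denominator of the
    normalized weight, guarding against non-positive denominators when the
    loose-edge shift ``gamma`` is negative.
    """

    mu: np.ndarray
    sigma: np.ndarray
    isolated: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    def denominators(self, gamma: float) -> np.ndarray:
        """Per-node clipped denominator ``max(mu + gamma*sigma, epsilon)``."""
        return np.maximum(self.mu + gamma * self.sigma, self.epsilon)


def compute_node_stats(
    g: WeightedGraph, epsilon: float = DEFAULT_EPSILON
) -> NodeWeightStats:
    """Compute mu(v) and population sigma(v) over each node's incident weights."""
    n = g.n_nodes
    deg = np.diff(g.adj.indptr)
    isolated = deg == 0
    safe_deg = np.maximum(deg, 1)
    row_sum = np.asarray(g.adj.sum(axis=1)).ravel()
    mu = row_sum / safe_deg
    sq_sum = np.asarray(g.adj.multiply(g.adj).sum(axis=1)).ravel()
    var = np.maximum(sq_sum / safe_deg - mu**2, 0.0)
    sigma = np.sqrt(var)
    mu[isolated] = np.nan
    sigma[isolated] = np.nan
    return NodeWeightStats(mu=mu, sigma=sigma, isolated=isolated, epsilon=epsilon)


def normalized_weight(
    g: WeightedGraph, s: NodeWeightStats, v: str, u: str, gamma: float = 0.0
) -> float:
    """Normalized weight ``w~_gamma(v, u) = w(v,u) / max(mu(v)+gamma*sigma(v), eps)``.

    Asymmetric in its arguments: the denominator uses the incident-weight
    statistics of the *first* argument ``v``.  A non-edge has normalized
    weight exactly 0.  An edge is gamma-*loose* when this value is < 1 and
    gamma-*tight* otherwise.
    """
    iv = g.index(v)
    if s.isolated[iv]:
        raise ValueError(f"node {v!r} is isolated; its weight stats are undefined")
    den = max(s.mu[iv] + gamma * s.sigma[iv], s.epsilon)
    return g.weight(v, u) / den


def sparsify_by_threshold(g: WeightedGraph, threshold: float) -> WeightedGraph:
    """Keep exactly the edges with weight >= threshold; node set unchanged."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = g.adj.copy()
    adj.data = np.where(adj.data >= threshold, adj.data, 0.0)
    adj.eliminate_zeros()
    adj.sort_indices()
    return WeightedGraph(list(g.node_ids), adj, g.directed)


def is_connected(g: WeightedGraph) -> bool:
    """True iff a single connected component spans all nodes."""
    if g.n_nodes == 0:
        raise ValueError("connectivity of an empty graph is undefined")
    if g.n_nodes == 1:
        return True
    n_comp, _ = connected_components(g.adj, directed=g.directed, connection="weak")
    return n_comp == 1


# -- file formats --------------------------------------------------------

def load_edgelist(
    path: str | Path, weighted: bool = True, directed: bool = False
) -> WeightedGraph:
    """Read a whitespace-separated edge list (``src dst [weight]``).

    Lines starting with ``#`` are ignored.  With ``weighted=False`` every
    edge gets weight 1.0 regardless of a third column.  Malformed lines and
    negative weights raise :class:`GraphFormatError` with the line number.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if weighted and len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise GraphFormatError(
                        f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                    ) from None
                if not np.isfinite(w) or w < 0:
                    raise GraphFormatError(
                        f"{path}:{lineno}: weight must be finite and >= 0, got {w}"
                    )
            else:
                w = 1.0
            edges.append((u, v, w))
    return WeightedGraph.from_edges(edges, directed=directed)


def save_edgelist(g: WeightedGraph, path: str | Path, precision: int = 12) -> None:
    """Write the graph as a tab-separated edge list (each undirected edge once)."""
    with open(path, "w") as fh:
        coo = sp.triu(g.adj).tocoo() if not g.directed else g.adj.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{g.node_ids[i]}\t{g.node_ids[j]}\t{w:.{precision}g}\n")


def load_dense(
    matrix_path: str | Path, ids_path: str | Path, directed: bool = False
) -> WeightedGraph:
    """Read a dense adjacency (whitespace-separated matrix) plus ID list."""
    matrix = np.loadtxt(matrix_path, ndmin=2)
    node_ids = [line.strip() for line in open(ids_path) if line.strip()]
    return WeightedGraph.from_dense(matrix, node_ids, directed=directed)


def save_dense(g: WeightedGraph, matrix_path: str | Path, ids_path: str | Path) -> None:
    np.savetxt(matrix_path, g.to_dense(), fmt="%.12g", delimiter="\t")
    with open(ids_path, "w") as fh:
        fh.write("\n".join(g.node_ids) + "\n")
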