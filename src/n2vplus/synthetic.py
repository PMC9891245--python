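"""Synthetic benchmark graphs: the barbell graph and hierarchical cluster graphs.

Two families probe whether an embedding respects community structure on
weighted graphs:

* **Barbell**: two complete modules joined through a bridge node, optionally
  perturbed with low-weight "loose" edges between every remaining pair so
  the graph becomes fully connected.  Node types (bridge / peripheral /
  interior) are the qualitative targets.

* **Hierarchical cluster graphs** (KkLl): Gaussian point clouds arranged on
  a K-ary cluster tree of depth L in a latent space, turned into a fully
  connected weighted graph with an RBF kernel.  Labels are cluster identity
  and hierarchy level.  Geometry is calibrated so the expected distance
  from a point to a point of the parent cluster is ~1 while sibling-cluster
  points sit ~sqrt(2) apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .graph import WeightedGraph

__all__ = [
    "HierClusterSpec",
    "LabeledGraph",
    "BarbellGraph",
    "make_barbell",
    "make_hier_cluster_points",
    "points_to_rbf_graph",
    "make_hier_cluster_graph",
    "write_labels",
    "read_labels",
]


@dataclass
class BarbellGraph:
    """Barbell graph plus its per-node type labels."""

    graph: WeightedGraph
    node_type: dict[str, str]  # "bridge" | "peripheral" | "interior"

    def nodes_of_type(self, kind: str) -> list[str]:
        return [v for v, t in self.node_type.items() if t == kind]


@dataclass
class LabeledGraph:
    """A weighted graph with per-node cluster and hierarchy-level labels."""

    graph: WeightedGraph
    cluster_label: np.ndarray  # int, aligned with graph.node_ids
    level_label: np.ndarray  # int in [0, L], deterministic in cluster_label


@dataclass(frozen=True)
class HierClusterSpec:
    """Specification of a hierarchical cluster graph.

    K : children per cluster (>= 2); L : levels below the root.
    n_per_cluster : points drawn per cluster (the root cluster included).
    sigma_noise : isotropic per-coordinate std of points around their center.
    parent_child_distance : design constant 1.0 — the expected Euclidean
        distance between a child-cluster point and a parent-cluster point
        (sibling-cluster points then sit about sqrt(2) as far apart because
        the K displacements at one branching are mutually orthogonal).  The
        center-to-center displacement is derived from it; see
        ``center_displacement``.
    kernel_scale : RBF length-scale used when the cloud becomes a graph.
    latent_dim : dimension of the latent space; default K*L, enough to give
        every level its own block of K orthogonal displacement axes (so any
        two same-level cluster centers are at least sqrt(2) displacements
        apart).
    """

    K: int = 3
    L: int = 2
    n_per_cluster: int = 30
    sigma_noise: float = 0.1
    parent_child_distance: float = 1.0
    kernel_scale: float = 1.0
    latent_dim: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n_per_cluster < 1:
            raise ValueError("n_per_cluster must be >= 1")

    @property
    def n_clusters(self) -> int:
        return sum(self.K**l for l in range(self.L + 1))

    @property
    def n_nodes(self) -> int:
        return self.n_per_cluster * self.n_clusters

    @property
    def dim(self) -> int:
        return self.latent_dim if self.latent_dim is not None else self.K * self.L

    @property
    def center_displacement(self) -> float:
        """Child-center displacement length calibrated at the point level.

        The design constant ``parent_child_distance`` is the *expected
        distance between a child-cluster point and a parent-cluster point*.
        Since the difference of two points carries noise variance
        2*sigma_noise^2 per latent coordinate, the center-to-center
        displacement is shrunk to sqrt(D^2 - 2*sigma^2*d) so the point-level
        expectation comes out at D.  In the noiseless limit this is exactly
        ``parent_child_distance``.
        """
        d2 = self.parent_child_distance**2 - 2.0 * self.sigma_noise**2 * self.dim
        if d2 <= 0:
            raise ValueError(
                "sigma_noise too large for the requested parent_child_distance"
            )
        return float(np.sqrt(d2))


def make_barbell(module_size: int = 20, noise_weight: float = 0.0) -> BarbellGraph:
    """Two complete modules of ``module_size`` nodes joined by a bridge node.

    All structural edges have weight 1.0: each module is complete, and the
    bridge connects to exactly one *peripheral* node in each module.  With
    ``noise_weight > 0`` every remaining non-adjacent pair is added with
    that weight, making the graph complete (the perturbed barbell).
    """
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if noise_weight < 0:
        raise ValueError("noise_weight must be >= 0")
    m = module_size
    ids = [f"a{i:02d}" for i in range(m)] + [f"b{i:02d}" for i in range(m)] + ["bridge"]
    edges: list[tuple[str, str, float]] = []
    for side in ("a", "b"):
        for i in range(m):
            for j in range(i + 1, m):
                edges.append((f"{side}{i:02d}", f"{side}{j:02d}", 1.0))
    edges.append(("bridge", "a00", 1.0))
    edges.append(("bridge", "b00", 1.0))
    node_type = {v: "interior" for v in ids}
    node_type["bridge"] = "bridge"
    node_type["a00"] = node_type["b00"] = "peripheral"
    if noise_weight > 0:
        present = {frozenset((u, v)) for u, v, _ in edges}
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                if frozenset((u, v)) not in present:
                    edges.append((u, v, noise_weight))
    g = WeightedGraph.from_edges(edges, extra_nodes=ids)
    # from_edges orders nodes by first appearance in the edge list; rebuild
    # the label map keyed by the ids actually stored
    return BarbellGraph(graph=g, node_type={v: node_type[v] for v in g.node_ids})


def _cluster_tree(spec: HierClusterSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Breadth-first cluster tree: (parent, level, centers).

    Level ``l`` uses its own block of K orthogonal axes, so the K child
    displacements at any branching are mutually orthogonal: sibling centers
    sit exactly sqrt(2) displacements apart, child-parent centers exactly
    one displacement apart, and any two distinct same-level centers at
    least sqrt(2) displacements apart.
    """
    K, L, d = spec.K, spec.L, spec.dim
    if d < K * L:
        raise ValueError("latent_dim must be >= K*L to host per-level axis blocks")
    step = spec.center_displacement
    parent = [-1]
    level = [0]
    centers = [np.zeros(d)]
    frontier = [0]
    for l in range(1, L + 1):
        nxt = []
        for pc in frontier:
            for j in range(K):
                axis = np.zeros(d)
                axis[(l - 1) * K + j] = step
                parent.append(pc)
                level.append(l)
                centers.append(centers[pc] + axis)
                nxt.append(len(parent) - 1)
        frontier = nxt
    return np.array(parent), np.array(level), np.vstack(centers)


def make_hier_cluster_points(
    spec: HierClusterSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the latent point cloud for a hierarchical cluster spec.

    Cluster centers are placed recursively: each child center is its parent
    center plus a displacement along a fresh axis, the K displacements at
    one branching mutually orthogonal.  The displacement length is
    calibrated (see ``HierClusterSpec.center_displacement``) so that the
    *expected distance between a child point and a parent point* equals
    ``parent_child_distance`` (= 1 by design), with sibling points about
    sqrt(2) as far; in the noiseless limit the center distances are exactly
    1 and sqrt(2).  Points are drawn isotropically around their center with
    std ``sigma_noise`` per coordinate.

    Returns ``(points, cluster_label, level_label)`` with one row per node.
    """
    parent, level, centers = _cluster_tree(spec)
    rng = np.random.default_rng(spec.seed)
    n, M = spec.n_per_cluster, centers.shape[0]
    cluster_label = np.repeat(np.arange(M), n)
    level_label = level[cluster_label]
    points = centers[cluster_label] + rng.normal(
        scale=spec.sigma_noise, size=(M * n, spec.dim)
    )
    return points, cluster_label, level_label


def points_to_rbf_graph(
    points: np.ndarray,
    kernel_scale: float = 1.0,
    node_ids: list[str] | None = None,
) -> WeightedGraph:
    """Fully connected weighted graph with w(i,j) = exp(-||xi-xj||^2 / (2 s^2)).

    Weights lie in (0, 1]; coincident points get weight exactly 1.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be > 0")
    sq = squareform(pdist(points, metric="sqeuclidean"))
    w = np.exp(-sq / (2.0 * kernel_scale**2))
    np.fill_diagonal(w, 0.0)
    if node_ids is None:
        width = len(str(points.shape[0] - 1))
        node_ids = [f"n{i:0{width}d}" for i in range(points.shape[0])]
    return WeightedGraph.from_dense(w, node_ids)


def make_hier_cluster_graph(spec: HierClusterSpec) -> LabeledGraph:
    """Full pipeline: latent cloud -> RBF graph -> labeled graph.

    With the defaults (K=3, L=2, 30 nodes per cluster) this is the K3L2
    benchmark: 13 clusters, 390 nodes, fully connected.
    """
    points, cluster_label, level_label = make_hier_cluster_points(spec)
    g = points_to_rbf_graph(points, kernel_scale=spec.kernel_scale)
    return LabeledGraph(graph=g, cluster_label=cluster_label, level_label=level_label)


def write_labels(
    lg: LabeledGraph, path: str | Path, sidecar: dict | None = None
) -> None:
    """TSV of (node_id, cluster_label, level_label); optional JSON sidecar."""
    with open(path, "w") as fh:
        fh.write("node_id\tcluster_label\tlevel_label\n")
        for v, c, l in zip(lg.graph.node_ids, lg.cluster_label, lg.level_label):
            fh.write(f"{v}\t{c}\t{l}\n")
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


def read_labels(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a labels TSV back into {node_id: {column: value}}."""
    out: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        for line in fh:
            parts = line.split()
            if parts:
                out[parts[0]] = {
                    k: int(v) for k, v in zip(header[1:], parts[1:])
                }
    return out


def spec_sidecar(spec: HierClusterSpec) -> dict:
    return {"spec": asdict(spec)}
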