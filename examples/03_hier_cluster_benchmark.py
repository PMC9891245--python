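"""Hierarchical cluster graph classification: node2vec vs node2vec+.

Generates the K3L2 benchmark (13 Gaussian clusters on a 3-ary, 2-level
tree; 390 nodes; fully connected RBF-kernel graph), embeds it with both
methods at p=1, q=100, and scores cluster- and level-classification with
an l2 logistic probe (10% train / 90% test, fresh embedding per repeat).
Three repeats here to keep the demo quick; the test suite runs ten.
"""

import warnings

from n2vplus import HierClusterSpec, SplitSpec, make_hier_cluster_graph
from n2vplus.evaluation import embedding_factory, evaluate_multiclass
from n2vplus.walk import WalkConfig

lg = make_hier_cluster_graph(HierClusterSpec(seed=0))
labels = {
    "cluster": dict(zip(lg.graph.node_ids, map(int, lg.cluster_label))),
    "level": dict(zip(lg.graph.node_ids, map(int, lg.level_label))),
}
split = SplitSpec(train_fraction=0.1, repeats=3, seed=0)

print("K3L2: 390 nodes, fully connected, sigma=0.1; macro F1, mean of 3 repeats")
for mode in ("node2vec", "node2vecplus"):
    factory = embedding_factory(lg.graph, WalkConfig(p=1.0, q=100.0, mode=mode))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate_multiclass(factory, labels, split)
    means = report.task_means("test")
    print(f"  {mode:14s} cluster = {means['cluster']:.3f}   level = {means['level']:.3f}")
print("\nOn a fully connected weighted graph node2vec cannot exploit q, so its"
      "\nwalks stay first-order; node2vec+ suppresses loose inter-cluster edges"
      "\nand recovers the cluster structure.")
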