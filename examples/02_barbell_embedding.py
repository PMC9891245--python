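"""Embedding the perturbed barbell graph.

Two complete 20-node modules joined by a bridge node, perturbed with
0.1-weight loose edges so the graph is complete.  node2vec sees every
candidate step as an "in" edge on a complete graph, so (with p=1) its walks
ignore q entirely; node2vec+ recognises the loose edges and responds to q.
We quantify module structure by mean cosine similarity within vs across
modules.
"""

import numpy as np

from n2vplus import make_barbell, train_embeddings, generate_walks
from n2vplus.walk import WalkConfig

bb = make_barbell(module_size=20, noise_weight=0.1)
ids = bb.graph.node_ids
side = np.array([v[0] for v in ids])  # 'a' / 'b' modules, bridge


def module_cohesion(mode: str, q: float, seed: int = 0) -> tuple[float, float]:
    cfg = WalkConfig(p=1.0, q=q, mode=mode, seed=seed)
    emb = train_embeddings(generate_walks(bb.graph, cfg), dim=32, seed=seed)
    X = emb.subset(ids)
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    a, b = X[side == "a"], X[side == "b"]
    return float((a @ a.T).mean() + (b @ b.T).mean()) / 2, float((a @ b.T).mean())


print(f"{'mode':14s} {'q':>6s} {'within-module':>14s} {'across-modules':>15s}")
for mode in ("node2vec", "node2vecplus"):
    for q in (0.01, 100.0):
        w, x = module_cohesion(mode, q)
        print(f"{mode:14s} {q:6g} {w:14.3f} {x:15.3f}")
print("\nnode2vec's rows are identical for both q (no out edges on a complete"
      "\ngraph); node2vec+ separates the modules sharply at q=100 and mixes"
      "\nthem at q=0.01, as the in-out parameter is supposed to do.")
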