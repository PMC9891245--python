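"""Independent brute-force oracle for second-order transition probabilities.

Evaluates the walk-bias definitions literally on plain dict/list structures,
sharing no code with the package's graph or walk modules.  Used to verify
the CSR-based implementation entry-wise.
"""

from __future__ import annotations


def oracle_transition(
    edges: dict[tuple[str, str], float],
    vp: str | None,
    vc: str,
    mode: str,
    p: float = 1.0,
    q: float = 1.0,
    gamma: float = 0.0,
    eps: float = 1e-6,
) -> dict[str, float]:
    """Exact next-step distribution from a literal reading of the formulas.

    ``edges`` maps ordered pairs to weights and must contain both (u, v)
    and (v, u) for every undirected edge.
    """
    nodes = sorted({u for u, _ in edges} | {v for _, v in edges})

    def w(u, v):
        return edges.get((u, v), 0.0)

    def nbrs(v):
        return [u for u in nodes if w(v, u) > 0]

    def mu(v):
        ws = [w(v, u) for u in nbrs(v)]
        return sum(ws) / len(ws)

    def sigma(v):
        m = mu(v)
        ws = [w(v, u) for u in nbrs(v)]
        return (sum((x - m) ** 2 for x in ws) / len(ws)) ** 0.5

    def wtilde(v, u):
        return w(v, u) / max(mu(v) + gamma * sigma(v), eps)

    # Tightness is tested with a 1e-9 margin: an edge exactly on the w~ = 1
    # boundary in real arithmetic (e.g. the larger edge of a degree-2 node
    # at gamma=1) is tight, and must not flip branch under fp rounding.
    def alpha(vn):
        if vp is None or mode == "first_order":
            return 1.0
        if vn == vp:
            return 1.0 / p
        if mode == "node2vec":
            return 1.0 if w(vn, vp) > 0 else 1.0 / q
        a = wtilde(vn, vp)
        if a >= 1.0 - 1e-9:
            return 1.0
        b = wtilde(vc, vn)
        if b < 1.0 - 1e-9:
            return min(1.0, 1.0 / q)
        return 1.0 / q + (1.0 - 1.0 / q) * a

    scores = {vn: alpha(vn) * w(vc, vn) for vn in nbrs(vc)}
    total = sum(scores.values())
    return {vn: s / total for vn, s in scores.items()}
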