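"""Numba kernels: biased walk simulation on CSR adjacencies and SGNS training.

Kept separate from the public modules so the jitted code stays small and the
Python-level API remains readable.  All kernels are single-threaded and use
``np.random.seed`` with explicitly derived stream seeds, so a fixed master
seed gives a bitwise-reproducible walk corpus and embedding.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_FIRST_ORDER = 0
MODE_NODE2VEC = 1
MODE_NODE2VECPLUS = 2


@njit(cache=True, inline="always")
def _edge_weight(indptr, indices, data, u, v):
    """Weight of directed CSR entry (u, v); 0.0 if absent. Binary search."""
    lo = indptr[u]
    hi = indptr[u + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        m = indices[mid]
        if m == v:
            return data[mid]
        elif m < v:
            lo = mid + 1
        else:
            hi = mid
    return 0.0


@njit(cache=True)
def _step_scores(indptr, indices, data, den, mode, p, q, prev, cur, scores):
    """Unnormalized transition scores alpha*w over the neighbors of ``cur``.

    ``prev`` = -1 denotes the first step of a walk (first-order move).
    ``den`` is the per-node clipped denominator max(mu + gamma*sigma, eps);
    only read in node2vec+ mode.  Returns the number of neighbors.
    """
    lo = indptr[cur]
    hi = indptr[cur + 1]
    k = 0
    for e in range(lo, hi):
        nb = indices[e]
        w = data[e]
        if prev < 0 or mode == MODE_FIRST_ORDER:
            alpha = 1.0
        elif nb == prev:
            alpha = 1.0 / p
        elif mode == MODE_NODE2VEC:
            if _edge_weight(indptr, indices, data, nb, prev) > 0.0:
                alpha = 1.0
            else:
                alpha = 1.0 / q
        else:  # node2vec+ (1e-9 margin: boundary edges are tight)
            a = _edge_weight(indptr, indices, data, nb, prev) / den[nb]
            if a >= 1.0 - 1e-9:
                alpha = 1.0  # in edge: candidate tightly connected to prev
            else:
                b = w / den[cur]
                if b < 1.0 - 1e-9:
                    alpha = min(1.0, 1.0 / q)  # noisy edge: never amplified
                else:
                    alpha = 1.0 / q + (1.0 - 1.0 / q) * a  # out edge, interpolated
        scores[k] = alpha * w
        k += 1
    return k


@njit(cache=True)
def _simulate_walks(
    indptr, indices, data, den, mode, p, q, starts, seeds, walk_length
):
    """Simulate one walk per start node; walks[i, :] are node indices (-1 pad)."""
    n_walks = starts.shape[0]
    max_deg = 0
    n = indptr.shape[0] - 1
    for v in range(n):
        d = indptr[v + 1] - indptr[v]
        if d > max_deg:
            max_deg = d
    walks = np.full((n_walks, walk_length), -1, dtype=np.int64)
    scores = np.empty(max_deg, dtype=np.float64)
    for i in range(n_walks):
        np.random.seed(seeds[i])
        cur = starts[i]
        prev = -1
        walks[i, 0] = cur
        for t in range(1, walk_length):
            k = _step_scores(indptr, indices, data, den, mode, p, q, prev, cur, scores)
            if k == 0:
                break  # dead end; unreachable on connected undirected graphs
            total = 0.0
            for j in range(k):
                total += scores[j]
            if total <= 0.0:
                break
            r = np.random.random() * total
            acc = 0.0
            pick = k - 1
            for j in range(k):
                acc += scores[j]
                if r < acc:
                    pick = j
                    break
            nxt = indices[indptr[cur] + pick]
            walks[i, t] = nxt
            prev = cur
            cur = nxt
    return walks


@njit(cache=True, fastmath=True)
def _train_sgns(
    tokens,
    offsets,
    vocab_size,
    dim,
    window,
    negative,
    epochs,
    alpha0,
    seed,
    neg_table,
):
    """Skipgram with negative sampling over a walk corpus.

    ``tokens`` is the flat corpus of vocabulary indices; ``offsets`` delimits
    sentences (walks).  Follows the reference word2vec semantics: dynamic
    window shrinking, sigmoid clipped at |x| = 6, linear learning-rate decay
    to 1e-4 of the initial rate, unigram^(3/4) negative table.  Returns the
    input (center-word) matrix.
    """
    np.random.seed(seed)
    syn0 = ((np.random.random((vocab_size, dim)) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((vocab_size, dim), dtype=np.float32)
    neu1e = np.zeros(dim, dtype=np.float32)
    table_size = neg_table.shape[0]
    n_tokens = tokens.shape[0]
    total = n_tokens * epochs
    processed = 0
    n_sent = offsets.shape[0] - 1
    for _ep in range(epochs):
        for s in range(n_sent):
            start = offsets[s]
            end = offsets[s + 1]
            for i in range(start, end):
                alpha = alpha0 * (1.0 - processed / (total + 1.0))
                if alpha < alpha0 * 1e-4:
                    alpha = alpha0 * 1e-4
                processed += 1
                center = tokens[i]
                shrink = np.random.randint(window)
                lo = i - window + shrink
                if lo < start:
                    lo = start
                hi = i + window - shrink
                if hi > end - 1:
                    hi = end - 1
                for jpos in range(lo, hi + 1):
                    if jpos == i:
                        continue
                    ctx = tokens[jpos]
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = center
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(table_size)]
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += syn0[ctx, d] * syn1[target, d]
                        if f > 6.0:
                            g = (label - 1.0) * alpha
                        elif f < -6.0:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        for d in range(dim):
                            neu1e[d] += g * syn1[target, d]
                        for d in range(dim):
                            syn1[target, d] += g * syn0[ctx, d]
                    for d in range(dim):
                        syn0[ctx, d] += neu1e[d]
    return syn0
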