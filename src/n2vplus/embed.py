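"""Skipgram-with-negative-sampling embeddings from a walk corpus.

Walks are treated as sentences and nodes as words; the embedding maximises
the probability of reconstructing each node's sampled neighborhood (the
nodes co-occurring within a context window), with the softmax partition
function approximated by negative sampling.  The trainer is a compact,
single-threaded numba kernel following the reference word2vec semantics
(dynamic window shrinking, unigram^0.75 negative table, linear
learning-rate decay), so a fixed seed yields a bitwise-identical matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import _train_sgns
from .walk import WalkCorpus

__all__ = ["EmbeddingMatrix", "train_embeddings", "load_word2vec", "save_word2vec"]

NEG_TABLE_SIZE = 1_000_000
NEG_POWER = 0.75


@dataclass
class EmbeddingMatrix:
    """Dense node embedding: one row per node, in ``node_ids`` order."""

    node_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("vectors must be (n_nodes, dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]

    def subset(self, nodes: list[str]) -> np.ndarray:
        """Row matrix for the given nodes, in the given order."""
        return self.vectors[[self._index[v] for v in nodes]]

    def save(self, path: str | Path) -> None:
        save_word2vec(self, path)


def _build_vocab(corpus: WalkCorpus) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for walk in corpus.walks:
        for v in walk:
            counts[v] = counts.get(v, 0) + 1
    # frequency-descending, ties broken by node id: deterministic vocab order
    vocab = sorted(counts, key=lambda v: (-counts[v], v))
    index = {v: i for i, v in enumerate(vocab)}
    freq = np.array([counts[v] for v in vocab], dtype=np.float64)
    return vocab, index, freq


def _negative_table(freq: np.ndarray, size: int = NEG_TABLE_SIZE) -> np.ndarray:
    """Unigram^0.75 sampling table: index i appears proportional to freq_i^0.75."""
    probs = freq**NEG_POWER
    probs /= probs.sum()
    bounds = np.cumsum(probs) * size
    table = np.searchsorted(bounds, np.arange(size) + 0.5).astype(np.int64)
    return np.minimum(table, freq.size - 1)


def train_embeddings(
    corpus: WalkCorpus,
    dim: int = 128,
    window: int = 10,
    epochs: int = 1,
    negative: int = 5,
    alpha: float = 0.025,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Train an embedding covering every node that appears in the corpus.

    ``dim=128`` and ``window=10`` are the defaults used throughout; one
    training epoch suffices because the corpus already repeats each start
    node ``num_walks`` times.  Deterministic for a fixed seed (the kernel
    is single-threaded).
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    if dim < 1 or window < 1:
        raise ValueError("dim and window must be >= 1")
    vocab, index, freq = _build_vocab(corpus)
    offsets = np.zeros(len(corpus.walks) + 1, dtype=np.int64)
    for i, walk in enumerate(corpus.walks):
        offsets[i + 1] = offsets[i] + len(walk)
    tokens = np.empty(offsets[-1], dtype=np.int64)
    pos = 0
    for walk in corpus.walks:
        for v in walk:
            tokens[pos] = index[v]
            pos += 1
    neg_table = _negative_table(freq)
    syn0 = _train_sgns(
        tokens,
        offsets,
        len(vocab),
        dim,
        window,
        negative,
        epochs,
        alpha,
        np.uint32(seed % (2**32)),
        neg_table,
    )
    return EmbeddingMatrix(node_ids=vocab, vectors=np.asarray(syn0, dtype=np.float64))


def save_word2vec(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write the word2vec text format: header "n d", then "id v1 ... vd" rows."""
    with open(path, "w") as fh:
        fh.write(f"{len(emb.node_ids)} {emb.dim}\n")
        for node, row in zip(emb.node_ids, emb.vectors):
            fh.write(node + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def load_word2vec(path: str | Path) -> EmbeddingMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, d = int(header[0]), int(header[1])
        node_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"{path}: row for {parts[0]!r} has wrong width")
            node_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(node_ids) != n:
        raise ValueError(f"{path}: header announces {n} rows, found {len(node_ids)}")
    return EmbeddingMatrix(node_ids=node_ids, vectors=np.array(rows))
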