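"""Classification evaluation of node embeddings.

Embeddings are scored with logistic-regression probes: multinomial (macro
F1) for multiclass node labels, one-vs-rest binary probes scored with
log2(auPRC / prior) for collections of gene sets.  The module also provides
the split machinery (repeated random fractions, and the ranked "study-bias"
holdout where the best-annotated entities train and the least-annotated
test), exhaustive grid search over walk hyperparameters, and a Wilcoxon
paired comparison between two methods' reports.

log2(auPRC/prior) is the log2 fold change of average precision over the
positive-class prior; it corrects for class imbalance and emphasises the
correctness of top predictions, unlike AUROC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score

from .embed import EmbeddingMatrix, train_embeddings
from .graph import WeightedGraph
from .walk import WalkConfig, generate_walks

__all__ = [
    "SplitSpec",
    "EvalReport",
    "log2_auprc_prior",
    "evaluate_multiclass",
    "evaluate_multilabel",
    "grid_search",
    "paired_comparison",
    "node2vec_grid",
    "node2vecplus_grid",
    "embedding_factory",
    "read_label_tsv",
    "read_gmt",
]

# identical probe settings for every method under comparison (fairness)
PROBE_C = 1.0
PROBE_MAX_ITER = 1000

NODE2VEC_PQ = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0)
NODE2VECPLUS_PQ = (0.01, 0.1, 1.0, 10.0, 100.0)
NODE2VECPLUS_GAMMA = (0.0, 1.0, 2.0)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split specification.

    ``random_fraction``: per repeat, a fresh seeded shuffle assigns
    ``train_fraction`` of the nodes to train (then ``valid_fraction`` to
    validation, if nonzero) and the rest to test.

    ``ranked_holdout``: deterministic study-bias split — the top
    ``train_fraction`` of nodes by ``ranking_score`` train, the bottom
    ``test_fraction`` test, the middle validates.
    """

    mode: str = "random_fraction"
    train_fraction: float = 0.1
    valid_fraction: float = 0.0
    test_fraction: float | None = None
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random_fraction", "ranked_holdout"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        test = self.test_fraction
        if test is None:
            test = 1.0 - self.train_fraction - self.valid_fraction
        if self.train_fraction <= 0 or test <= 0:
            raise ValueError("train and test fractions must be positive")
        if self.train_fraction + self.valid_fraction + test > 1.0 + 1e-9:
            raise ValueError("fractions must sum to <= 1")

    def resolved_test_fraction(self) -> float:
        if self.test_fraction is not None:
            return self.test_fraction
        return 1.0 - self.train_fraction - self.valid_fraction


def study_bias_split() -> "SplitSpec":
    """The 60/20/20 ranked holdout used for gene classification tasks."""
    return SplitSpec(
        mode="ranked_holdout",
        train_fraction=0.6,
        valid_fraction=0.2,
        test_fraction=0.2,
        repeats=1,
    )


def iter_splits(
    n: int,
    spec: SplitSpec,
    ranking_score: Optional[np.ndarray] = None,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Yield ``(train_idx, valid_idx, test_idx)`` per repeat.

    Partitions are disjoint and reproducible from the seed.  For
    ``ranked_holdout`` the split is deterministic (ties broken by index) and
    identical across repeats.
    """
    n_train = max(1, int(round(spec.train_fraction * n)))
    n_valid = int(round(spec.valid_fraction * n))
    n_test = max(1, int(round(spec.resolved_test_fraction() * n)))
    if spec.mode == "ranked_holdout":
        if ranking_score is None:
            raise ValueError("ranked_holdout requires a ranking_score")
        order = np.argsort(-np.asarray(ranking_score), kind="stable")
        train = order[:n_train]
        test = order[n - n_test :]
        valid = order[n_train : n - n_test]
        for _ in range(spec.repeats):
            yield train, valid, test
        return
    for r in range(spec.repeats):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(r,)))
        order = rng.permutation(n)
        train = order[:n_train]
        valid = order[n_train : n_train + n_valid]
        test = order[n_train + n_valid : n_train + n_valid + n_test]
        yield train, valid, test


@dataclass
class EvalReport:
    """Long-format record of per-(task, repeat, split) metric values."""

    records: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def add(self, task: str, repeat: int, split: str, metric: str, value: float) -> None:
        self.records.append(
            {"task": task, "repeat": repeat, "split": split,
             "metric": metric, "value": value}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def tasks(self, split: str = "test") -> list[str]:
        return sorted({r["task"] for r in self.records if r["split"] == split})

    def task_means(self, split: str = "test") -> pd.Series:
        df = self.to_frame()
        df = df[df["split"] == split]
        return df.groupby("task")["value"].mean()

    def mean(self, split: str = "test") -> float:
        return float(self.task_means(split).mean())

    def save(self, prefix: str | Path) -> None:
        """Write the long table as TSV and a JSON summary next to it."""
        prefix = str(prefix)
        self.to_frame().to_csv(prefix + ".tsv", sep="\t", index=False)
        summary = {
            "meta": self.meta,
            "task_means_test": {
                k: float(v) for k, v in self.task_means("test").items()
            },
            "mean_test": self.mean("test"),
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)

    @classmethod
    def load(cls, prefix: str | Path) -> "EvalReport":
        df = pd.read_csv(str(prefix) + ".tsv", sep="\t")
        return cls(records=df.to_dict("records"))


def log2_auprc_prior(labels: np.ndarray, scores: np.ndarray) -> float:
    """log2 of average precision over the positive-class prior.

    0 means chance-level ranking; log2(1/prior) is the ceiling reached by a
    perfect ranking.  Invariant under strictly monotone transforms of the
    scores.  Requires at least one positive and one negative label.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("need at least one positive and one negative label")
    ap = average_precision_score(labels, scores)
    prior = n_pos / labels.size
    return float(np.log2(ap / prior))


EmbeddingSource = EmbeddingMatrix | Callable[[int], EmbeddingMatrix]


def embedding_factory(
    g: WeightedGraph,
    walk_cfg: WalkConfig,
    dim: int = 128,
    window: int = 10,
    epochs: int = 1,
    negative: int = 5,
) -> Callable[[int], EmbeddingMatrix]:
    """Closure regenerating walks + embedding from a per-repeat seed.

    Used when the full evaluation (embedding generation included) is
    repeated: each repeat reruns the walks and the trainer under a fresh
    derived seed.
    """

    def make(seed: int) -> EmbeddingMatrix:
        cfg = replace(walk_cfg, seed=int(seed))
        corpus = generate_walks(g, cfg)
        return train_embeddings(
            corpus, dim=dim, window=window, epochs=epochs,
            negative=negative, seed=int(seed),
        )

    return make


def _repeat_seed(master: int, repeat: int) -> int:
    state = np.random.SeedSequence(master, spawn_key=(repeat, 1)).generate_state(1)[0]
    return int(state % (2**31))


def _resolve_embedding(emb: EmbeddingSource, master_seed: int, repeat: int):
    if callable(emb):
        return emb(_repeat_seed(master_seed, repeat))
    return emb


def evaluate_multiclass(
    emb: EmbeddingSource,
    labels: Mapping[str, int],
    split: SplitSpec,
    task_names: Mapping[str, str] | None = None,
) -> EvalReport:
    """Repeated multiclass probe: l2 multinomial logistic regression, macro F1.

    ``emb`` is either a fixed :class:`EmbeddingMatrix` or a callable
    ``seed -> EmbeddingMatrix`` (see :func:`embedding_factory`), in which
    case a fresh embedding is generated for every repeat.  ``labels`` may
    hold several label columns via nested mapping; plain mapping = single
    task named "multiclass".

    A class absent from a repeat's training rows is recorded as missing
    with a warning; macro F1 is then computed over the classes present in
    training, never silently dropped.
    """
    tasks: dict[str, Mapping[str, int]]
    if labels and isinstance(next(iter(labels.values())), Mapping):
        tasks = dict(labels)  # type: ignore[arg-type]
    else:
        tasks = {"multiclass": labels}
    report = EvalReport(meta={"split": split.mode, "repeats": split.repeats})
    for repeat in range(split.repeats):
        matrix = _resolve_embedding(emb, split.seed, repeat)
        for task, lab in tasks.items():
            nodes = [v for v in matrix.node_ids if v in lab]
            y = np.array([lab[v] for v in nodes])
            if np.unique(y).size < 2:
                raise ValueError(f"task {task!r} needs >= 2 classes")
            X = matrix.subset(nodes)
            splits = list(iter_splits(len(nodes), replace(split, repeats=1, seed=_repeat_seed(split.seed, repeat))))
            train, _valid, test = splits[0]
            present = np.unique(y[train])
            missing = np.setdiff1d(np.unique(y), present)
            if missing.size:
                warnings.warn(
                    f"task {task!r} repeat {repeat}: classes {missing.tolist()} absent "
                    "from training; macro F1 computed over present classes",
                    stacklevel=2,
                )
            clf = LogisticRegression(C=PROBE_C, max_iter=PROBE_MAX_ITER)
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            score = f1_score(
                y[test], pred, labels=present, average="macro", zero_division=0
            )
            report.add(task, repeat, "test", "macro_f1", float(score))
    return report


def evaluate_multilabel(
    emb: EmbeddingMatrix,
    genesets: Mapping[str, set[str]],
    split: SplitSpec,
    ranking_score: Mapping[str, float] | None = None,
) -> EvalReport:
    """One-vs-rest binary probes over gene sets, scored by log2(auPRC/prior).

    The default protocol is the ranked study-bias holdout (60/20/20): the
    most-annotated genes train, the least-annotated test.  Validation and
    test metrics are both reported (validation drives model selection).
    Tasks lacking a positive in train or test are skipped with a warning
    and listed in the report metadata.
    """
    nodes = list(emb.node_ids)
    X = emb.vectors
    if split.mode == "ranked_holdout":
        if ranking_score is None:
            raise ValueError("ranked_holdout requires per-node ranking scores")
        scores_arr = np.array([ranking_score.get(v, 0.0) for v in nodes])
    else:
        scores_arr = None
    report = EvalReport(meta={"split": split.mode, "skipped": []})
    splits = list(iter_splits(len(nodes), split, ranking_score=scores_arr))
    for repeat, (train, valid, test) in enumerate(splits):
        for task, members in sorted(genesets.items()):
            y = np.array([v in members for v in nodes], dtype=int)
            if y[train].sum() == 0 or y[test].sum() == 0:
                warnings.warn(
                    f"task {task!r}: no positive example in train or test; skipped",
                    stacklevel=2,
                )
                report.meta["skipped"].append(task)
                continue
            clf = LogisticRegression(C=PROBE_C, max_iter=PROBE_MAX_ITER)
            clf.fit(X[train], y[train])
            for split_name, idx in (("valid", valid), ("test", test)):
                if idx.size == 0:
                    continue
                prob = clf.predict_proba(X[idx])[:, 1]
                if 0 < y[idx].sum() < idx.size:
                    report.add(
                        task, repeat, split_name, "log2_auprc_prior",
                        log2_auprc_prior(y[idx], prob),
                    )
    return report


def node2vec_grid(
    p_values: Sequence[float] = NODE2VEC_PQ,
    q_values: Sequence[float] = NODE2VEC_PQ,
    **cfg_kwargs,
) -> list[WalkConfig]:
    """The (p, q) tuning grid for node2vec: 9 x 9 = 81 configurations."""
    return [
        WalkConfig(p=p, q=q, mode="node2vec", **cfg_kwargs)
        for p in sorted(p_values)
        for q in sorted(q_values)
    ]


def node2vecplus_grid(
    p_values: Sequence[float] = NODE2VECPLUS_PQ,
    q_values: Sequence[float] = NODE2VECPLUS_PQ,
    gamma_values: Sequence[float] = NODE2VECPLUS_GAMMA,
    **cfg_kwargs,
) -> list[WalkConfig]:
    """The (p, q, gamma) grid for node2vec+: 5 x 5 x 3 = 75 configurations."""
    return [
        WalkConfig(p=p, q=q, gamma=g, mode="node2vecplus", **cfg_kwargs)
        for p in sorted(p_values)
        for q in sorted(q_values)
        for g in sorted(gamma_values)
    ]


def grid_search(
    configs: Sequence[WalkConfig],
    objective: Callable[[WalkConfig], float],
) -> tuple[WalkConfig, pd.DataFrame]:
    """Exhaustive search: evaluate every config, return the argmax and the table.

    Ties break deterministically toward the first config in enumeration
    order (grids enumerate sorted p, then q, then gamma).
    """
    if not configs:
        raise ValueError("empty grid")
    rows = []
    best_cfg, best_val = None, -np.inf
    for cfg in configs:
        val = float(objective(cfg))
        rows.append(
            {"p": cfg.p, "q": cfg.q, "gamma": cfg.gamma, "mode": cfg.mode,
             "objective": val}
        )
        if val > best_val:
            best_cfg, best_val = cfg, val
    return best_cfg, pd.DataFrame(rows)


def paired_comparison(
    report_a: EvalReport, report_b: EvalReport, split: str = "test"
) -> dict:
    """Wilcoxon signed-rank test on per-task paired metric values.

    Per-task values are means over repeats.  Zero differences are dropped
    (signed-rank convention); the exact null is used for <= 25 informative
    pairs, the normal approximation with continuity correction above.  If
    every difference is zero the result is the "no difference" sentinel
    (p = 1, statistic NaN).
    """
    a = report_a.task_means(split)
    b = report_b.task_means(split)
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(
            f"task sets differ: only in A {only_a}, only in B {only_b}"
        )
    tasks = sorted(a.index)
    diffs = (b[tasks] - a[tasks]).to_numpy(dtype=float)
    nonzero = diffs[diffs != 0]
    result = {
        "n_tasks": len(tasks),
        "differences": dict(zip(tasks, diffs)),
        "median_difference": float(np.median(diffs)),
    }
    if nonzero.size == 0:
        result.update({"statistic": float("nan"), "pvalue": 1.0,
                       "note": "no difference"})
        return result
    if nonzero.size <= 25:
        stat, p = stats.wilcoxon(nonzero, method="exact")
    else:
        stat, p = stats.wilcoxon(nonzero, method="approx", correction=True)
    result.update({"statistic": float(stat), "pvalue": float(p)})
    return result


def read_label_tsv(path: str | Path) -> dict[str, int]:
    """Read a (node_id, label) TSV; a header line is skipped if non-numeric."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            parts = line.split()
            if not parts or line.startswith("#"):
                continue
            if lineno == 0:
                try:
                    int(parts[1])
                except (ValueError, IndexError):
                    continue
            out[parts[0]] = int(parts[1])
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set format: task_id <tab> description <tab> member1 <tab> ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out
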