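"""Evaluation protocols: pair-level k-fold CV, cold-start disease holdout,
metric suite and top-k recovery.

Pair-level CV partitions the known (positive) drug-disease pairs into k
folds; each fold's positives are masked out of the training adjacency
and scored against all never-positive pairs.  The cold-start ("novel
disease") protocol instead holds out a fraction of disease columns
entirely, so the held-out diseases are unseen nodes.  Leakage is
asserted programmatically on every split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    recall_score,
    roc_auc_score,
)

from .model import EMPHCN, LossSpec, ModelConfig
from .netio import AssociationMatrix, HeteroNetwork

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    """One train/test partition of drug-disease pairs (index pairs)."""

    fold_id: int
    train_positive_pairs: list[tuple[int, int]]
    test_positive_pairs: list[tuple[int, int]]
    train_negative_pairs: list[tuple[int, int]]
    test_negative_pairs: list[tuple[int, int]]

    def __post_init__(self):
        overlap = set(self.train_positive_pairs) & set(self.test_positive_pairs)
        if overlap:
            raise AssertionError(f"leakage: {len(overlap)} pairs in train and test")

    def training_adjacency(self, shape: tuple[int, int]) -> np.ndarray:
        a = np.zeros(shape, dtype=np.float64)
        for i, j in self.train_positive_pairs:
            a[i, j] = 1.0
        return a

    def assert_no_leakage(self, assoc: AssociationMatrix) -> None:
        a_train = self.training_adjacency(assoc.matrix.shape)
        for i, j in self.test_positive_pairs:
            assert a_train[i, j] == 0, "test positive present in training adjacency"
        for i, j in self.train_positive_pairs:
            assert assoc.matrix[i, j] == 1
        for i, j in self.test_negative_pairs:
            assert assoc.matrix[i, j] == 0


@dataclass
class EvalReport:
    """Aggregate metrics with per-fold breakdown and config echo."""

    per_fold: list[dict]
    mean: dict = field(init=False)
    sd: dict = field(init=False)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [k for k in self.per_fold[0] if isinstance(self.per_fold[0][k], float)]
        self.mean = {k: float(np.mean([f[k] for f in self.per_fold])) for k in keys}
        self.sd = {k: float(np.std([f[k] for f in self.per_fold])) for k in keys}


def kfold_pair_split(assoc: AssociationMatrix, k: int, seed: int,
                     neg_ratio: Optional[float] = None,
                     positive_fraction: float = 1.0) -> list[FoldSplit]:
    """Shuffle positives by seed and partition into k near-equal folds.

    All never-positive pairs are test negatives.  Training negatives are
    all of them by default, or a per-fold subsample at ``neg_ratio``
    negatives per positive.  ``positive_fraction`` < 1 discards a random
    share of positives before splitting (positive-subsampling sweep).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    pos = [tuple(p) for p in np.argwhere(assoc.matrix == 1)]
    if len(pos) < k:
        raise ValueError("fewer positives than folds")
    if positive_fraction < 1.0:
        n_keep = max(k, int(round(positive_fraction * len(pos))))
        keep_idx = rng.choice(len(pos), size=n_keep, replace=False)
        pos = [pos[i] for i in sorted(keep_idx)]
    order = rng.permutation(len(pos))
    neg = [tuple(p) for p in np.argwhere(assoc.matrix == 0)]
    folds = []
    bounds = np.linspace(0, len(pos), k + 1).astype(int)
    for f in range(k):
        test_idx = set(order[bounds[f]:bounds[f + 1]].tolist())
        test_pos = [pos[i] for i in sorted(test_idx)]
        train_pos = [pos[i] for i in range(len(pos)) if i not in test_idx]
        if neg_ratio is None:
            train_neg = neg
        else:
            n_train_neg = min(len(neg), int(round(neg_ratio * len(train_pos))))
            sel = rng.choice(len(neg), size=n_train_neg, replace=False)
            train_neg = [neg[i] for i in sorted(sel)]
        split = FoldSplit(f, train_pos, test_pos, train_neg, neg)
        split.assert_no_leakage(assoc)
        folds.append(split)
    all_test = [p for s in folds for p in s.test_positive_pairs]
    assert len(all_test) == len(set(all_test)) == len(pos), "folds must partition positives"
    return folds


def novel_disease_split(assoc: AssociationMatrix, fraction: float, seed: int,
                        _retry: bool = True) -> FoldSplit:
    """Hold out a fraction of disease columns entirely (cold start).

    All positives in held-out columns become test positives and are
    removed from the training adjacency; test negatives are the other
    pairs in those columns.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    m, n = assoc.matrix.shape
    n_held = max(1, int(round(fraction * n)))
    held = set(rng.choice(n, size=n_held, replace=False).tolist())
    test_pos = [(i, j) for i, j in np.argwhere(assoc.matrix == 1) if j in held]
    if not test_pos:
        if _retry:
            return novel_disease_split(assoc, fraction, seed + 1, _retry=False)
        raise ValueError("held-out diseases have no positives")
    train_pos = [(i, j) for i, j in np.argwhere(assoc.matrix == 1) if j not in held]
    test_neg = [(i, j) for i, j in np.argwhere(assoc.matrix == 0) if j in held]
    train_neg = [(i, j) for i, j in np.argwhere(assoc.matrix == 0) if j not in held]
    split = FoldSplit(0, train_pos, test_pos, train_neg, test_neg)
    split.assert_no_leakage(assoc)
    return split


def novel_disease_partition(assoc: AssociationMatrix, folds: int, seed: int) -> list[FoldSplit]:
    """Disjoint cold-start partition covering every disease exactly once."""
    rng = np.random.default_rng(seed)
    m, n = assoc.matrix.shape
    order = rng.permutation(n)
    bounds = np.linspace(0, n, folds + 1).astype(int)
    splits = []
    for f in range(folds):
        held = set(order[bounds[f]:bounds[f + 1]].tolist())
        test_pos = [(i, j) for i, j in np.argwhere(assoc.matrix == 1) if j in held]
        train_pos = [(i, j) for i, j in np.argwhere(assoc.matrix == 1) if j not in held]
        test_neg = [(i, j) for i, j in np.argwhere(assoc.matrix == 0) if j in held]
        train_neg = [(i, j) for i, j in np.argwhere(assoc.matrix == 0) if j not in held]
        split = FoldSplit(f, train_pos, test_pos, train_neg, test_neg)
        split.assert_no_leakage(assoc)
        splits.append(split)
    return splits


def compute_metrics(scored_pairs, threshold: float = 0.5) -> dict:
    """AUROC, AUPR and thresholded recall/accuracy/F1 for (score, label)s.

    AUROC uses the rank statistic with tie averaging; AUPR is the
    step-wise (non-interpolated) precision-recall integral — the variant
    matters at the extreme positive sparsity typical here.
    """
    scores = np.asarray([s for s, _ in scored_pairs], dtype=np.float64)
    labels = np.asarray([int(l) for _, l in scored_pairs])
    if labels.min() == labels.max():
        raise ValueError("both classes required to compute metrics")
    pred = (scores >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
        "accuracy": float(accuracy_score(labels, pred)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
    }


def topk_recovery(scored_pairs, k: int) -> int:
    """Test positives among the k top-scoring test pairs (ties by order)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scored_pairs):
        raise ValueError("k exceeds the number of scored pairs")
    order = sorted(range(len(scored_pairs)),
                   key=lambda i: (-scored_pairs[i][0], i))
    return int(sum(scored_pairs[i][1] for i in order[:k]))


def degree_product_scores(a_train: np.ndarray) -> np.ndarray:
    """Popularity baseline: score_ij = deg(drug i) * deg(disease j)."""
    a = np.asarray(a_train, dtype=np.float64)
    return np.outer(a.sum(axis=1), a.sum(axis=0))


def _score_split(scores: np.ndarray, split: FoldSplit) -> list[tuple[float, int]]:
    pairs = [(float(scores[i, j]), 1) for i, j in split.test_positive_pairs]
    pairs += [(float(scores[i, j]), 0) for i, j in split.test_negative_pairs]
    return pairs


def cross_validate(network: HeteroNetwork, cfg: ModelConfig,
                   protocol: str = "kfold", folds: int = 10, repeats: int = 1,
                   fraction: float = 0.2, seed: int = 0,
                   neg_ratio: Optional[float] = None,
                   epochs: Optional[int] = None,
                   partition_mode: bool = False) -> EvalReport:
    """Train a fresh model per fold/repeat and aggregate the metric suite.

    ``protocol='kfold'`` runs pair-level CV; ``'novel_disease'`` runs the
    cold-start holdout, repeated with distinct seeds (or, with
    ``partition_mode``, as a disjoint partition of diseases).
    """
    assoc = network.assoc
    if protocol == "kfold":
        splits = []
        for rep in range(repeats):
            splits += kfold_pair_split(assoc, folds, seed + rep, neg_ratio=neg_ratio)
    elif protocol == "novel_disease":
        if partition_mode:
            splits = novel_disease_partition(assoc, repeats, seed)
        else:
            splits = [novel_disease_split(assoc, fraction, seed + rep)
                      for rep in range(repeats)]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    per_fold = []
    for idx, split in enumerate(splits):
        split.assert_no_leakage(assoc)
        a_train = split.training_adjacency(assoc.matrix.shape)
        spec = LossSpec(
            positive_mask=a_train > 0,
            negative_mask=_pair_mask(split.train_negative_pairs, assoc.matrix.shape),
        )
        fold_cfg = ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + idx})
        emp = EMPHCN(network, fold_cfg)
        emp.fit(a_train=a_train, loss_spec=spec, epochs=epochs)
        scores = emp.predict(a_train=a_train)
        metrics = compute_metrics(_score_split(scores, split))
        metrics["fold"] = split.fold_id
        metrics["final_loss"] = emp.training_log[-1]["loss"] if emp.training_log else float("nan")
        per_fold.append(metrics)
        logger.info("fold %d: %s", idx, {k: round(v, 4) for k, v in metrics.items()
                                         if isinstance(v, float)})
    return EvalReport(per_fold=per_fold, config={**cfg.__dict__, "protocol": protocol,
                                                 "folds": folds, "repeats": repeats,
                                                 "seed": seed, "epochs": epochs})


def _pair_mask(pairs, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for i, j in pairs:
        mask[i, j] = True
    return mask
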