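"""Pair-counting F-measure and per-class purity for clustering evaluation.

A clustering is viewed as one co-assignment decision per pair of events: a
true positive is a pair sharing both its ground-truth class and its predicted
cluster.  Precision ``P = TP/(TP+FP)``, recall ``R = TP/(TP+FN)`` and the
F-measure is their harmonic mean.  This pair-counting definition differs from
the FlowCAP challenge's per-class F-measure.

The purity measure scores each ground-truth class against the single cluster
with the largest overlap: ``S1`` = overlap / cluster size, ``S2`` = overlap /
class size, ``P = 2 S1 S2 / (S1 + S2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairConfusion", "pair_confusion", "f_measure", "p_measure", "PurityScore"]


@dataclass(frozen=True)
class PairConfusion:
    """Counts of event pairs: TP (same class & cluster), FP, FN."""

    TP: int
    FP: int
    FN: int


@dataclass(frozen=True)
class PurityScore:
    """Purity of one ground-truth class against its best-overlap cluster."""

    class_id: int
    best_cluster: int
    S1: float
    S2: float
    P: float


def _contingency(truth, pred):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and pred must be equal-length 1-D label vectors")
    classes, ti = np.unique(truth, return_inverse=True)
    clusters, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return classes, clusters, table


def _pairs(x):
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_confusion(truth, pred) -> PairConfusion:
    """Pair counts computed from the class x cluster contingency table."""
    truth = np.asarray(truth)
    if truth.size < 2:
        raise ValueError("need at least 2 events")
    _, _, table = _contingency(truth, pred)
    tp = int(_pairs(table).sum())
    same_cluster = int(_pairs(table.sum(axis=0)).sum())
    same_class = int(_pairs(table.sum(axis=1)).sum())
    return PairConfusion(TP=tp, FP=same_cluster - tp, FN=same_class - tp)


def f_measure(truth, pred) -> float:
    """Harmonic mean of pair-counting precision and recall, in [0, 1].

    Degenerate conventions: a labeling with no same-cluster pairs has
    precision 1; no same-class pairs gives recall 1; F is 0 whenever TP is 0
    while some same-class pair was missed.
    """
    c = pair_confusion(truth, pred)
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else 1.0
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else 1.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def p_measure(truth, pred) -> list[PurityScore]:
    """Per-class purity scores, one for each ground-truth class.

    For each class the cluster with the maximum overlap is selected (ties go
    to the lowest cluster id).
    """
    classes, clusters, table = _contingency(truth, pred)
    scores = []
    cluster_sizes = table.sum(axis=0)
    class_sizes = table.sum(axis=1)
    for k, class_id in enumerate(classes):
        if class_sizes[k] == 0:
            raise ValueError(f"class {class_id} is empty")
        j = int(np.argmax(table[k]))  # argmax takes the first (lowest id) tie
        overlap = table[k, j]
        s1 = overlap / cluster_sizes[j]
        s2 = overlap / class_sizes[k]
        p = 2 * s1 * s2 / (s1 + s2) if s1 + s2 > 0 else 0.0
        scores.append(
            PurityScore(
                class_id=class_id if np.isscalar(class_id) else class_id.item(),
                best_cluster=clusters[j] if np.isscalar(clusters[j]) else clusters[j].item(),
                S1=float(s1),
                S2=float(s2),
                P=float(p),
            )
        )
    return scores
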