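"""Partition-assisted clustering: refine a partition into K final clusters.

Pipeline: partition the marker space into N rectangles (DSP or BSP+LL), take
the per-leaf means as rational initial centers, run a small number of Lloyd
k-means iterations to round the rectangle corners, then merge the clusters
hierarchically down to K using a minimum squared-Mahalanobis cluster
distance,

    D(X, Y) = min{ (xbar-ybar)' Sx^-1 (xbar-ybar),
                   (xbar-ybar)' Sy^-1 (xbar-ybar) },

the same merging metric used by flowMeans.  The distance is used squared,
exactly as defined; no square root is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances_argmin

from .io_prep import EventMatrix
from .partition import bsp_ll_partition, dsp_partition, initial_centers

__all__ = [
    "ClusterSummary",
    "ClusterLabeling",
    "PacConfig",
    "kmeans_refine",
    "merge_distance",
    "merge_to_k",
    "pac",
    "summarize_clusters",
]

# Relative ridge added to each covariance before inversion; clusters smaller
# than n_markers + 1 events cannot support a full-rank sample covariance and
# fall back to its diagonal.
_COV_EPS = 1e-6


@dataclass
class ClusterSummary:
    """Mean, covariance and size of one cluster."""

    mean: np.ndarray
    covariance: np.ndarray
    size: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("cluster mean must be finite")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class ClusterLabeling:
    """Per-event integer labels in ``[0, n_clusters)`` plus summaries."""

    labels: np.ndarray
    summaries: list[ClusterSummary]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=len(self.summaries))
        if self.labels.size and self.labels.max() >= len(self.summaries):
            raise ValueError("label without a summary")
        if sum(s.size for s in self.summaries) != len(self.labels):
            raise ValueError("summary sizes do not sum to n_events")
        for k, s in enumerate(self.summaries):
            if s.size != sizes[k]:
                raise ValueError(f"summary {k} inconsistent with labels")

    @property
    def n_clusters(self) -> int:
        return len(self.summaries)


@dataclass
class PacConfig:
    """Settings for one PAC run.

    N initial rectangles (2-3x the expected number of subpopulations works
    well), K final clusters, m Lloyd iterations (50 suffices thanks to the
    rational initialization), partition method, and a seed recorded for
    reproducibility of any caller-side randomness (PAC itself is
    deterministic given the data).
    """

    N: int
    K: int
    m: int = 50
    method: str = "dsp"
    seed: int = 0
    min_leaf_size: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.K <= self.N:
            raise ValueError("need 1 <= K <= N")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.method not in ("dsp", "bsp_ll", "bsp"):
            raise ValueError(f"unknown partition method {self.method!r}")


def summarize_clusters(values: np.ndarray, labels: np.ndarray) -> list[ClusterSummary]:
    """Recompute per-cluster mean/covariance/size from a label vector."""
    summaries = []
    for k in range(int(labels.max()) + 1 if labels.size else 0):
        members = values[labels == k]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {k} is empty")
        cov = (
            np.cov(members, rowvar=False)
            if members.shape[0] > 1
            else np.zeros((values.shape[1], values.shape[1]))
        )
        summaries.append(
            ClusterSummary(members.mean(axis=0), np.atleast_2d(cov), members.shape[0])
        )
    return summaries


def _assign(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return pairwise_distances_argmin(values, centers)


def kmeans_refine(
    m: EventMatrix,
    centers: np.ndarray,
    iterations: int = 50,
) -> ClusterLabeling:
    """Lloyd iterations from the given centers.

    Runs exactly ``iterations`` assign/update rounds or stops early once the
    assignment no longer changes; ``iterations=0`` returns the plain
    nearest-center assignment.  Clusters emptied along the way are dropped and
    the labels compacted.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 1:
        raise ValueError("need at least one center")
    if centers.shape[1] != m.n_markers:
        raise ValueError(
            f"centers have {centers.shape[1]} dims, data has {m.n_markers}"
        )
    values = m.values
    labels = _assign(values, centers)
    for _ in range(iterations):
        # update step: mean of each non-empty cluster; empty ones are dropped
        live = np.unique(labels)
        centers = np.stack([values[labels == k].mean(axis=0) for k in live])
        new_labels = live[_assign(values, centers)]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    # compact labels to [0, n_clusters)
    live, labels = np.unique(labels, return_inverse=True)
    return ClusterLabeling(
        labels=labels,
        summaries=summarize_clusters(values, labels),
        sample_id=m.sample_id,
    )


def _regularized_inverse(s: ClusterSummary, n_markers: int, name) -> np.ndarray:
    cov = s.covariance
    if s.size < n_markers + 1:
        cov = np.diag(np.diag(cov))
    ridge = _COV_EPS * (np.trace(cov) / n_markers)
    cov = cov + ridge * np.eye(n_markers)
    try:
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance of cluster {name} is singular after regularization"
        ) from exc


def merge_distance(x: ClusterSummary, y: ClusterSummary) -> float:
    """Smaller of the two squared Mahalanobis distances between cluster means."""
    p = len(x.mean)
    d = x.mean - y.mean
    inv_x = _regularized_inverse(x, p, "X")
    inv_y = _regularized_inverse(y, p, "Y")
    return float(min(d @ inv_x @ d, d @ inv_y @ d))


def merge_to_k(m: EventMatrix, labeling: ClusterLabeling, K: int) -> ClusterLabeling:
    """Greedy hierarchical merging of the labeling down to K clusters.

    At each step the argmin pair under :func:`merge_distance` is merged (ties
    broken by the lowest index pair), events are pooled and the summary
    recomputed from them.  Event count is conserved.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > labeling.n_clusters:
        raise ValueError(
            f"K={K} exceeds current cluster count {labeling.n_clusters}"
        )
    values = m.values
    labels = labeling.labels.copy()
    summaries = {k: labeling.summaries[k] for k in range(labeling.n_clusters)}
    p = values.shape[1]

    inv = {k: _regularized_inverse(s, p, k) for k, s in summaries.items()}

    def dist(i, j):
        d = summaries[i].mean - summaries[j].mean
        return min(d @ inv[i] @ d, d @ inv[j] @ d)

    keys = sorted(summaries)
    dmat = {}
    for a_i, i in enumerate(keys):
        for j in keys[a_i + 1:]:
            dmat[(i, j)] = dist(i, j)

    while len(summaries) > K:
        (i, j) = min(dmat, key=lambda ij: (dmat[ij], ij))
        labels[labels == j] = i
        members = values[labels == i]
        cov = np.cov(members, rowvar=False) if members.shape[0] > 1 else np.zeros((p, p))
        summaries[i] = ClusterSummary(members.mean(axis=0), np.atleast_2d(cov), members.shape[0])
        inv[i] = _regularized_inverse(summaries[i], p, i)
        del summaries[j], inv[j]
        dmat = {ij: v for ij, v in dmat.items() if j not in ij}
        for k in summaries:
            if k == i:
                continue
            dmat[(min(i, k), max(i, k))] = dist(i, k)
    # compact the surviving labels, preserving original cluster order
    survivors, labels = np.unique(labels, return_inverse=True)
    return ClusterLabeling(
        labels=labels,
        summaries=summarize_clusters(values, labels),
        sample_id=labeling.sample_id,
    )


def pac(m: EventMatrix, cfg: PacConfig) -> ClusterLabeling:
    """Full partition-assisted clustering of one sample.

    partition(N) -> initial centers -> m k-means iterations -> merge to K.
    Deterministic given the data and configuration.
    """
    if cfg.method == "dsp":
        part = dsp_partition(m, cfg.N, min_leaf_size=cfg.min_leaf_size)
    else:
        part = bsp_ll_partition(m, cfg.N)
    centers = initial_centers(part, m)
    labeling = kmeans_refine(m, centers, iterations=cfg.m)
    target = cfg.K
    if labeling.n_clusters < target:
        warnings.warn(
            f"only {labeling.n_clusters} clusters survived refinement; "
            f"cannot reach K={target}"
        )
        target = labeling.n_clusters
    return merge_to_k(m, labeling, target)
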