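"""Recursive hyper-rectangle partitioning of marker space.

Two partitioners produce the rational initial structure for clustering:

* DSP — discrepancy-guided sequential partition.  Each leaf is scored by a
  Kolmogorov-style discrepancy between the empirical distribution of its
  points (per dimension, rescaled to the leaf bounds) and the uniform
  distribution; the leaf with the largest gap is split at the coordinate
  where the deviation is attained.
* BSP+LL — binary sequential partition with one-step look-ahead.  Cuts are
  restricted to leaf midpoints; a candidate cut is scored by its penalized
  log-likelihood gain under a piecewise-uniform density plus the best single
  follow-up midpoint cut inside either child.

Both cover the data bounding box with pairwise-disjoint half-open
hyper-rectangles so that every event is owned by exactly one leaf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_prep import EventMatrix

__all__ = [
    "RectangleLeaf",
    "PartitionResult",
    "leaf_uniformity_gap",
    "dsp_partition",
    "bsp_ll_partition",
    "initial_centers",
]

# Kolmogorov-Smirnov 5% critical constant; the per-leaf DSP stopping
# threshold defaults to 1.36 / sqrt(n_leaf).
_KS_CRIT = 1.36


@dataclass
class RectangleLeaf:
    """One half-open hyper-rectangle ``[lower, upper)`` with its events."""

    lower: np.ndarray
    upper: np.ndarray
    member_indices: np.ndarray
    depth: int = 0
    # cached best split: (score, dim, cut); None when not yet scored
    _best: tuple | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return len(self.member_indices)

    def log_volume(self, box_width: np.ndarray) -> float:
        """Log volume in box-normalized coordinates (root leaf -> 0)."""
        return float(np.sum(np.log((self.upper - self.lower) / box_width)))


@dataclass
class PartitionResult:
    """Disjoint leaves covering the data bounding box."""

    leaves: list[RectangleLeaf]
    method: str
    n_events: int
    # penalized-score trajectory over acceptance events (BSP only)
    score_trace: list[float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        total = sum(leaf.size for leaf in self.leaves)
        if total != self.n_events:
            raise ValueError(
                f"leaves hold {total} events, expected {self.n_events}"
            )

    def leaf_table(self):
        """Per-leaf bounds and occupancy as a DataFrame (debug aid)."""
        import pandas as pd

        rows = []
        for i, leaf in enumerate(self.leaves):
            row = {"leaf": i, "size": leaf.size, "depth": leaf.depth}
            for d in range(len(leaf.lower)):
                row[f"lo_{d}"] = leaf.lower[d]
                row[f"hi_{d}"] = leaf.upper[d]
            rows.append(row)
        return pd.DataFrame(rows)


def _gap_stats(x: np.ndarray, lo: float, hi: float):
    """Deviation and bracket-gap statistics of sorted 1-D points on [lo, hi).

    Returns ``(score, gap, cut)``: ``score`` is the Kolmogorov-style maximum
    deviation between the empirical CDF of the rescaled points and the
    uniform CDF; ``gap`` is the two-sided bracket gap — the largest sum of an
    ECDF surplus at some point and an ECDF deficit further right, which
    measures how strongly two adjacent near-uniform rectangles of different
    density are separated (large for multimodal leaves, small for unimodal
    ones); ``cut`` is the rank midpoint of the bracket attaining the gap,
    i.e. a coordinate inside the low-density valley.
    """
    n = len(x)
    u = (x - lo) / (hi - lo)
    i = np.arange(1, n + 1)
    d_plus = i / n - u          # ECDF above uniform, attained just right of x
    d_minus = u - (i - 1) / n   # uniform above ECDF, attained at x
    score = float(max(d_plus.max(), d_minus.max()))
    prefix = np.maximum.accumulate(d_plus)
    g = prefix + d_minus
    j_star = int(np.argmax(g))
    i_star = int(np.argmax(d_plus[: j_star + 1]))
    gap = float(g[j_star])
    j = min((i_star + j_star) // 2, n - 2)
    cut = float(0.5 * (x[j] + x[j + 1]))
    # clamp strictly inside (lo, hi) so both sides can be non-empty
    span = hi - lo
    eps = max(1e-12 * max(1.0, abs(lo), abs(hi)), 1e-9 * span)
    cut = min(max(cut, lo + eps), hi - eps)
    return score, gap, cut


def leaf_uniformity_gap(values_1d, lo: float, hi: float) -> tuple[float, float]:
    """Kolmogorov-style discrepancy of 1-D points against uniform on [lo, hi).

    Returns ``(score, best_cut)`` where ``score`` is the maximum deviation
    between the empirical CDF of the rescaled points and the uniform CDF, and
    ``best_cut`` sits in the valley bracketed by the two signed deviation
    peaks (the emptiest stretch of the interval), clamped strictly inside
    ``(lo, hi)``.
    """
    x = np.sort(np.asarray(values_1d, dtype=float))
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if not hi > lo:
        raise ValueError("degenerate interval: lo must be < hi")
    score, _, cut = _gap_stats(x, lo, hi)
    return score, cut


def _bounding_box(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    width = hi - lo
    pad = np.where(width > 0, width * 1e-6, np.maximum(np.abs(hi), 1.0) * 1e-6)
    return lo.astype(float), (hi + pad).astype(float)  # half-open upper edge


def _score_leaf_dsp(values, leaf: RectangleLeaf, min_leaf_size: int):
    """Score one leaf for splitting.

    Stores ``(score, gap, dim, cut)``: ``score`` is the leaf's largest
    per-dimension KS deviation (compared against the stopping threshold);
    the split dimension and cut maximize the bracket gap, the measure of how
    cleanly the cut separates two adjacent rectangles of different density.
    """
    X = values[leaf.member_indices]
    n = X.shape[0]
    best = (0.0, 0.0, -1, np.nan)
    if n < 2 * min_leaf_size:
        leaf._best = best
        return
    max_score = 0.0
    best_gap, best_dim, best_cut = -1.0, -1, np.nan
    for d in range(X.shape[1]):
        xs = np.sort(X[:, d])
        lo, hi = leaf.lower[d], leaf.upper[d]
        score, gap, cut = _gap_stats(xs, lo, hi)
        max_score = max(max_score, score)
        # clamp the cut so each child keeps >= min_leaf_size events
        lo_cut = xs[min_leaf_size - 1]
        hi_cut = xs[n - min_leaf_size]
        if not hi_cut > lo_cut:
            continue  # too many ties; no valid cut along this dimension
        cut = min(max(cut, np.nextafter(lo_cut, np.inf)), hi_cut)
        n_left = int(np.count_nonzero(X[:, d] < cut))
        if n_left < min_leaf_size or n - n_left < min_leaf_size:
            continue
        if gap > best_gap:
            best_gap, best_dim, best_cut = gap, d, float(cut)
    if best_dim >= 0:
        best = (max_score, best_gap, best_dim, best_cut)
    leaf._best = best


def dsp_partition(
    m: EventMatrix,
    leaf_budget: int,
    uniformity_threshold: float | None = None,
    min_leaf_size: int = 10,
) -> PartitionResult:
    """Discrepancy sequential partition into at most ``leaf_budget`` leaves.

    Repeatedly splits the leaf with the largest uniformity gap (over all
    dimensions) at its best cut until every leaf's gap falls below the
    threshold (default ``1.36 / sqrt(n_leaf)``, the 5% KS critical value),
    the leaf budget is reached, or leaves become too small to split.
    """
    if leaf_budget < 1:
        raise ValueError("leaf budget must be >= 1")
    if min_leaf_size < 2:
        raise ValueError("min_leaf_size must be >= 2")
    values = m.values
    n = values.shape[0]
    lo, hi = _bounding_box(values)
    root = RectangleLeaf(lo.copy(), hi.copy(), np.arange(n), depth=0)
    leaves = [root]
    if n < min_leaf_size:
        warnings.warn("fewer events than min_leaf_size; returning one leaf")
        return PartitionResult(leaves=leaves, method="dsp", n_events=n)

    _score_leaf_dsp(values, root, min_leaf_size)
    while len(leaves) < leaf_budget:
        # candidate leaves: splittable and above their own threshold; the
        # queue is ordered by the statistic sqrt(n) * gap so that a mild
        # density gap supported by many events outranks a large one in a
        # small leaf (the same scale the stopping threshold 1.36/sqrt(n)
        # lives on)
        best_i, best_key = -1, None
        for i, leaf in enumerate(leaves):
            score, gap, d, cut = leaf._best
            if d < 0:
                continue
            theta = (
                uniformity_threshold
                if uniformity_threshold is not None
                else _KS_CRIT / np.sqrt(leaf.size)
            )
            if score < theta:
                continue
            key = gap * np.sqrt(leaf.size)
            if best_key is None or key > best_key:
                best_key, best_i = key, i
        if best_i < 0:
            break
        leaf = leaves[best_i]
        _, _, d, cut = leaf._best
        col = values[leaf.member_indices, d]
        left_mask = col < cut
        lo_l, hi_l = leaf.lower.copy(), leaf.upper.copy()
        hi_l[d] = cut
        lo_r, hi_r = leaf.lower.copy(), leaf.upper.copy()
        lo_r[d] = cut
        left = RectangleLeaf(lo_l, hi_l, leaf.member_indices[left_mask],
                             depth=leaf.depth + 1)
        right = RectangleLeaf(lo_r, hi_r, leaf.member_indices[~left_mask],
                              depth=leaf.depth + 1)
        _score_leaf_dsp(values, left, min_leaf_size)
        _score_leaf_dsp(values, right, min_leaf_size)
        leaves[best_i] = left  # keep creation-order determinism
        leaves.append(right)
    return PartitionResult(leaves=leaves, method="dsp", n_events=n)


def _xlogx(v):
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = v[pos] * np.log(v[pos])
    return out


def _bsp_candidates(values, leaf: RectangleLeaf, lam: float):
    """Score all (dim) midpoint cuts of one leaf with one-step look-ahead.

    The immediate penalized gain of cutting ``n_l`` points into ``(na, nb)``
    at the midpoint is ``na log na + nb log nb - n_l log n_l + n_l log 2 -
    lam`` (volume and total-count terms cancel for midpoint cuts).  The
    candidate score adds the best non-negative follow-up midpoint gain inside
    either child.  Stores ``(total, immediate, dim)`` for the leaf's best cut.
    """
    X = values[leaf.member_indices]
    n_l, a = X.shape
    if n_l < 2:
        leaf._best = (-np.inf, -np.inf, -1, "hi", -1, -np.inf)
        return
    lo, hi = leaf.lower, leaf.upper
    mid = 0.5 * (lo + hi)
    q1 = lo + 0.25 * (hi - lo)
    q3 = lo + 0.75 * (hi - lo)
    B = (X >= mid).astype(np.float32)
    nB = B.sum(axis=0).astype(np.int64)          # events in the upper child
    M = (B.T @ B).astype(np.int64)               # joint upper-upper counts
    c1 = (X >= q1).sum(axis=0).astype(np.int64)
    c3 = (X >= q3).sum(axis=0).astype(np.int64)

    n_hi = nB.astype(float)
    n_lo = n_l - n_hi
    gain_imm = (
        _xlogx(n_hi) + _xlogx(n_lo) - _xlogx(n_l) + n_l * np.log(2.0) - lam
    )

    # follow-up gains: cutting child (of cut-dim j) at dimension k's midpoint
    def split_gain(na, ntot):
        na = np.asarray(na, dtype=float)
        ntot = np.asarray(ntot, dtype=float)
        nb = ntot - na
        with np.errstate(invalid="ignore"):
            g = _xlogx(na) + _xlogx(nb) - _xlogx(ntot) + ntot * np.log(2.0) - lam
        return np.where(ntot >= 2, g, -np.inf)

    # upper child of cut j, follow-up dim k != j: counts M[j, k]
    g_hi = split_gain(M, n_hi[:, None] * np.ones((1, a)))
    # lower child of cut j, follow-up dim k != j: nB[k] - M[j, k]
    g_lo = split_gain(nB[None, :] - M, n_lo[:, None] * np.ones((1, a)))
    # same-dimension follow-ups use the quartile counts
    di = np.arange(a)
    g_hi[di, di] = split_gain(c3, n_hi)[di]
    g_lo[di, di] = split_gain(c1 - nB, n_lo)[di]

    follow = np.maximum(g_hi.max(axis=1), g_lo.max(axis=1))
    total = gain_imm + np.maximum(follow, 0.0)
    j = int(np.argmax(total))
    if g_hi[j].max() >= g_lo[j].max():
        f_side, f_dim, f_gain = "hi", int(np.argmax(g_hi[j])), float(g_hi[j].max())
    else:
        f_side, f_dim, f_gain = "lo", int(np.argmax(g_lo[j])), float(g_lo[j].max())
    leaf._best = (float(total[j]), float(gain_imm[j]), j, f_side, f_dim, f_gain)


def _midpoint_split(values, leaves, index, dim, lam):
    """Split ``leaves[index]`` at its midpoint along ``dim`` in place.

    The left child replaces the parent; the right child is appended, so leaf
    order stays deterministic.  Returns the two children's positions.
    """
    leaf = leaves[index]
    cut = 0.5 * (leaf.lower[dim] + leaf.upper[dim])
    col = values[leaf.member_indices, dim]
    left_mask = col < cut
    lo_l, hi_l = leaf.lower.copy(), leaf.upper.copy()
    hi_l[dim] = cut
    lo_r, hi_r = leaf.lower.copy(), leaf.upper.copy()
    lo_r[dim] = cut
    left = RectangleLeaf(lo_l, hi_l, leaf.member_indices[left_mask],
                         depth=leaf.depth + 1)
    right = RectangleLeaf(lo_r, hi_r, leaf.member_indices[~left_mask],
                          depth=leaf.depth + 1)
    _bsp_candidates(values, left, lam)
    _bsp_candidates(values, right, lam)
    leaves[index] = left
    leaves.append(right)
    return index, len(leaves) - 1


def bsp_ll_partition(
    m: EventMatrix,
    leaf_budget: int,
    lookahead: int = 1,
) -> PartitionResult:
    """Binary sequential partition with one-step look-ahead midpoint cuts.

    Greedily accepts the (leaf, dimension) midpoint cut whose penalized
    log-likelihood gain, augmented by the best single follow-up cut inside
    either child, is largest and positive.  When the immediate gain alone is
    not positive (e.g. the balanced first cut of a symmetric bimodal leaf),
    the follow-up cut the look-ahead scored is committed together with it, so
    every acceptance event strictly increases the penalized score (recorded
    in ``score_trace``).  The per-leaf complexity penalty is
    ``0.5 * log(n_events)``.
    """
    if leaf_budget < 1:
        raise ValueError("leaf budget must be >= 1")
    if lookahead != 1:
        raise ValueError("only one-step look-ahead is implemented")
    values = m.values
    n = values.shape[0]
    lo, hi = _bounding_box(values)
    root = RectangleLeaf(lo.copy(), hi.copy(), np.arange(n), depth=0)
    leaves = [root]
    if n < 2:
        warnings.warn("fewer than 2 events; returning one leaf")
        return PartitionResult(leaves=leaves, method="bsp_ll", n_events=n)
    lam = 0.5 * np.log(n)

    _bsp_candidates(values, root, lam)
    result = PartitionResult(leaves=leaves, method="bsp_ll", n_events=n)
    trace = [bsp_partition_score(result, m)]
    while len(leaves) < leaf_budget:
        best_i, best_total = -1, 0.0
        for i, leaf in enumerate(leaves):
            total, imm, d, *_ = leaf._best
            if d < 0 or total <= 0:
                continue
            # a candidate that only pays off through its follow-up needs
            # room for both cuts within the leaf budget
            if imm <= 0 and len(leaves) + 2 > leaf_budget:
                continue
            if total > best_total:
                best_total, best_i = total, i
        if best_i < 0:
            break
        total, imm, d, f_side, f_dim, f_gain = leaves[best_i]._best
        left_i, right_i = _midpoint_split(values, leaves, best_i, d, lam)
        if imm <= 0 and f_gain > 0:
            child_i = right_i if f_side == "hi" else left_i
            _midpoint_split(values, leaves, child_i, f_dim, lam)
        result = PartitionResult(leaves=leaves, method="bsp_ll", n_events=n)
        trace.append(bsp_partition_score(result, m))
    result.score_trace = trace
    return result


def bsp_partition_score(p: PartitionResult, m: EventMatrix) -> float:
    """Penalized piecewise-uniform log-likelihood of a partition.

    ``sum_l n_l log(n_l / (n V_l)) - 0.5 log(n) |leaves|`` with volumes in
    box-normalized coordinates.  Exposed so the greedy cut gains can be
    checked against a direct evaluation.
    """
    values = m.values
    n = p.n_events
    lo, hi = _bounding_box(values)
    width = hi - lo
    score = 0.0
    for leaf in p.leaves:
        if leaf.size == 0:
            continue
        score += leaf.size * (
            np.log(leaf.size) - np.log(n) - leaf.log_volume(width)
        )
    return float(score - 0.5 * np.log(n) * len(p.leaves))


def initial_centers(p: PartitionResult, m: EventMatrix) -> np.ndarray:
    """One center per non-empty leaf: the mean of its member events.

    Centers are emitted in leaf order, which is deterministic (leaf creation
    order with the left child replacing its parent in place).
    """
    centers = [
        m.values[leaf.member_indices].mean(axis=0)
        for leaf in p.leaves
        if leaf.size > 0
    ]
    return np.asarray(centers)
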