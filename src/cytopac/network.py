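"""Marker-network inference and comparison for subpopulations.

Each sufficiently large subpopulation is characterized by an undirected
marker graph: pairwise mutual information is estimated by the plug-in
(histogram) estimator on equal-frequency bins, edges are ranked by the MRNET
maximum-relevance/minimum-redundancy criterion, and the top ``d`` edges
(``d`` = number of markers by default) define the network.  Networks are
compared structurally by the Jaccard distance of their edge sets; edge
weights are reported but never enter the distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkerNetwork",
    "mutual_information_matrix",
    "mrnet_edges",
    "top_d_network",
    "jaccard_distance",
    "hub_markers",
    "network_from_events",
]

# Subpopulations below this many events are considered too small for a stable
# covariance / mutual-information structure (used by the alignment stage).
LARGE_SUBPOP_THRESHOLD = 1000


@dataclass
class MarkerNetwork:
    """Top-d mutual-information edges of one subpopulation."""

    markers: list[str]
    edges: dict[tuple[str, str], float]  # (marker_a, marker_b) sorted pairs
    d: int
    source: tuple = ("", -1, 0)  # (sample_id, subpopulation_id, size)

    def __post_init__(self) -> None:
        if len(self.edges) > self.d:
            raise ValueError("more edges than the budget d")
        marker_set = set(self.markers)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in marker_set or b not in marker_set:
                raise ValueError(f"edge ({a}, {b}) outside the marker set")

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.markers)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


def _equal_frequency_bins(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin indices with (near) equal occupancy; invariant under strictly
    monotone transforms of the column."""
    n = len(column)
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(column, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information_matrix(values: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Plug-in mutual information (nats) between all marker pairs.

    Columns are discretized into ``ceil(n ** (1/3))`` equal-frequency bins by
    default.  The diagonal holds the marginal (binned) entropies.  Constant
    columns carry zero information and trigger a warning.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if p < 2:
        raise ValueError("need at least 2 markers")
    if n < 2:
        raise ValueError("need at least 2 events")
    if n_bins is None:
        n_bins = int(np.ceil(n ** (1 / 3)))
    n_bins = max(n_bins, 1)
    binned = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        if np.ptp(values[:, j]) == 0:
            warnings.warn(f"column {j} is constant; its MI is 0")
            binned[:, j] = 0  # a constant carries no information
        else:
            binned[:, j] = _equal_frequency_bins(values[:, j], n_bins)
    marg = [np.bincount(binned[:, j], minlength=n_bins) for j in range(p)]
    h = np.array([_entropy(c) for c in marg])
    mi = np.zeros((p, p))
    np.fill_diagonal(mi, h)
    for i in range(p):
        for j in range(i + 1, p):
            joint = np.bincount(
                binned[:, i] * n_bins + binned[:, j], minlength=n_bins * n_bins
            )
            mi[i, j] = mi[j, i] = max(h[i] + h[j] - _entropy(joint), 0.0)
    return mi


def mrnet_edges(mi: np.ndarray, marker_names: list[str] | None = None):
    """MRNET edge ranking from a mutual-information matrix.

    For every marker taken as target, a forward maximum-relevance /
    minimum-redundancy selection ranks the remaining markers; the score of
    candidate ``j`` when selected is ``MI(target, j)`` minus the mean MI
    between ``j`` and the already-selected set.  The undirected edge score is
    the larger of the two directed scores.  Returns ``[((a, b), score), ...]``
    sorted by score descending, ties by the lexicographic marker pair.
    """
    mi = np.asarray(mi, dtype=float)
    p = mi.shape[0]
    if mi.shape != (p, p) or not np.allclose(mi, mi.T, atol=1e-10):
        raise ValueError("mi must be a square symmetric matrix")
    if marker_names is None:
        marker_names = [f"V{i + 1}" for i in range(p)]
    if p < 3:
        # degenerate: a single possible edge, ranked by raw MI
        pairs = [
            ((marker_names[i], marker_names[j]), float(mi[i, j]))
            for i in range(p)
            for j in range(i + 1, p)
        ]
        return sorted(pairs, key=lambda e: (-e[1], e[0]))

    score = np.full((p, p), -np.inf)
    for t in range(p):
        remaining = [j for j in range(p) if j != t]
        selected: list[int] = []
        while remaining:
            best_j, best_s = -1, -np.inf
            for j in remaining:
                redundancy = (
                    float(np.mean(mi[j, selected])) if selected else 0.0
                )
                s = mi[t, j] - redundancy
                if s > best_s:
                    best_j, best_s = j, s
            score[t, best_j] = best_s
            selected.append(best_j)
            remaining.remove(best_j)
    sym = np.maximum(score, score.T)
    ranked = [
        ((min(marker_names[i], marker_names[j]), max(marker_names[i], marker_names[j])),
         float(sym[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
    ]
    return sorted(ranked, key=lambda e: (-e[1], e[0]))


def top_d_network(
    ranking,
    d: int | None = None,
    markers: list[str] | None = None,
    source: tuple = ("", -1, 0),
) -> MarkerNetwork:
    """Keep the ``d`` best positive-score edges of a ranking.

    ``d`` defaults to the number of markers (the convention used throughout:
    one edge per marker).  Ties at the cutoff are resolved by the
    lexicographic marker pair, which the ranking already encodes.
    """
    if markers is None:
        markers = sorted({m for (a, b), _ in ranking for m in (a, b)})
    if d is None:
        d = len(markers)
    if d < 1:
        raise ValueError("d must be >= 1")
    kept = [(pair, s) for pair, s in ranking if s > 0][:d]
    return MarkerNetwork(
        markers=list(markers),
        edges={pair: s for pair, s in kept},
        d=d,
        source=source,
    )


def network_from_events(
    values: np.ndarray,
    marker_names: list[str],
    d: int | None = None,
    source: tuple = ("", -1, 0),
    n_bins: int | None = None,
) -> MarkerNetwork:
    """Convenience: MI matrix -> MRNET ranking -> top-d network."""
    mi = mutual_information_matrix(values, n_bins=n_bins)
    ranking = mrnet_edges(mi, marker_names)
    return top_d_network(ranking, d=d, markers=marker_names, source=source)


def jaccard_distance(g1: MarkerNetwork, g2: MarkerNetwork) -> float:
    """1 - |shared edges| / |union of edges|, ignoring weights."""
    e1, e2 = g1.edge_set, g2.edge_set
    union = e1 | e2
    if not union:
        warnings.warn("both edge sets are empty; distance defined as 0")
        return 0.0
    return 1.0 - len(e1 & e2) / len(union)


def hub_markers(g: MarkerNetwork, h: int | None = None) -> list[str]:
    """The ``h`` most-connected markers; degree ties break lexicographically."""
    if not g.markers:
        raise ValueError("empty network")
    degree = {m: 0 for m in g.markers}
    for a, b in g.edges:
        degree[a] += 1
        degree[b] += 1
    ordered = sorted(degree, key=lambda m: (-degree[m], m))
    return ordered if h is None else ordered[:h]
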