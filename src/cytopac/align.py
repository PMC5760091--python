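"""Multiple alignment of subpopulation networks across samples (MAN).

Subpopulations discovered per sample are pooled and aligned into *clades* —
dataset-level cellular states, each containing at most one (merged)
subpopulation per sample:

1. infer a marker network for every subpopulation large enough for stable
   mutual-information estimates (> ``large_threshold`` events);
2. agglomeratively cluster the networks by Jaccard distance and cut the
   dendrogram into ``k`` clades;
3. merge subpopulations of the same sample falling into the same clade
   (consolidating over-partitioning); never merge across samples;
4. rescue the small subpopulations by expression: each joins the clade with
   the nearest member centroid in marker space, unless within-sample
   expression grouping isolates it away from every large subpopulation, in
   which case it founds a sample-specific minor clade;
5. discard clades carrying fewer than ``discard_threshold`` events.

Because networks are invariant to per-sample shifts in marker level, the
alignment is robust to batch effects that displace subpopulation means.
Alternative modes align by networks alone (all subpopulations, no size gate)
or by centroid expression alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, pdist

from .io_prep import EventMatrix
from .network import (
    LARGE_SUBPOP_THRESHOLD,
    MarkerNetwork,
    jaccard_distance,
    network_from_events,
)
from .pac import ClusterLabeling

__all__ = [
    "ManConfig",
    "CladeAssignment",
    "network_dendrogram",
    "cut_to_clades",
    "merge_within_sample",
    "man",
    "clade_proportions",
    "elbow_curve",
    "suggest_knee",
    "clade_annotation_table",
    "ElbowResult",
]


@dataclass
class ManConfig:
    """Settings for one MAN run.

    ``k`` network clades; subpopulations with more than ``large_threshold``
    events take part in network alignment; clades below ``discard_threshold``
    events are dropped; small subpopulations are grouped into
    ``expression_groups_per_sample`` expression clusters per sample when
    deciding between rescue and a sample-specific minor clade.
    """

    k: int
    large_threshold: int = LARGE_SUBPOP_THRESHOLD
    discard_threshold: int = 100
    expression_groups_per_sample: int = 5
    linkage: str = "average"
    mode: str = "sequential"  # sequential | network | means
    edge_budget: int | None = None  # top-d edges; default = n_markers

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.large_threshold <= 0 or self.discard_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.linkage not in ("single", "complete", "average"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")
        if self.mode not in ("sequential", "network", "means"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CladeAssignment:
    """Mapping of (sample, subpopulation) to clade, with bookkeeping.

    ``assignments`` maps each original (sample_id, subpopulation) to a clade
    id, or ``None`` when its clade was discarded.  ``event_clades`` gives the
    per-event clade id per sample (-1 for discarded).  Clades 0..k-1 are
    network clades in dendrogram-cut order; minor sample-specific clades are
    numbered afterwards.
    """

    assignments: dict
    clade_kind: dict
    event_clades: dict
    sample_sizes: dict
    k: int

    def __post_init__(self) -> None:
        # a clade may contain at most one merged subpopulation per sample;
        # several original subpopulations mapping there are by definition
        # merged, so the check is on event-level bookkeeping instead
        for sid, ev in self.event_clades.items():
            if len(ev) != self.sample_sizes[sid]:
                raise ValueError(f"event clades of {sid} have the wrong length")

    @property
    def clades(self) -> list:
        return sorted(self.clade_kind)

    def clade_sample_counts(self) -> pd.DataFrame:
        rows = {}
        for sid, ev in self.event_clades.items():
            counts = pd.Series(ev[ev >= 0]).value_counts()
            rows[sid] = counts
        df = pd.DataFrame(rows).fillna(0).astype(int)
        return df.reindex(sorted(df.index)).sort_index(axis=1)


def network_dendrogram(networks: list[MarkerNetwork], linkage: str = "average"):
    """Agglomerative tree over pairwise Jaccard network distances.

    Returns a scipy linkage matrix; a single network yields a trivial tree
    (empty matrix).
    """
    n = len(networks)
    if n == 0:
        raise ValueError("no networks to align")
    if n == 1:
        return np.empty((0, 4))
    condensed = np.array(
        [
            jaccard_distance(networks[i], networks[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    return scipy_linkage(condensed, method=linkage)


def cut_to_clades(tree: np.ndarray, k: int, n_leaves: int | None = None) -> np.ndarray:
    """Cut a dendrogram into ``k`` clades (0-based, first-appearance order).

    With tied merge heights the cut may yield fewer than ``k`` distinct
    clades (e.g. identical networks all collapse into one), matching the
    agglomerative tree's structure.
    """
    if n_leaves is None:
        n_leaves = len(tree) + 1
    if not 1 <= k <= n_leaves:
        raise ValueError(f"k={k} out of range [1, {n_leaves}]")
    if len(tree) == 0:
        return np.zeros(n_leaves, dtype=int)
    raw = fcluster(tree, t=k, criterion="maxclust")
    _, first = np.unique(raw, return_index=True)
    order = {raw[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([order[r] for r in raw], dtype=int)


def merge_within_sample(assignments: dict, labelings: dict):
    """Merge same-sample subpopulations that share a clade.

    ``assignments`` maps (sample_id, subpop) -> clade; ``labelings`` maps
    sample_id -> per-event subpop labels.  Subpopulations of one sample in
    the same clade are unioned under the smallest involved subpop id; labels
    are rewritten in place on a copy.  Cross-sample members are never merged.
    Returns ``(new_labelings, new_assignments, alias)`` where ``alias`` maps
    every original (sample_id, subpop) to its merged representative.
    """
    new_labelings = {sid: np.array(lab, copy=True) for sid, lab in labelings.items()}
    groups: dict = {}
    for (sid, sub), clade in assignments.items():
        groups.setdefault((sid, clade), []).append(sub)
    alias = {}
    new_assignments = {}
    for (sid, clade), subs in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        rep = min(subs)
        for sub in subs:
            alias[(sid, sub)] = rep
            if sub != rep:
                lab = new_labelings[sid]
                lab[lab == sub] = rep
        new_assignments[(sid, rep)] = clade
    return new_labelings, new_assignments, alias


def _subpop_stats(m: EventMatrix, labels: np.ndarray):
    """Per-subpopulation (indices, size, centroid) keyed by label."""
    stats = {}
    for sub in np.unique(labels):
        idx = np.flatnonzero(labels == sub)
        stats[int(sub)] = (idx, len(idx), m.values[idx].mean(axis=0))
    return stats


def man(samples: list[tuple[EventMatrix, ClusterLabeling]], cfg: ManConfig) -> CladeAssignment:
    """Full multiple-alignment-of-networks over per-sample PAC labelings."""
    sample_ids = [m.sample_id for m, _ in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("sample_id values must be unique across samples")
    marker_names = samples[0][0].marker_names
    data = {m.sample_id: m for m, _ in samples}
    labelings = {m.sample_id: lab.labels for m, lab in samples}
    stats = {sid: _subpop_stats(data[sid], labelings[sid]) for sid in sample_ids}

    # ---- choose the aligned pool and assign network clades -----------------
    if cfg.mode == "means":
        pool = [(sid, sub) for sid in sample_ids for sub in stats[sid]]
        centroids = np.array([stats[sid][sub][2] for sid, sub in pool])
        if len(pool) == 1:
            clade_ids = np.zeros(1, dtype=int)
        else:
            tree = scipy_linkage(pdist(centroids), method=cfg.linkage)
            clade_ids = cut_to_clades(tree, min(cfg.k, len(pool)), len(pool))
        small = []
    else:
        gate = 0 if cfg.mode == "network" else cfg.large_threshold
        pool = [
            (sid, sub)
            for sid in sample_ids
            for sub in stats[sid]
            if stats[sid][sub][1] > gate
        ]
        small = [
            (sid, sub)
            for sid in sample_ids
            for sub in stats[sid]
            if stats[sid][sub][1] <= gate
        ]
        if not pool:
            warnings.warn(
                "no subpopulation exceeds large_threshold; all are sample-specific"
            )
            clade_ids = np.empty(0, dtype=int)
        else:
            networks = [
                network_from_events(
                    data[sid].values[stats[sid][sub][0]],
                    marker_names,
                    d=cfg.edge_budget,
                    source=(sid, sub, stats[sid][sub][1]),
                )
                for sid, sub in pool
            ]
            tree = network_dendrogram(networks, cfg.linkage)
            clade_ids = cut_to_clades(tree, min(cfg.k, len(pool)), len(pool))

    assignments = {key: int(c) for key, c in zip(pool, clade_ids)}
    clade_kind = {int(c): "network" for c in clade_ids}

    # ---- merge same-sample co-clade subpopulations --------------------------
    labelings, assignments, alias = merge_within_sample(assignments, labelings)
    stats = {sid: _subpop_stats(data[sid], labelings[sid]) for sid in sample_ids}

    # ---- rescue small subpopulations by expression --------------------------
    next_clade = (max(clade_kind) + 1) if clade_kind else 0
    member_centroids = [
        (clade, stats[sid][sub][2]) for (sid, sub), clade in assignments.items()
    ]
    for sid in sample_ids:
        sample_small = [sub for s, sub in small if s == sid]
        if not sample_small:
            continue
        subs = sorted(stats[sid])
        cents = np.array([stats[sid][s][2] for s in subs])
        # the grouping must stay coarser than the subpopulation count, else
        # every subpopulation is a singleton and "isolated" loses meaning
        n_groups = min(cfg.expression_groups_per_sample, max(len(subs) - 1, 1))
        if len(subs) == 1:
            groups = np.zeros(1, dtype=int)
        else:
            gtree = scipy_linkage(pdist(cents), method=cfg.linkage)
            groups = cut_to_clades(gtree, n_groups, len(subs))
        group_of = dict(zip(subs, groups))
        large_groups = {
            group_of[sub] for (s, sub) in assignments if s == sid
        }
        minor_clade_of_group: dict = {}
        for sub in sorted(sample_small):
            g = group_of[sub]
            if g not in large_groups and member_centroids:
                # isolated with no large companion: sample-specific minor clade
                if g not in minor_clade_of_group:
                    minor_clade_of_group[g] = next_clade
                    clade_kind[next_clade] = "minor"
                    next_clade += 1
                assignments[(sid, sub)] = minor_clade_of_group[g]
            elif not member_centroids:
                # no large subpopulations anywhere: everything sample-specific
                minor = minor_clade_of_group.get(g)
                if minor is None:
                    minor = minor_clade_of_group[g] = next_clade
                    clade_kind[next_clade] = "minor"
                    next_clade += 1
                assignments[(sid, sub)] = minor
            else:
                d = cdist(
                    stats[sid][sub][2][None, :],
                    np.array([c for _, c in member_centroids]),
                )[0]
                assignments[(sid, sub)] = member_centroids[int(np.argmin(d))][0]

    # merge again: rescued subpopulations join their clade's sample member
    labelings, assignments, alias2 = merge_within_sample(assignments, labelings)
    alias = {key: alias2.get((key[0], rep), rep) for key, rep in alias.items()}
    for key in list(alias2):
        alias.setdefault(key, alias2[key])
    stats = {sid: _subpop_stats(data[sid], labelings[sid]) for sid in sample_ids}

    # ---- discard underpopulated clades --------------------------------------
    clade_events: dict = {}
    for (sid, sub), clade in assignments.items():
        clade_events[clade] = clade_events.get(clade, 0) + stats[sid][sub][1]
    discarded = {
        c for c, n_ev in clade_events.items() if n_ev < cfg.discard_threshold
    }
    for c in discarded:
        clade_kind[c] = "discarded"

    # ---- per-event clade labels ---------------------------------------------
    event_clades = {}
    for sid in sample_ids:
        ev = np.full(len(labelings[sid]), -1, dtype=int)
        for (s, sub), clade in assignments.items():
            if s != sid or clade in discarded:
                continue
            ev[labelings[sid] == sub] = clade
        event_clades[sid] = ev

    final_assignments = {}
    for (sid, orig_sub) in {
        (m.sample_id, int(s)) for m, lab in samples for s in np.unique(lab.labels)
    }:
        rep = alias.get((sid, orig_sub), orig_sub)
        clade = assignments.get((sid, rep))
        final_assignments[(sid, orig_sub)] = (
            None if clade is None or clade in discarded else clade
        )

    # invariant: one merged subpopulation per (clade, sample)
    seen = set()
    for (sid, sub), clade in assignments.items():
        if clade in discarded:
            continue
        if (sid, clade) in seen:
            raise AssertionError("clade holds two unmerged subpopulations of one sample")
        seen.add((sid, clade))

    return CladeAssignment(
        assignments=final_assignments,
        clade_kind=clade_kind,
        event_clades=event_clades,
        sample_sizes={sid: data[sid].n_events for sid in sample_ids},
        k=cfg.k,
    )


def clade_proportions(assignment: CladeAssignment) -> pd.DataFrame:
    """Clade x sample matrix of event fractions.

    Each entry is the fraction of the sample's events carried by the clade;
    events of discarded clades are excluded from the numerator but kept in
    the denominator, so columns sum to at most 1.
    """
    counts = assignment.clade_sample_counts()
    if counts.empty:
        return counts.astype(float)
    totals = pd.Series(assignment.sample_sizes)
    return counts.div(totals, axis=1).fillna(0.0)


def clade_annotation_table(
    samples: list[tuple[EventMatrix, ClusterLabeling]],
    assignment: CladeAssignment,
    n_hubs: int = 4,
) -> pd.DataFrame:
    """Annotate each (sample, clade) by its network hubs and mean expression.

    For every surviving clade member the marker network is re-inferred from
    the member's events and its most-connected markers (joined by ``.``)
    label the cellular state; mean marker levels are appended as columns.
    """
    from .network import hub_markers, network_from_events

    marker_names = samples[0][0].marker_names
    rows = []
    for m, _ in samples:
        sid = m.sample_id
        ev = assignment.event_clades[sid]
        for clade in sorted(set(ev[ev >= 0])):
            values = m.values[ev == clade]
            net = network_from_events(values, marker_names,
                                      source=(sid, int(clade), len(values)))
            hubs = hub_markers(net, n_hubs)
            row = {
                "sample": sid,
                "clade": int(clade),
                "n_events": len(values),
                "proportion": len(values) / m.n_events,
                "annotation": ".".join(hubs),
            }
            row.update(zip(marker_names, values.mean(axis=0)))
            rows.append(row)
    return pd.DataFrame(rows)


def suggest_knee(k_values, errors, span: float = 0.75):
    """Locate the elbow of an error-versus-k curve.

    The curve is smoothed by local regression and the knee is the point of
    maximum positive second difference (the strongest convex kink of a
    decreasing error curve).  Returns ``(smoothed, suggested_k, confident)``;
    a nearly straight curve gives a low-confidence suggestion.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    k_values = np.asarray(k_values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if len(k_values) < 3:
        raise ValueError("need at least 3 curve points")
    smoothed = lowess(errors, k_values, frac=span, return_sorted=False)
    d2 = smoothed[2:] - 2 * smoothed[1:-1] + smoothed[:-2]
    j = int(np.argmax(d2))
    suggested = int(k_values[j + 1])
    scale = np.ptp(smoothed)
    confident = bool(scale > 0 and d2[j] > 0.05 * scale)
    return smoothed, suggested, confident


@dataclass
class ElbowResult:
    """Within-clade error curve over candidate clade counts."""

    k_values: np.ndarray
    errors: np.ndarray
    smoothed: np.ndarray
    suggested_k: int | None
    confident: bool


def elbow_curve(
    samples: list[tuple[EventMatrix, ClusterLabeling]],
    k_range,
    cfg: ManConfig | None = None,
    span: float = 0.75,
) -> ElbowResult:
    """Average within-clade error versus the number of clades.

    For every candidate ``k`` the network dendrogram is cut, same-sample
    co-clade subpopulations are merged, and each sample's root-mean-square
    event distance to its merged-subpopulation centroid is averaged over
    samples.  The curve is locally smoothed and the suggested elbow is the
    point of maximum positive second difference (strongest convex kink);
    when the curve is nearly straight the suggestion is flagged
    low-confidence.  The final choice of ``k`` belongs to the analyst.
    """
    if cfg is None:
        cfg = ManConfig(k=2)
    k_values = np.array(sorted(set(int(k) for k in k_range)))
    sample_ids = [m.sample_id for m, _ in samples]
    data = {m.sample_id: m for m, _ in samples}
    labelings = {m.sample_id: lab.labels for m, lab in samples}
    stats = {sid: _subpop_stats(data[sid], labelings[sid]) for sid in sample_ids}
    gate = 0 if cfg.mode == "network" else cfg.large_threshold
    pool = [
        (sid, sub)
        for sid in sample_ids
        for sub in stats[sid]
        if stats[sid][sub][1] > gate or cfg.mode == "means"
    ]
    if len(pool) < 2:
        raise ValueError("need at least two aligned subpopulations")
    if max(k_values) > len(pool) or min(k_values) < 1:
        raise ValueError("k_range outside the valid cut range")

    if cfg.mode == "means":
        cents = np.array([stats[sid][sub][2] for sid, sub in pool])
        tree = scipy_linkage(pdist(cents), method=cfg.linkage)
    else:
        marker_names = samples[0][0].marker_names
        networks = [
            network_from_events(
                data[sid].values[stats[sid][sub][0]],
                marker_names,
                d=cfg.edge_budget,
                source=(sid, sub, stats[sid][sub][1]),
            )
            for sid, sub in pool
        ]
        tree = network_dendrogram(networks, cfg.linkage)

    # per-subpopulation moments so merged errors are O(1) per k
    moments = {}
    for sid, sub in pool:
        idx, n_ev, _ = stats[sid][sub]
        x = data[sid].values[idx]
        moments[(sid, sub)] = (n_ev, x.sum(axis=0), float((x * x).sum()))

    errors = []
    for k in k_values:
        clade_ids = cut_to_clades(tree, int(k), len(pool))
        merged: dict = {}
        for (sid, sub), c in zip(pool, clade_ids):
            key = (sid, int(c))
            n_ev, sx, sq = moments[(sid, sub)]
            if key in merged:
                n0, sx0, sq0 = merged[key]
                merged[key] = (n0 + n_ev, sx0 + sx, sq0 + sq)
            else:
                merged[key] = (n_ev, sx, sq)
        per_sample = {sid: [0.0, 0] for sid in sample_ids}
        for (sid, _), (n_ev, sx, sq) in merged.items():
            centroid = sx / n_ev
            ss = max(sq - n_ev * float(centroid @ centroid), 0.0)
            per_sample[sid][0] += ss
            per_sample[sid][1] += n_ev
        vals = [
            np.sqrt(ss / n_ev) for ss, n_ev in per_sample.values() if n_ev > 0
        ]
        errors.append(float(np.mean(vals)))
    errors = np.array(errors)

    if len(k_values) >= 3:
        smoothed, suggested, confident = suggest_knee(k_values, errors, span)
    else:
        smoothed = errors.copy()
        suggested, confident = None, False
    return ElbowResult(
        k_values=k_values,
        errors=errors,
        smoothed=smoothed,
        suggested_k=suggested,
        confident=confident,
    )
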