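"""Constellation layout: clade structure drawn over a 2-D embedding.

Subpopulation centroids are projected to the plane (Barnes-Hut t-SNE,
perplexity 30, 1000 iterations by default), each subpopulation keeps its
clade id and a color class (grey for sample-specific clades, colored for
multi-sample clades), members of a clade are connected each to its nearest
same-clade neighbor, and clade members lying far from their clade's 2-D
centroid are pruned into fresh clades.  All distances here are measured in
the embedding, so the pruning is embedding-dependent by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ConstellationLayout",
    "embed_centroids",
    "constellation_edges",
    "prune_clades",
    "constellation",
]


@dataclass
class ConstellationLayout:
    """Coordinates, clade ids, color classes, edges and the pruning log."""

    table: pd.DataFrame  # subpopulation, sample, clade, x, y, color_class
    edges: list[tuple[int, int]]  # index pairs into table rows
    pruning_log: list[str] = field(default_factory=list)


def embed_centroids(
    centroids: np.ndarray,
    perplexity: float = 30.0,
    iterations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """2-D embedding of centroids; deterministic given the seed.

    Fewer than 3 centroids fall back to the leading principal directions;
    a perplexity at or above the number of points is reduced automatically.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = centroids.shape[0]
    if n < 3:
        return _principal_plane(centroids)
    if perplexity >= n:
        import warnings

        new_p = max((n - 1) / 3.0, 1.0)
        warnings.warn(f"perplexity {perplexity} >= n={n}; reduced to {new_p:.1f}")
        perplexity = new_p
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        init="pca",
        method="barnes_hut" if n > 3 else "exact",
        random_state=seed,
    )
    return tsne.fit_transform(centroids)


def _principal_plane(centroids: np.ndarray) -> np.ndarray:
    centered = centroids - centroids.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = np.zeros((centroids.shape[0], 2))
    take = min(2, u.shape[1])
    coords[:, :take] = u[:, :take] * s[:take]
    return coords


def constellation_edges(coords: np.ndarray, clades) -> list[tuple[int, int]]:
    """Connect each clade member to its nearest same-clade neighbor in 2-D."""
    coords = np.asarray(coords, dtype=float)
    clades = np.asarray(clades)
    edges = set()
    for clade in np.unique(clades):
        idx = np.flatnonzero(clades == clade)
        if len(idx) < 2:
            continue
        d = squareform(pdist(coords[idx]))
        np.fill_diagonal(d, np.inf)
        for row, i in enumerate(idx):
            j = idx[int(np.argmin(d[row]))]
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def prune_clades(
    coords: np.ndarray,
    clades,
    multiplier: float = 2.0,
    global_cap: float | None = None,
):
    """Prune clade members lying far from their clade's 2-D centroid.

    Clades with three or more members: a member farther from the clade's 2-D
    centroid than ``multiplier`` times the clade's average member distance is
    pruned.  Two-member clades: the mean separation over all two-member
    clades forms a global reference, and pairs separated by more than
    ``multiplier`` times it are pruned.  An optional ``global_cap`` bounds
    every threshold from above.  Pruned members receive fresh clade ids.
    Returns ``(new_clades, log)``.
    """
    coords = np.asarray(coords, dtype=float)
    clades = np.asarray(clades).copy()
    log: list[str] = []
    next_id = int(np.max(clades)) + 1 if len(clades) else 0

    def threshold(rule_value: float) -> float:
        return rule_value if global_cap is None else min(rule_value, global_cap)

    pair_clades = []
    for clade in np.unique(clades):
        idx = np.flatnonzero(clades == clade)
        if len(idx) == 2:
            pair_clades.append((clade, idx))
    pair_seps = np.array(
        [np.linalg.norm(coords[i] - coords[j]) for _, (i, j) in pair_clades]
    )

    for clade in np.unique(clades):
        idx = np.flatnonzero(clades == clade)
        if len(idx) < 3:
            continue
        center = coords[idx].mean(axis=0)
        dist = np.linalg.norm(coords[idx] - center, axis=1)
        cutoff = threshold(multiplier * dist.mean())
        for i, di in zip(idx, dist):
            if di > cutoff:
                clades[i] = next_id
                log.append(
                    f"pruned member {i} from clade {clade} "
                    f"(distance {di:.3g} > {cutoff:.3g}); new clade {next_id}"
                )
                next_id += 1

    if len(pair_seps):
        ref = pair_seps.mean()
        cutoff = threshold(multiplier * ref)
        for (clade, (i, j)), sep in zip(pair_clades, pair_seps):
            if sep > cutoff:
                for member in (i, j):
                    clades[member] = next_id
                    log.append(
                        f"pruned member {member} from two-member clade {clade} "
                        f"(separation {sep:.3g} > {cutoff:.3g}); new clade {next_id}"
                    )
                    next_id += 1
    return clades, log


def constellation(
    centroids: np.ndarray,
    clades,
    samples,
    subpopulations=None,
    multiplier: float = 2.0,
    global_cap: float | None = None,
    perplexity: float = 30.0,
    iterations: int = 1000,
    seed: int = 0,
) -> ConstellationLayout:
    """Embed, prune, then connect: the full constellation layout.

    A clade whose members all come from one sample is classed grey
    (sample-specific); clades spanning samples are colored.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    clades = np.asarray(clades)
    samples = np.asarray(samples)
    if subpopulations is None:
        subpopulations = np.arange(len(clades))
    coords = embed_centroids(centroids, perplexity, iterations, seed)
    new_clades, log = prune_clades(coords, clades, multiplier, global_cap)
    edges = constellation_edges(coords, new_clades)
    color = [
        "grey" if len(set(samples[new_clades == c])) <= 1 else "colored"
        for c in new_clades
    ]
    table = pd.DataFrame(
        {
            "subpopulation": subpopulations,
            "sample": samples,
            "clade": new_clades,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "color_class": color,
        }
    )
    return ConstellationLayout(table=table, edges=edges, pruning_log=log)
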