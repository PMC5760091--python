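# Methods

`cytopac` clusters single-cell cytometry samples by partition-assisted
clustering (PAC) and links the discovered subpopulations across samples into
*clades* by multiple alignment of their marker networks (MAN). This note
records the models, the numerical choices, and what the synthetic benchmarks
do and do not establish.

## Partition-assisted clustering

Each sample is an `n x p` matrix of arcsinh-transformed marker intensities
(`asinh(x/5)`, the mass-cytometry convention; the transform is applied once
and flagged so it cannot be applied twice). Clustering proceeds in three
stages:

1. **Partitioning.** Marker space is covered by `N` disjoint half-open
   hyper-rectangles grown by recursive binary cuts, so that each rectangle is
   approximately uniform inside. The rectangle means serve as rational
   initial centers; `N` of 2-3x the expected number of subpopulations works
   well.
2. **Refinement.** `m` Lloyd k-means iterations (default 50) round out the
   rectangle corners. Iterations stop early if assignments stabilize;
   clusters emptied along the way are dropped.
3. **Merging.** Clusters are merged greedily down to `K` using the smaller
   of the two squared Mahalanobis distances between cluster means,

       D(X, Y) = min{ (x - y)' Sx^-1 (x - y),  (x - y)' Sy^-1 (x - y) },

   recomputing the pooled mean/covariance after every merge. The distance is
   used squared, exactly as defined. Ties in the argmin pair break to the
   lowest index pair.

### Discrepancy-guided partitioning (DSP)

Every leaf is scored per dimension after rescaling its points to the leaf
bounds:

* **deviation** `D` — the Kolmogorov-style maximum gap between the empirical
  CDF and the uniform CDF. A leaf splits only while `D >= 1.36 / sqrt(n)`
  (the 5% KS critical value), the uniformity stopping rule.
* **bracket gap** `G` — the largest ECDF surplus at one point plus ECDF
  deficit at a later point. The surplus peak and the deficit peak bracket
  the emptiest stretch of the interval, so `G` measures how strongly two
  adjacent near-uniform rectangles of different density are separated. The
  split dimension maximizes `G`, and the cut falls at the rank midpoint of
  the bracket — inside the density valley. The queue of splittable leaves is
  ordered by `sqrt(n) * G`, the same scale the stopping threshold lives on,
  so a mild gap supported by many events outranks a large gap in a tiny
  leaf.

Raw deviation alone is the wrong split criterion on both counts: a single
Gaussian deviates from uniformity *more* than a well-separated bimodal
mixture (so noise dimensions would win), and its argmax sits at the edge of
a cluster's mass rather than between clusters. Cuts are clamped so both
children keep at least `min_leaf_size` (default 10) events; the bounding box
is the per-dimension data range padded by a 1e-6 relative margin, with
half-open intervals so every event is owned by exactly one leaf.

### Bayesian sequential partitioning with one-step look-ahead (BSP+LL)

Cuts are restricted to leaf midpoints. Under a piecewise-uniform density the
penalized log-likelihood gain of splitting `n_l` points into `(n_a, n_b)` at
the midpoint is

    n_a log n_a + n_b log n_b - n_l log n_l + n_l log 2 - lambda,

with a per-leaf penalty `lambda = 0.5 log n` (BIC-flavored). Each candidate
is scored by this immediate gain plus the best single follow-up midpoint cut
inside either child (the one-step look-ahead), vectorized with boolean count
matrices so a full candidate sweep costs one `p x p` matrix product per
leaf. The best positive candidate is accepted; when the immediate gain alone
is not positive — the balanced first cut of a symmetric bimodal leaf gains
exactly zero — the scored follow-up cut is committed together with it, so
every acceptance event strictly raises the penalized score (the trajectory
is recorded in `score_trace` and asserted in tests). On uniform data the
first candidate is already rejected and a single leaf is returned.

### Numerical safeguards in merging

Sample covariances need not be invertible. Before inversion each covariance
receives a ridge `1e-6 * (trace(S)/p) * I`; clusters smaller than `p + 1`
events use their diagonal only. A covariance still singular after
regularization raises an error naming the cluster.

## Evaluation metrics

* **Pair-counting F-measure** — precision and recall over all event-pair
  co-assignment decisions, computed from the class x cluster contingency
  table in linear time. Conventions: a prediction with no same-cluster pairs
  has precision 1; no same-class pairs gives recall 1; F = 0 whenever no
  true-positive pair exists but some same-class pair was split. This is not
  the FlowCAP per-class F-measure.
* **Purity (p-measure)** — for each ground-truth class, the cluster with
  maximal overlap (ties to the lowest cluster id) scores
  `S1 = overlap/|cluster|`, `S2 = overlap/|class|`, `P = 2 S1 S2/(S1+S2)`.

## Marker networks and cross-sample alignment

For each subpopulation with more than 1000 events (smaller ones have
unstable covariance), pairwise mutual information between markers is
estimated by the plug-in histogram estimator on `ceil(n^(1/3))`
equal-frequency bins (nats; invariant under strictly monotone per-marker
transforms, hence invariant to per-sample shifts — the batch-effect
robustness of the whole alignment). Note the estimator's upward bias of
about `(B-1)^2 / (2n)` nats on independent pairs (~0.02 at `n = 10^4`).
Edges are ranked by MRNET: a forward maximum-relevance/minimum-redundancy
selection per target marker, the undirected edge score being the larger of
the two directed scores; the top `d` positive-score edges (default `d` =
number of markers) define the subpopulation's network.

Networks are compared by the structure-only Jaccard distance
`1 - |shared edges| / |union|`; weights are reported but never compared.
The pooled networks are clustered agglomeratively (average linkage by
default; single/complete available) and the dendrogram is cut into `k`
clades. Same-sample subpopulations sharing a clade merge (consolidating
over-partitioning); cross-sample members never merge, so each clade holds
at most one merged subpopulation per sample.

Small subpopulations (≤ 1000 events) are rescued by expression: each joins
the clade whose member centroid is nearest in Euclidean marker space, unless
within-sample expression grouping (hierarchical clustering of the sample's
subpopulation centroids into at most 5 groups, and always fewer groups than
subpopulations, else every group is a meaningless singleton) isolates it
away from every large subpopulation — then it founds a sample-specific minor
clade (at most groups-1 per sample). Clades with fewer than 100 events are
discarded. Alternative alignment modes: `network` (all subpopulations
aligned by network regardless of size — no rescue) and `means`
(centroid-only hierarchical clustering), provided for comparison; the
sequential default is the recommended procedure.

**Elbow analysis.** For each candidate `k` the dendrogram is cut, same-sample
members merge, and the per-sample root-mean-square event distance to the
merged-subpopulation centroid is averaged over samples. The curve is
smoothed by local regression (span 0.75) and the suggested elbow is the
point of maximum positive second difference — the strongest convex kink of a
decreasing error curve. A nearly straight curve flags the suggestion
low-confidence, and the final choice belongs to the analyst.

## Constellation layout

Clade-member centroids are embedded in 2-D (Barnes-Hut t-SNE, perplexity 30,
1000 iterations, seeded; fewer than 3 centroids fall back to the principal
plane). Within each clade every member connects to its nearest same-clade
neighbor in the embedding. Members of clades with ≥ 3 subpopulations lying
farther from the clade's 2-D centroid than `multiplier` (default 2) times
the clade's average distance are pruned into fresh clades; two-member clades
use twice the mean pair separation over all two-member clades as a global
reference, and an optional global cap bounds every threshold. Distances are
measured in the embedding, so pruning is embedding-dependent by design.
Note that with the centroid and the average computed over all members, a
member of an `n`-clade can exceed `2x` the average only for `n >= 5`
(max/mean distance is bounded by `n/2`); pruning therefore acts on clades of
five or more members, which is also the regime where it is meaningful.

## Synthetic benchmarks

* **Mixture benchmarks `a_b_c_d`** — `b` Gaussian components in `a`
  dimensions, means uniform on `[0, c]^a`, covariances `A A'` with `A`
  standard normal (events are generated as `mean + z A'`, so the population
  covariance is exactly `A A'` and is stored for oracle checks), `d` events
  with equal mixing weights by default, multinomially allocated and shuffled.
* **Batch scenario** — two 5-marker samples, two subpopulations each
  (10,000 events per subpopulation), fixed per-subpopulation covariances
  identical across samples; sample 2's means sit 4 units higher on the two
  informative markers, exactly the inter-subpopulation gap, so pooling the
  samples overlaps two different subpopulations.
* **Dynamic scenario** — five 5-marker samples; trajectory A climbs 4.0 per
  sample on the informative markers from 0 while trajectory B drifts 0.1 per
  sample from 19.4; the gap shrinks strictly (19.4 to 3.8 standard
  deviations per marker) without closing, and by the last sample each
  trajectory is closer to the other than to its own previous position —
  which is what defeats centroid-only alignment. 2,500 events per
  subpopulation: over-partitioning with 3 clusters per sample then routinely
  leaves a fragment below the 1000-event network gate while its sibling
  stays above it, the regime in which sequential network-then-expression
  alignment succeeds but network-only alignment is corrupted by unstable
  fragment networks.

The two scenario covariances are fixed presets: unit-variance Gaussian
5-cycles (a correlation chain closed by one strong end-to-end correlation),
sharing the V1-V2 and V4-V5 edges and differing elsewhere (ideal network
Jaccard distance 0.75). Exactly five strong, non-redundant dependencies per
preset fill the one-edge-per-marker budget, so whole-subpopulation networks
are estimated reproducibly; the mean shifts ride on V3/V4, whose edges have
enough rank margin that fragment truncation leaves fragment networks close
to their parents. The generators are pure functions of their seed.

**What these benchmarks do not show.** They are clean Gaussian mixtures:
no zero-inflation, spillover, acquisition drift within a sample, or
non-elliptical populations. Passing them establishes the algorithmic
contracts (initialization quality, merge behavior, shift-invariant
alignment), not performance on arbitrary real cytometry data.

## Problem sizes used in the test suite

Unit and property tests run on hundreds to thousands of events. The
regenerated benchmark checks run the full published sizes (100,000 events,
10-50 dimensions, medians over 5 seeds); scenario checks use 20 seeds each.
The full suite completes in a few minutes on one CPU; the acceptance script
(5 benchmarks x 5 seeds at full size) takes about 90 seconds.

## Known limitations

* DSP's discrepancy statistic is one-dimensional per axis; structure visible
  only in oblique projections is found indirectly through recursion.
* BSP's look-ahead is fixed at one step; no posterior resampling.
* Mutual information is pairwise only — higher-order marker interactions do
  not influence network structure.
* `merge_to_k` recomputes one row of the distance matrix per merge
  (`O(K^2)` per step), fine for the intended K of tens, not thousands.
* Alignment quality depends on the linkage choice (average by default) and
  on the edge budget `d`; both are exposed in `ManConfig`.
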