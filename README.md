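# cytopac

Partition-assisted clustering and cross-sample network alignment for
high-dimensional single-cell cytometry.

Mass cytometry measures ~40 protein markers on hundreds of thousands of
cells per sample. Two practical problems dominate multi-sample studies:
finding the cell subpopulations in each sample automatically (instead of
hand-gating 2-D scatterplots), and deciding which subpopulation in sample 1
corresponds to which in sample 2 when batch effects have shifted every
marker's scale. `cytopac` addresses both:

* **PAC (partition-assisted clustering).** The marker space is recursively
  partitioned into hyper-rectangles — by discrepancy-guided cuts (d-PAC) or
  Bayesian midpoint cuts with one-step look-ahead (b-PAC) — whose occupancy
  approximates the data density. The rectangle means initialize a short
  k-means refinement (m = 50 iterations suffices), and clusters are merged
  down to K using the flowMeans-style distance
  `D(X,Y) = min{(x̄−ȳ)ᵀS_x⁻¹(x̄−ȳ), (x̄−ȳ)ᵀS_y⁻¹(x̄−ȳ)}`.
* **MAN (multiple alignment of networks).** Each large subpopulation is
  summarized by its top-d mutual-information marker network (MRNET ranking,
  d = number of markers). Networks are invariant to per-sample shifts, so
  hierarchically clustering them by Jaccard distance and cutting into k
  clades links the same cellular state across samples even when marker
  means moved. Small subpopulations are rescued by expression proximity;
  within-sample co-clade subpopulations merge, undoing over-partitioning.
* Evaluation (pair-counting F-measure, per-class purity), elbow analysis for
  choosing k, and a constellation layout (t-SNE of centroids with
  within-clade edges and outlier pruning) round out the pipeline.

## Worked example

Cluster two batch-shifted samples separately, then align their
subpopulations into clades:

```python
import cytopac as cp

# two 5-marker samples, same two subpopulations, sample 2 shifted upward
sample_1, sample_2 = cp.batch_scenario(seed=0)

labeled = []
for s in (sample_1, sample_2):
    labeling = cp.pac(s.events, cp.PacConfig(N=6, K=3, m=50, method="dsp"))
    print(s.events.sample_id, [c.size for c in labeling.summaries])
    labeled.append((s.events, labeling))

assignment = cp.man(labeled, cp.ManConfig(k=2))
print(cp.clade_proportions(assignment).round(3))
```

Output (seed 0):

```
sample_1 [7581, 2427, 9992]
sample_2 [7789, 2220, 9991]
   sample_1  sample_2
0       0.5       0.5
1       0.5       0.5
```

Each sample was over-partitioned into three PAC subpopulations (one true
subpopulation split 7581 + 2427). Aligning the subpopulation *networks* and
cutting at two clades pairs the states correctly across samples, and the
within-sample merge re-joins the split: clade 0 is one cellular state (50%
of each sample's events), clade 1 the other — even though their marker means
differ by a full inter-subpopulation gap between the samples, which defeats
centroid-based matching. Accuracy of the per-sample clustering against the
generating labels:

```python
f = cp.f_measure(sample_1.labels, labeled[0][1].labels)
print(round(f, 3))   # 0.896 for the over-partitioned 3-cluster labeling
```

From the shell, the same steps are available as `cytopac simulate`,
`cytopac pac`, `cytopac man`, and `cytopac metrics`.

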