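import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cytopac.partition import (
    bsp_ll_partition,
    bsp_partition_score,
    dsp_partition,
    initial_centers,
    leaf_uniformity_gap,
)
from cytopac.synthetic import SimSpec, gmm_sample
from conftest import make_matrix


class TestLeafUniformityGap:
    def test_uniform_quantiles_score_near_zero(self):
        k = 200
        pts = (np.arange(1, k + 1)) / (k + 1)
        score, _ = leaf_uniformity_gap(pts, 0.0, 1.0)
        assert score < 0.01

    def test_point_mass_at_lower_bound_scores_near_one(self):
        score, cut = leaf_uniformity_gap(np.zeros(100), 0.0, 1.0)
        assert score > 0.98
        assert 0.0 < cut < 1.0

    def test_score_matches_brute_force_scan(self, rng):
        # KS-style discrepancy equals the exhaustive max |F(x) - x| over the
        # sample points (checked at both ECDF one-sided limits)
        x = rng.beta(2.0, 2.0, size=200)
        score, _ = leaf_uniformity_gap(x, 0.0, 1.0)
        xs = np.sort(x)
        n = len(xs)
        brute = 0.0
        for i, xi in enumerate(xs):
            ecdf_before, ecdf_at = i / n, (i + 1) / n
            brute = max(brute, abs(ecdf_before - xi), abs(ecdf_at - xi))
        assert score == pytest.approx(brute, abs=1e-12)

    def test_two_gaussians_cut_in_valley(self, rng):
        x = np.concatenate([rng.normal(0, 1, 3000), rng.normal(10, 1, 3000)])
        lo, hi = x.min() - 1e-9, x.max() + 1e-9
        _, cut = leaf_uniformity_gap(x, lo, hi)
        assert 2.0 < cut < 8.0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            leaf_uniformity_gap([0.1, 0.2], 1.0, 1.0)


class TestDspPartition:
    def test_uniform_data_single_leaf_under_lenient_threshold(self, rng):
        m = make_matrix(rng.uniform(size=(1000, 2)))
        p = dsp_partition(m, leaf_budget=10, uniformity_threshold=0.9)
        assert len(p.leaves) == 1

    def test_two_gaussians_split_between_modes(self, rng):
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        m = make_matrix(np.column_stack([x, rng.normal(size=4000)]))
        p = dsp_partition(m, leaf_budget=2)
        assert len(p.leaves) == 2
        cut = p.leaves[0].upper[0]
        assert 2.0 < cut < 8.0
        assert min(leaf.size for leaf in p.leaves) >= 0.49 * 4000

    def test_five_modes_each_captured_by_distinct_leaf(self, rng):
        centers = np.array(
            [[0, 0], [20, 0], [0, 20], [20, 20], [10, 10]], dtype=float
        )
        vals = np.vstack([rng.normal(c, 1.0, size=(800, 2)) for c in centers])
        m = make_matrix(vals)
        p = dsp_partition(m, leaf_budget=10)
        cents = initial_centers(p, m)
        nearest = cdist(centers, cents).argmin(axis=1)
        assert len(set(nearest)) == 5

    def test_coverage_and_disjointness(self, rng):
        m = make_matrix(rng.normal(size=(500, 3)))
        p = dsp_partition(m, leaf_budget=8)
        seen = np.zeros(500, dtype=int)
        for leaf in p.leaves:
            seen[leaf.member_indices] += 1
            members = m.values[leaf.member_indices]
            assert np.all(members >= leaf.lower) and np.all(members < leaf.upper)
        np.testing.assert_array_equal(seen, 1)

    def test_tiny_input_returns_single_leaf_with_warning(self, rng):
        m = make_matrix(rng.normal(size=(5, 2)))
        with pytest.warns(UserWarning):
            p = dsp_partition(m, leaf_budget=4, min_leaf_size=10)
        assert len(p.leaves) == 1

    def test_invalid_budget(self, rng):
        m = make_matrix(rng.normal(size=(50, 2)))
        with pytest.raises(ValueError):
            dsp_partition(m, leaf_budget=0)


def _direct_partition_score(p, m):
    """Independent evaluator: sum n_l log(n_l/(n V_l)) - 0.5 log(n) |leaves|,
    volumes normalized to the (padded) data bounding box."""
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    width = hi - lo
    pad = np.where(width > 0, width * 1e-6, np.maximum(np.abs(hi), 1.0) * 1e-6)
    box = (hi + pad) - lo
    n = m.values.shape[0]
    total = 0.0
    for leaf in p.leaves:
        if leaf.size == 0:
            continue
        log_vol = np.sum(np.log((leaf.upper - leaf.lower) / box))
        total += leaf.size * (np.log(leaf.size / n) - log_vol)
    return total - 0.5 * np.log(n) * len(p.leaves)


class TestBspPartition:
    def test_uniform_data_stops_at_one_leaf(self, rng):
        m = make_matrix(rng.uniform(size=(2000, 2)))
        p = bsp_ll_partition(m, leaf_budget=8)
        assert len(p.leaves) == 1

    def test_score_matches_direct_evaluator(self, rng):
        vals = np.vstack(
            [rng.normal(0, 1, size=(800, 3)), rng.normal(6, 1, size=(800, 3))]
        )
        m = make_matrix(vals)
        p = bsp_ll_partition(m, leaf_budget=6)
        assert len(p.leaves) > 1
        assert bsp_partition_score(p, m) == pytest.approx(
            _direct_partition_score(p, m), rel=1e-10
        )

    def test_each_acceptance_strictly_increases_score(self, rng):
        vals = np.vstack(
            [rng.normal(0, 1, size=(700, 2)), rng.normal(8, 1, size=(700, 2))]
        )
        m = make_matrix(vals)
        p = bsp_ll_partition(m, leaf_budget=8)
        trace = p.score_trace
        assert len(trace) >= 2  # at least one acceptance happened
        assert all(b > a for a, b in zip(trace, trace[1:]))
        assert trace[-1] == pytest.approx(bsp_partition_score(p, m), rel=1e-10)

    def test_lookahead_isolates_offset_cluster(self, rng):
        # three clusters: two stacked on the left, one offset to the upper
        # right.  The very first accepted midpoint cut must already separate
        # the offset cluster from the other two, and within the recommended
        # budget (2-3x the cluster count) every mode owns a distinct center.
        vals = np.vstack(
            [
                rng.normal([0, 0], 0.7, size=(1000, 2)),
                rng.normal([0, 6], 0.7, size=(1000, 2)),
                rng.normal([9, 9], 0.7, size=(1000, 2)),
            ]
        )
        m = make_matrix(vals)
        first = bsp_ll_partition(m, leaf_budget=2)
        offset_leaf = [
            any(
                np.all(np.array([9, 9]) >= leaf.lower)
                and np.all(np.array([9, 9]) < leaf.upper)
                for leaf in first.leaves
            )
        ]
        sides = [
            np.all(np.array([0, 3]) >= leaf.lower)
            and np.all(np.array([9, 9]) < leaf.upper)
            for leaf in first.leaves
        ]
        assert not any(sides)  # no leaf spans both the left pair and (9,9)

        p = bsp_ll_partition(m, leaf_budget=7)
        cents = initial_centers(p, m)
        true_centers = np.array([[0, 0], [0, 6], [9, 9]], dtype=float)
        nearest = cdist(true_centers, cents).argmin(axis=1)
        assert len(set(nearest)) == 3


class TestInitialCenters:
    def test_single_leaf_gives_global_mean(self, rng):
        m = make_matrix(rng.normal(size=(300, 2)))
        p = dsp_partition(m, leaf_budget=1)
        cents = initial_centers(p, m)
        assert cents.shape == (1, 2)
        np.testing.assert_allclose(cents[0], m.values.mean(axis=0))

    def test_one_center_per_nonempty_leaf(self, rng):
        m = make_matrix(rng.normal(size=(400, 2)))
        p = dsp_partition(m, leaf_budget=5)
        cents = initial_centers(p, m)
        assert cents.shape[0] == sum(1 for leaf in p.leaves if leaf.size > 0)


class TestModeCapture:
    def test_gmm_components_map_to_distinct_centers(self):
        # well-separated mixtures: with N = 2x components the map
        # component -> nearest leaf-center stays injective across seeds
        hits = 0
        seeds = range(10)
        for seed in seeds:
            g = gmm_sample(SimSpec(a=5, b=4, c=40, d=4000, seed=seed))
            for method in (dsp_partition, bsp_ll_partition):
                p = method(g.events, 8)
                cents = initial_centers(p, g.events)
                nearest = cdist(g.means, cents).argmin(axis=1)
                hits += len(set(nearest)) == 4
        assert hits >= 0.95 * 2 * len(seeds)
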