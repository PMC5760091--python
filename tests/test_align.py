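import itertools

import numpy as np
import pytest

from cytopac.align import (
    CladeAssignment,
    ManConfig,
    clade_annotation_table,
    clade_proportions,
    cut_to_clades,
    elbow_curve,
    man,
    merge_within_sample,
    network_dendrogram,
    suggest_knee,
)
from cytopac.network import MarkerNetwork
from cytopac.pac import ClusterLabeling, PacConfig, pac, summarize_clusters
from cytopac.synthetic import batch_scenario, dynamic_scenario
from conftest import make_matrix


def net(edges, markers=("a", "b", "c", "d", "e")):
    return MarkerNetwork(
        markers=list(markers), edges={e: 1.0 for e in edges}, d=max(len(edges), 1)
    )


class TestDendrogramAndCut:
    def test_identical_networks_collapse_to_one_clade(self):
        nets = [net({("a", "b"), ("c", "d")})] * 4
        tree = network_dendrogram(nets)
        assert len(set(cut_to_clades(tree, 2, 4))) == 1

    def test_two_identical_pairs_cut_into_the_pairs(self):
        n1 = net({("a", "b"), ("b", "c")})
        n2 = net({("c", "d"), ("d", "e")})
        nets = [n1, n2, n1, n2]
        tree = network_dendrogram(nets)
        clades = cut_to_clades(tree, 2, 4)
        # exhaustive check: the only 2-partition with zero within-clade
        # distance is {0, 2} vs {1, 3}
        assert clades[0] == clades[2]
        assert clades[1] == clades[3]
        assert clades[0] != clades[1]

    def test_k_one_and_k_n(self):
        nets = [net({("a", "b")}), net({("b", "c")}), net({("c", "d")})]
        tree = network_dendrogram(nets)
        assert len(set(cut_to_clades(tree, 1, 3))) == 1
        assert len(set(cut_to_clades(tree, 3, 3))) == 3

    def test_k_out_of_range(self):
        nets = [net({("a", "b")}), net({("b", "c")})]
        tree = network_dendrogram(nets)
        with pytest.raises(ValueError):
            cut_to_clades(tree, 3, 2)
        with pytest.raises(ValueError):
            cut_to_clades(tree, 0, 2)

    def test_single_network_trivial_tree(self):
        tree = network_dendrogram([net({("a", "b")})])
        np.testing.assert_array_equal(cut_to_clades(tree, 1, 1), [0])


class TestMergeWithinSample:
    def test_no_co_membership_is_identity(self):
        labels = {"s1": np.array([0, 0, 1, 1])}
        assignments = {("s1", 0): 0, ("s1", 1): 1}
        new_labels, new_assign, alias = merge_within_sample(assignments, labels)
        np.testing.assert_array_equal(new_labels["s1"], labels["s1"])
        assert new_assign == assignments

    def test_same_sample_co_clade_subpops_merge(self):
        labels = {"s1": np.array([0, 1, 2, 2, 1, 0])}
        assignments = {("s1", 0): 7, ("s1", 1): 7, ("s1", 2): 3}
        new_labels, new_assign, alias = merge_within_sample(assignments, labels)
        np.testing.assert_array_equal(new_labels["s1"], [0, 0, 2, 2, 0, 0])
        assert new_assign == {("s1", 0): 7, ("s1", 2): 3}
        assert alias[("s1", 1)] == 0

    def test_cross_sample_members_never_merge(self):
        labels = {"s1": np.array([0, 0]), "s2": np.array([0, 0])}
        assignments = {("s1", 0): 4, ("s2", 0): 4}
        new_labels, new_assign, _ = merge_within_sample(assignments, labels)
        assert set(new_assign) == {("s1", 0), ("s2", 0)}

    def test_event_counts_conserved(self, rng):
        labels = {"s1": rng.integers(0, 5, size=200)}
        assignments = {("s1", j): j % 2 for j in range(5)}
        new_labels, _, _ = merge_within_sample(assignments, labels)
        assert len(new_labels["s1"]) == 200


def _labeled_sample(rng, sample_id, centers, sizes):
    """Ground-truth-labeled 5-marker sample; subpopulations draw their
    dependence structure from the fixed scenario presets so their marker
    networks are well defined (alternating between the two presets)."""
    from cytopac.synthetic import SCENARIO_COVARIANCES

    presets = [SCENARIO_COVARIANCES["A"], SCENARIO_COVARIANCES["B"]]
    parts, labels = [], []
    for k, (c, n) in enumerate(zip(centers, sizes)):
        chol = np.linalg.cholesky(presets[k % 2])
        parts.append(np.asarray(c) + rng.standard_normal((n, 5)) @ chol.T)
        labels.append(np.full(n, k))
    values = np.vstack(parts)
    labels = np.concatenate(labels)
    m = make_matrix(values, sample_id=sample_id)
    return m, ClusterLabeling(labels, summarize_clusters(values, labels), sample_id)


class TestManPipeline:
    def test_single_sample_identity_assignment(self, two_blobs):
        m, truth = two_blobs
        lab = pac(m, PacConfig(N=4, K=2, m=20))
        out = man([(m, lab)], ManConfig(k=2, large_threshold=100))
        clades = {out.assignments[("blobs", j)] for j in range(lab.n_clusters)}
        assert len(clades) == lab.n_clusters

    def test_no_clade_holds_two_subpops_of_one_sample(self):
        samples = batch_scenario(n_per_subpop=2000, seed=3)
        labeled = [
            (s.events, pac(s.events, PacConfig(N=6, K=3, m=30))) for s in samples
        ]
        out = man(labeled, ManConfig(k=3))
        # event-level check: within a sample, each PAC subpopulation maps to
        # exactly one clade, i.e. co-clade subpopulations were merged wholesale
        by_sample = {m.sample_id: lab.labels for m, lab in labeled}
        for sid, ev in out.event_clades.items():
            labels = by_sample[sid]
            for sub in set(labels):
                clades_of_sub = set(ev[labels == sub])
                assert len(clades_of_sub) == 1

    def test_event_conservation_minus_discards(self):
        samples = batch_scenario(n_per_subpop=1500, seed=5)
        labeled = [
            (s.events, pac(s.events, PacConfig(N=6, K=3, m=30))) for s in samples
        ]
        out = man(labeled, ManConfig(k=3))
        for s in samples:
            ev = out.event_clades[s.events.sample_id]
            assert len(ev) == s.events.n_events  # discarded stay as -1 rows

    def test_alignment_invariant_to_per_sample_shift(self):
        # batch robustness restated: shifting every marker of one sample by a
        # constant must not change the clade structure
        samples = batch_scenario(n_per_subpop=3000, seed=11)
        labeled = [
            (s.events, pac(s.events, PacConfig(N=6, K=3, m=30))) for s in samples
        ]
        base = man(labeled, ManConfig(k=3))

        from dataclasses import replace

        shifted_m = replace(
            labeled[0][0], values=labeled[0][0].values + 7.5
        )
        shifted_lab = pac(shifted_m, PacConfig(N=6, K=3, m=30))
        shifted = man([(shifted_m, shifted_lab), labeled[1]], ManConfig(k=3))
        # same clade partition over (sample, subpop) units
        def partition(assign):
            groups = {}
            for key, clade in assign.assignments.items():
                groups.setdefault(clade, set()).add(key)
            return {frozenset(g) for g in groups.values()}

        assert partition(base) == partition(shifted)

    def test_small_subpop_with_matching_centroid_joins_that_clade(self, rng):
        # sample 1: two large subpops; sample 2: one large + one small whose
        # centroid coincides with sample 1's second subpop
        m1, lab1 = _labeled_sample(
            rng, "s1", [np.zeros(5), np.full(5, 10.0)], [2000, 2000]
        )
        m2, lab2 = _labeled_sample(
            rng, "s2", [np.zeros(5), np.full(5, 10.0)], [2000, 300]
        )
        out = man(
            [(m1, lab1), (m2, lab2)],
            ManConfig(k=2, large_threshold=1000, expression_groups_per_sample=2),
        )
        assert out.assignments[("s2", 1)] == out.assignments[("s1", 1)]

    def test_isolated_small_subpop_becomes_sample_specific_minor_clade(self, rng):
        m1, lab1 = _labeled_sample(
            rng, "s1", [np.zeros(5), np.full(5, 10.0)], [2000, 2000]
        )
        m2, lab2 = _labeled_sample(
            rng,
            "s2",
            [np.zeros(5), np.full(5, 10.0), np.full(5, -40.0)],
            [2000, 2000, 300],
        )
        out = man(
            [(m1, lab1), (m2, lab2)],
            ManConfig(k=2, large_threshold=1000, expression_groups_per_sample=3),
        )
        minor = out.assignments[("s2", 2)]
        assert out.clade_kind[minor] == "minor"
        assert minor not in {
            out.assignments[("s1", 0)], out.assignments[("s1", 1)]
        }

    def test_underpopulated_clade_discarded(self, rng):
        m1, lab1 = _labeled_sample(
            rng, "s1", [np.zeros(5), np.full(5, 10.0)], [2000, 2000]
        )
        m2, lab2 = _labeled_sample(
            rng,
            "s2",
            [np.zeros(5), np.full(5, 10.0), np.full(5, -40.0)],
            [2000, 2000, 90],
        )
        out = man(
            [(m1, lab1), (m2, lab2)],
            ManConfig(k=2, large_threshold=1000, expression_groups_per_sample=3),
        )
        assert out.assignments[("s2", 2)] is None  # 90 events < 100
        ev = out.event_clades["s2"]
        assert (ev == -1).sum() == 90


class TestCladeProportions:
    def test_sample_specific_clade_single_nonzero_column(self, rng):
        m1, lab1 = _labeled_sample(
            rng, "s1", [np.zeros(5), np.full(5, 10.0)], [2000, 2000]
        )
        m2, lab2 = _labeled_sample(
            rng,
            "s2",
            [np.zeros(5), np.full(5, 10.0), np.full(5, -40.0)],
            [2000, 2000, 400],
        )
        out = man(
            [(m1, lab1), (m2, lab2)],
            ManConfig(k=2, large_threshold=1000, expression_groups_per_sample=3),
        )
        props = clade_proportions(out)
        minor = out.assignments[("s2", 2)]
        assert props.loc[minor, "s1"] == 0.0
        assert props.loc[minor, "s2"] == pytest.approx(400 / 4400)
        assert (props.sum(axis=0) <= 1.0 + 1e-9).all()

    def test_equal_split_gives_half_half(self, rng):
        m1, lab1 = _labeled_sample(rng, "s1", [np.zeros(5), np.full(5, 9.0)], [1500, 1500])
        m2, lab2 = _labeled_sample(rng, "s2", [np.zeros(5), np.full(5, 9.0)], [1500, 1500])
        out = man([(m1, lab1), (m2, lab2)], ManConfig(k=2))
        props = clade_proportions(out)
        c0 = out.assignments[("s1", 0)]
        assert props.loc[c0, "s1"] == pytest.approx(0.5)
        assert props.loc[c0, "s2"] == pytest.approx(0.5)


class TestAnnotation:
    def test_hub_annotation_table_columns_and_hubs(self, rng):
        m1, lab1 = _labeled_sample(rng, "s1", [np.zeros(5), np.full(5, 10.0)], [2000, 2000])
        m2, lab2 = _labeled_sample(rng, "s2", [np.zeros(5), np.full(5, 10.0)], [2000, 2000])
        samples = [(m1, lab1), (m2, lab2)]
        out = man(samples, ManConfig(k=2))
        table = clade_annotation_table(samples, out, n_hubs=2)
        assert set(table.columns) >= {"sample", "clade", "annotation", "proportion"}
        assert len(table) == 4  # 2 samples x 2 clades
        # matched subpopulations across samples share the hub annotation
        for clade, group in table.groupby("clade"):
            assert group["annotation"].nunique() == 1
        np.testing.assert_allclose(table["proportion"], 0.5)


class TestElbow:
    def test_piecewise_linear_kink_detected(self):
        ks = np.arange(2, 12)
        errors = np.where(ks <= 5, 50.0 - 8.0 * ks, 10.0 - 0.2 * (ks - 5))
        _, suggested, confident = suggest_knee(ks, errors, span=0.3)
        assert suggested == 5
        assert confident

    def test_straight_line_flagged_low_confidence(self):
        ks = np.arange(2, 12)
        errors = 30.0 - 1.5 * ks
        _, _, confident = suggest_knee(ks, errors, span=0.6)
        assert not confident

    def test_curve_over_scenario_samples_decreases(self):
        samples = dynamic_scenario(n_per_subpop=1200, seed=2)
        labeled = [
            (s.events, pac(s.events, PacConfig(N=4, K=2, m=30))) for s in samples
        ]
        res = elbow_curve(
            labeled, k_range=range(1, 6), cfg=ManConfig(k=2, large_threshold=500)
        )
        assert res.errors[0] >= res.errors[-1]
        assert len(res.errors) == 5

    def test_short_k_range_gives_no_suggestion(self):
        samples = dynamic_scenario(n_per_subpop=1200, seed=2)
        labeled = [
            (s.events, pac(s.events, PacConfig(N=4, K=2, m=30))) for s in samples
        ]
        res = elbow_curve(
            labeled, k_range=[2, 3], cfg=ManConfig(k=2, large_threshold=500)
        )
        assert res.suggested_k is None
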