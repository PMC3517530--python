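"""Hierarchical clustering, dendrogram cuts, labeling and classification."""

import itertools

import numpy as np
import pytest

from surfwave.cluster import (Dendrogram, classify, cut_k_groups,
                              cut_two_groups, hierarchical_cluster,
                              majority_label, pairwise_distance)


# ---------------------------------------------------------------------------
# Independent greedy oracle computing linkage criteria from first principles
# ---------------------------------------------------------------------------

def ess(points):
    pts = np.asarray(points)
    return float(((pts - pts.mean(axis=0)) ** 2).sum())


def greedy_oracle(x, linkage):
    """Brute-force greedy agglomeration: at each step evaluate the criterion
    for every candidate pair directly from the member points."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pa, pb = clusters[a], clusters[b]
            if linkage == "ward":
                crit = ess(x[pa + pb]) - ess(x[pa]) - ess(x[pb])
            else:
                crit = float(np.mean([np.linalg.norm(x[i] - x[j])
                                      for i in pa for j in pb]))
            if best is None or (crit, (a, b)) < best:
                best = (crit, (a, b))
        crit, (a, b) = best
        merges.append((a, b, crit))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestPairwiseDistance:
    def test_identical_vectors_have_zero_distance(self):
        d = pairwise_distance(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d[0, 1] == 0.0

    def test_three_four_five(self):
        d = pairwise_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert abs(d[0, 1] - 5.0) < 1e-12

    def test_standardized_euclidean_formula(self):
        # feature sds (1, 2) -> d((0,0),(2,2)) = sqrt(4 + 1) = sqrt(5)
        x = np.array([[0.0, 0.0], [2.0, 2.0], [1.0, 1.0], [-1.0, -3.0]])
        sd = x.std(axis=0, ddof=1)
        d = pairwise_distance(x, metric="standardized_euclidean")
        expected = np.sqrt(((x[0] - x[1]) ** 2 / sd ** 2).sum())
        assert abs(d[0, 1] - expected) < 1e-12

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestLinkageOracles:
    def test_ward_singleton_pair_is_half_squared_distance(self):
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        d = hierarchical_cluster(x, linkage="ward")
        assert abs(d.merges[0][2] - 0.5 * 4.0) < 1e-12

    def test_average_linkage_singleton_vs_pair(self):
        x = np.array([[0.0], [10.0], [11.0]])
        d = hierarchical_cluster(x, linkage="average")
        # first merge: (10, 11); then average of d(0,10), d(0,11) = 10.5
        assert abs(d.merges[1][2] - 10.5) < 1e-12

    def test_one_dimensional_pairs_merge_first_under_ward(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        d = hierarchical_cluster(x, linkage="ward")
        first_two = {tuple(sorted(m[:2])) for m in d.merges[:2]}
        assert first_two == {(0, 1), (2, 3)}

    @pytest.mark.parametrize("linkage", ["ward", "average"])
    def test_merge_sequences_match_brute_force_oracle(self, linkage):
        """Greedy merge order and heights equal the direct ESS / mean-pair
        computation on every seeded cohort with n <= 8."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 9))
            x = rng.normal(size=(n, 3))
            ours = hierarchical_cluster(x, linkage=linkage).merges
            oracle = greedy_oracle(x, linkage)
            assert len(ours) == len(oracle)
            for (a1, b1, h1), (a2, b2, h2) in zip(ours, oracle):
                assert {a1, b1} == {a2, b2}
                assert abs(h1 - h2) < 1e-9

    @pytest.mark.parametrize("linkage", ["ward", "average"])
    def test_heights_are_monotone(self, linkage):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 4))
        h = hierarchical_cluster(x, linkage=linkage).heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 3))
        d1 = hierarchical_cluster(x)
        perm = rng.permutation(12)
        d2 = hierarchical_cluster(x[perm])
        mem1 = {frozenset(g) for g in cut_k_groups(d1, 4)}
        mem2 = {frozenset(int(perm[i]) for i in g)
                for g in cut_k_groups(d2, 4)}
        assert mem1 == mem2
        assert np.abs(np.sort(d1.heights()) - np.sort(d2.heights())).max() < 1e-9


class TestCuts:
    def test_two_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, (10, 5)),
                            rng.normal(10, 1, (10, 5))])
        groups = cut_two_groups(hierarchical_cluster(x))
        assert sorted(map(len, groups)) == [10, 10]
        assert set(groups[0]) == set(range(10))

    def test_n2_gives_singletons(self):
        groups = cut_two_groups(hierarchical_cluster(np.array([[0.0], [1.0]])))
        assert groups == [[0], [1]]

    def test_four_blob_k4_cut(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [20, 0], [0, 20], [20, 20]], dtype=float)
        x = np.concatenate([c + rng.normal(0, 0.5, (5, 2)) for c in centers])
        groups = cut_k_groups(hierarchical_cluster(x), 4)
        assert sorted(map(len, groups)) == [5, 5, 5, 5]
        for g in groups:
            assert len({i // 5 for i in g}) == 1

    def test_single_leaf_cut_rejected(self):
        d = Dendrogram(1, ())
        with pytest.raises(ValueError):
            cut_two_groups(d)

    def test_newick_export_has_all_leaves(self):
        x = np.arange(5, dtype=float)[:, None]
        d = hierarchical_cluster(x, labels=[f"L{i}" for i in range(5)])
        nwk = d.to_newick()
        assert all(f"L{i}" in nwk for i in range(5))
        assert nwk.endswith(";")


class TestLabelingAndClassification:
    def test_majority_rule_with_minority_members(self):
        # 41 patients + 6 controls in one group -> labeled patient
        rng = np.random.default_rng(2)
        x = rng.normal(size=(53, 4))
        labels = np.array(["ADHD"] * 41 + ["healthy"] * 12)
        groups = [list(range(47)), list(range(47, 53))]
        model = majority_label(groups, labels, x)
        assert model.group_labels == ("ADHD", "healthy")

    def test_pure_group_keeps_its_label(self):
        x = np.zeros((4, 2))
        model = majority_label([[0, 1], [2, 3]],
                               np.array(["TS", "TS", "HC", "HC"]), x)
        assert model.group_labels[0] == "TS"

    def test_tie_broken_alphabetically_with_warning(self, caplog):
        x = np.zeros((6, 2))
        labels = np.array(["b", "b", "b", "a", "a", "a"])
        with caplog.at_level("WARNING"):
            model = majority_label([[0, 1, 2, 3, 4, 5]], labels, x)
        assert model.group_labels[0] == "a"
        assert model.ties == (0,)

    def test_vector_at_group_mean_classified_with_zero_distance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, (5, 3)),
                            rng.normal(8, 1, (5, 3))])
        labels = np.array(["p"] * 5 + ["c"] * 5)
        model = majority_label([list(range(5)), list(range(5, 10))], labels, x)
        lab, dists, tie = classify(model.group_means[0], model)
        assert lab == "p"
        assert dists[0] < 1e-12
        assert not tie

    def test_equidistant_vector_flagged_and_goes_first(self):
        x = np.array([[0.0], [0.0], [2.0], [2.0]])
        model = majority_label([[0, 1], [2, 3]],
                               np.array(["a", "a", "b", "b"]), x)
        lab, _d, tie = classify(np.array([1.0]), model)
        assert lab == "a"
        assert tie

    def test_classification_scale_consistent(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, (5, 3)),
                            rng.normal(6, 1, (5, 3))])
        labels = np.array(["p"] * 5 + ["c"] * 5)
        model = majority_label([list(range(5)), list(range(5, 10))], labels, x)
        from dataclasses import replace
        scaled = replace(model, group_means=model.group_means * 7.0)
        v = rng.normal(0, 1, 3)
        assert classify(v * 7.0, scaled)[0] == classify(v, model)[0]

    def test_dimension_mismatch_rejected(self):
        x = np.zeros((4, 3))
        model = majority_label([[0, 1], [2, 3]],
                               np.array(["a", "a", "b", "b"]), x)
        with pytest.raises(ValueError):
            classify(np.zeros(5), model)
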