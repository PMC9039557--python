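"""Correlation/distance matrices, hierarchical clustering, PCA, k-means."""

import numpy as np
import pytest

from peakdiff.unsupervised import (
    DistanceSpec,
    correlation_matrix,
    distance_matrix,
    hierarchical_cluster,
    kmeans_features,
    pca,
)


class TestCorrelation:
    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        m = np.column_stack([col, col, rng.normal(size=50)])
        corr = correlation_matrix(m)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_negated_column_anticorrelates(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=50)
        corr = correlation_matrix(np.column_stack([col, -col]))
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(40, 5))
        corr = correlation_matrix(m)
        for i in range(5):
            for j in range(5):
                x, y = m[:, i] - m[:, i].mean(), m[:, j] - m[:, j].mean()
                r = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
                assert corr[i, j] == pytest.approx(r, abs=1e-12)

    def test_spearman_is_rank_pearson(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(30, 3))
        from scipy.stats import rankdata

        expected = correlation_matrix(np.apply_along_axis(rankdata, 0, m))
        np.testing.assert_allclose(correlation_matrix(m, "spearman"), expected)

    def test_zero_variance_column_warns_and_zeroes(self):
        m = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            corr = correlation_matrix(m)
        assert corr[0, 1] == 0.0 and corr[0, 0] == 1.0


class TestDistances:
    def test_identical_samples_have_zero_correlation_distance(self):
        col = np.arange(10.0)
        d = distance_matrix(np.column_stack([col, col]), "correlation_pearson")
        assert d[0, 1] == pytest.approx(0.0)

    def test_euclidean_three_four_five(self):
        m = np.array([[0.0, 3.0], [0.0, 4.0]])
        d = distance_matrix(m, "euclidean")
        assert d[0, 1] == pytest.approx(5.0)

    def test_minkowski_p1_equals_manhattan(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(20, 4))
        np.testing.assert_allclose(
            distance_matrix(m, DistanceSpec("minkowski", minkowski_p=1)),
            distance_matrix(m, "manhattan"),
        )

    def test_correlation_distance_consistent_with_correlation(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(30, 5))
        np.testing.assert_allclose(
            distance_matrix(m, "correlation_pearson"),
            (lambda c: 1 - c + np.diag(np.diag(c) - 1))(correlation_matrix(m)),
            atol=1e-12,
        )

    def test_unknown_distance_lists_options(self):
        with pytest.raises(ValueError, match="euclidean"):
            distance_matrix(np.ones((4, 3)), "mahalanobis")


class TestHierarchical:
    def test_two_samples_merge_at_their_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        res = hierarchical_cluster(d)
        assert res.merge_tree.shape == (1, 4)
        assert res.merge_tree[0, 2] == pytest.approx(0.7)

    def test_first_split_separates_simulated_groups(self):
        rng = np.random.default_rng(6)
        base_a, base_b = rng.normal(size=100), rng.normal(size=100) + 3
        cols = [base_a + rng.normal(0, 0.1, 100) for _ in range(3)]
        cols += [base_b + rng.normal(0, 0.1, 100) for _ in range(3)]
        d = distance_matrix(np.column_stack(cols), "euclidean")
        res = hierarchical_cluster(d)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res.merge_tree, 2, criterion="maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_permutation_invariance_of_merge_heights(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(50, 6))
        d = distance_matrix(m, "euclidean")
        perm = rng.permutation(6)
        d_perm = d[np.ix_(perm, perm)]
        h1 = np.sort(hierarchical_cluster(d).merge_tree[:, 2])
        h2 = np.sort(hierarchical_cluster(d_perm).merge_tree[:, 2])
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(d)


class TestPca:
    def test_duplicated_sample_has_identical_scores(self):
        rng = np.random.default_rng(8)
        col = rng.normal(size=100)
        m = np.column_stack([col, col, rng.normal(size=100), rng.normal(size=100)])
        res = pca(m)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(9)
        res = pca(rng.normal(size=(80, 5)))
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-12)
        assert v.sum() <= 1 + 1e-9

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError, match="non-constant"):
            pca(np.ones((10, 3)))

    def test_monotone_drift_orders_samples_on_pc1(self):
        rng = np.random.default_rng(10)
        drift = rng.normal(size=200)
        cols = [drift * t + rng.normal(0, 0.2, 200) for t in (0.0, 1.0, 2.0, 3.0)]
        res = pca(np.column_stack(cols))
        pc1 = res.scores[:, 0]
        assert np.all(np.diff(pc1) > 0) or np.all(np.diff(pc1) < 0)


class TestKmeans:
    def archetype_matrix(self, rng, n_per=60):
        profiles = np.array(
            [[5.0, 1.0, 1.0], [1.0, 5.0, 1.0], [1.0, 1.0, 5.0]]
        )
        rows, truth = [], []
        for k, prof in enumerate(profiles):
            rows.append(prof + rng.normal(0, 0.3, size=(n_per, 3)))
            truth += [k] * n_per
        return np.vstack(rows), np.array(truth)

    def test_recovers_planted_archetypes(self):
        rng = np.random.default_rng(11)
        m, truth = self.archetype_matrix(rng)
        labels = kmeans_features(m, 3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        m, _ = self.archetype_matrix(rng)
        a = kmeans_features(m, 3, seed=5)
        b = kmeans_features(m, 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_k_equal_to_peaks_gives_singletons(self):
        rng = np.random.default_rng(13)
        m = rng.normal(size=(6, 3))
        labels = kmeans_features(m, 6, seed=0)
        assert len(set(labels)) == 6

    def test_k_larger_than_peaks_rejected(self):
        with pytest.raises(ValueError):
            kmeans_features(np.ones((3, 2)), 4, seed=0)

    def test_labels_renumbered_by_descending_size(self):
        rng = np.random.default_rng(14)
        m = np.vstack(
            [rng.normal(0, 0.1, size=(80, 2)), rng.normal(10, 0.1, size=(20, 2))]
        )
        labels = kmeans_features(m, 2, seed=0)
        assert (labels == 1).sum() > (labels == 2).sum()
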