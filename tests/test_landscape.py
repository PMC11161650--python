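import numpy as np
import pytest

from endonet import (
    hier_cluster,
    kmeans_cluster,
    label_phenotypes,
    module_activity,
    network_from_edges,
    proportions,
    run_pca,
)
from endonet.attractors import Attractor
from endonet.landscape import binarize_threshold, signature_from_centroid


def make_blobs(rng, centers, n_per=30, sd=0.05):
    X = np.vstack([c + sd * rng.standard_normal((n_per, len(c))) for c in centers])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestPCA:
    def test_collinear_data_has_single_component(self, rng):
        t = rng.uniform(-1, 1, 40)
        X = np.outer(t, [1.0, 2.0, -0.5]) + np.array([3.0, 0.0, 1.0])
        pca = run_pca(X)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_leaves_spectrum_unchanged(self, rng):
        X = rng.standard_normal((30, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        s1 = run_pca(X).explained_variance_ratio
        s2 = run_pca(X @ Q).explained_variance_ratio
        assert np.allclose(s1, s2, atol=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.standard_normal((20, 5))
        pca = run_pca(X)
        recon = pca.scores @ pca.loadings + pca.mean
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            run_pca(np.ones((10, 3)))


class TestHierCluster:
    def test_recovers_separated_blobs(self, rng):
        X, y = make_blobs(rng, [np.zeros(4), 5 * np.ones(4), [-5, 5, -5, 5]])
        _, labels = hier_cluster(X, k=3)
        # perfect recovery up to label permutation
        for blob in range(3):
            assert len(set(labels[y == blob])) == 1
        assert len(set(labels)) == 3

    def test_k_one_groups_everything(self, rng):
        X = rng.standard_normal((10, 2))
        _, labels = hier_cluster(X, k=1)
        assert set(labels) == {0}

    def test_duplicate_rows_merge_at_height_zero(self, rng):
        X = rng.standard_normal((5, 3))
        X = np.vstack([X, X[0]])
        Z, _ = hier_cluster(X, k=2)
        assert Z[0, 2] == 0.0

    def test_k_beyond_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            hier_cluster(rng.standard_normal((3, 2)), k=4)


class TestKMeans:
    def test_centroids_near_true_means(self, rng):
        centers = [np.zeros(3), 4 * np.ones(3), [-4, 4, 0]]
        X, y = make_blobs(rng, centers, n_per=40, sd=0.1)
        km = kmeans_cluster(X, k=3, seed=0)
        for c in centers:
            assert min(np.linalg.norm(km.centroids - c, axis=1)) < 0.1

    def test_identical_rows_single_cluster(self):
        X = np.tile([1.0, 2.0], (6, 1))
        km = kmeans_cluster(X, k=1, seed=0)
        assert np.allclose(km.centroids[0], [1.0, 2.0])
        assert km.inertia == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_same_assignments(self, rng):
        X = rng.standard_normal((50, 4))
        a = kmeans_cluster(X, k=3, seed=7).assignments
        b = kmeans_cluster(X, k=3, seed=7).assignments
        assert np.array_equal(a, b)

    def test_k_beyond_distinct_rows_rejected(self):
        X = np.tile([1.0, 2.0], (6, 1))
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=2)


class TestProportions:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((111, 68, 81), (42.69, 26.15, 31.15)),
            ((123, 63, 66), (48.81, 25.00, 26.19)),
            ((47, 61, 119), (20.70, 26.87, 52.42)),
        ],
    )
    def test_domain_percentages(self, counts, expected):
        assignments = np.repeat(np.arange(len(counts)), counts)
        tab = proportions(assignments)
        assert tuple(np.round(tab["percent"], 2)) == expected
        assert tab["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_cluster_is_everything(self):
        tab = proportions(np.zeros(17, dtype=int))
        assert tab["percent"].iloc[0] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            proportions([])


SPEC3 = network_from_edges(
    [("A", "A", 1), ("B", "B", 1), ("C", "C", 1), ("A", "B", -1)]
)


class TestLabelPhenotypes:
    sig = {"A": 1, "B": 0, "C": 0}

    def test_exact_signature_centroid_labeled_normal(self):
        cents = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        labels, agree = label_phenotypes(cents, self.sig, SPEC3, threshold=0.5)
        assert labels[0] == "normal"
        assert agree[0] == 1.0

    def test_labels_invariant_under_cluster_permutation(self, rng):
        cents = np.array([[1.0, 0.1, 0.0], [0.1, 0.9, 1.0], [0.9, 0.9, 0.1]])
        labels, _ = label_phenotypes(cents, self.sig, SPEC3, threshold=0.5)
        perm = [2, 0, 1]
        labels_p, _ = label_phenotypes(cents[perm], self.sig, SPEC3, threshold=0.5)
        assert [labels_p[perm.index(i)] for i in range(3)] == labels

    def test_anti_signature_never_beats_matching_centroid(self):
        cents = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0]])
        labels, agree = label_phenotypes(cents, self.sig, SPEC3, threshold=0.5)
        assert labels[1] == "normal"
        assert agree[0] == 0.0

    def test_unknown_marker_rejected(self):
        with pytest.raises(KeyError):
            label_phenotypes(np.zeros((1, 3)), {"Z": 1}, SPEC3)

    def test_subtype_signatures_label_remaining_clusters(self):
        subs = {"type-1": {"B": 1}, "type-2": {"C": 1}}
        cents = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        labels, _ = label_phenotypes(cents, self.sig, SPEC3, subtype_signatures=subs,
                                     threshold=0.5)
        assert labels == ["normal", "type-1", "type-2"]


class TestModuleActivity:
    modules = {"m1": ["A", "B"], "m2": ["C"]}

    def test_high_members_on_low_members_off(self):
        act = module_activity(np.array([0.9, 0.8, 0.1]), self.modules, SPEC3)
        assert act == {"m1": "ON", "m2": "OFF"}

    def test_oscillating_member_propagates_flag(self):
        a = Attractor(
            x=np.array([0.9, 0.8, 0.1]),
            eta=np.ones(3),
            stability="stable",
            node_oscillating=np.array([False, True, False]),
        )
        act = module_activity(a, self.modules, SPEC3)
        assert act["m1"] == "ON|OFF"
        assert act["m2"] == "OFF"

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            module_activity(np.zeros(3), {"m": []}, SPEC3)


class TestThresholds:
    def test_midpoint_of_range_with_flat_fallback(self):
        X = np.array([[0.0, 2.0, 1.0], [1.0, 4.0, 1.0]])
        thr = binarize_threshold(X)
        assert np.allclose(thr, [0.5, 3.0, 0.5])

    def test_signature_from_centroid_binarizes(self):
        sig = signature_from_centroid(np.array([0.9, 0.2, 0.6]), SPEC3, threshold=0.5)
        assert sig == {"A": 1, "B": 0, "C": 1}
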