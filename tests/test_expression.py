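import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from endonet import cluster_samples, concordance, load_expression, preprocess
from endonet.expression import ExpressionMatrix, discretize_profile, write_expression
from endonet.synthetic import CohortSpec, make_expression_cohort


def label_agreement(true_labels, assignments):
    """Best-permutation fraction of samples assigned to their true group."""
    groups = sorted(set(true_labels))
    k = max(len(groups), int(np.max(assignments)) + 1)
    cost = np.zeros((k, k))
    for t, a in zip(true_labels, assignments):
        cost[groups.index(t) if t in groups else 0, a] -= 1
    rows, cols = linear_sum_assignment(cost)
    return -cost[rows, cols].sum() / len(true_labels)


class TestLoad:
    def test_toy_matrix_shape_and_values(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text(
            "gene\ts1\ts2\ts3\ts4\nG1\t1\t2\t3\t4\nG2\t5\t6\t7\t8\nG3\t9\t10\t11\t12\n"
        )
        m = load_expression(p)
        assert m.shape == (3, 4)
        assert m.values.loc["G2", "s3"] == 7.0
        assert m.labels is None  # no label file: unsupervised only

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\ts1\nG1\t1\nG1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_expression(p)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\ts1\ts2\nG1\t1\tok\nG2\t2\t3\n")
        with pytest.raises(ValueError, match="G1.*s2"):
            load_expression(p)

    def test_synthetic_cohort_round_trips(self, tmp_path):
        matrix, labels = make_expression_cohort(
            CohortSpec(groups={"a": 3, "b": 2}, n_genes=6, sigma=0.2, seed=1)
        )
        write_expression(matrix, tmp_path / "e.tsv", tmp_path / "l.tsv")
        back = load_expression(tmp_path / "e.tsv", tmp_path / "l.tsv")
        assert np.allclose(back.values.to_numpy(), matrix.values.to_numpy())
        assert list(back.labels) == list(labels)


class TestPreprocess:
    def _matrix(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 4.0, 7.0], "s2": [2.0, 4.0, 7.0], "s3": [4.0, 4.0, 7.0]},
            index=["G1", "G2", "G3"],
        )
        return ExpressionMatrix(vals)

    def test_constant_genes_dropped_under_zscore(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = preprocess(self._matrix(), zscore=True)
        assert out.genes == ["G1"]

    def test_zscore_rows_are_standardized(self):
        with pytest.warns(UserWarning):
            out = preprocess(self._matrix(), zscore=True)
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-12)
        assert np.allclose(out.values.std(axis=1, ddof=0), 1.0)

    def test_log2_of_powers_of_two(self):
        out = preprocess(self._matrix(), log_transform=True)
        assert out.values.loc["G2"].tolist() == [2.0, 2.0, 2.0]
        assert out.values.loc["G1", "s3"] == 2.0

    def test_log_of_nonpositive_rejected(self):
        vals = pd.DataFrame({"s1": [0.0]}, index=["G1"])
        with pytest.raises(ValueError, match="positive"):
            preprocess(ExpressionMatrix(vals), log_transform=True)


class TestClusterSamples:
    def test_planted_cohort_recovered_at_low_noise(self):
        matrix, labels = make_expression_cohort(CohortSpec(sigma=0.1, seed=3))
        assign, centroids, _ = cluster_samples(matrix, k=3, seed=0)
        assert label_agreement(list(labels), assign) >= 0.95
        assert centroids.shape == (3, matrix.shape[0])

    def test_k_one_single_cluster(self):
        matrix, _ = make_expression_cohort(
            CohortSpec(groups={"a": 4}, n_genes=5, seed=0)
        )
        assign, _, _ = cluster_samples(matrix, k=1)
        assert set(assign) == {0}

    def test_accuracy_degrades_monotonically_with_noise(self):
        accs = []
        for sigma in (0.05, 0.5, 2.0):
            scores = []
            for seed in range(3):
                matrix, labels = make_expression_cohort(
                    CohortSpec(sigma=sigma, seed=seed, n_genes=20)
                )
                assign, _, _ = cluster_samples(matrix, k=3, seed=0)
                scores.append(label_agreement(list(labels), assign))
            accs.append(np.mean(scores))
        assert accs[0] >= accs[1] >= accs[2] - 1e-9

    def test_more_clusters_than_samples_rejected(self):
        matrix, _ = make_expression_cohort(
            CohortSpec(groups={"a": 2}, n_genes=4, seed=0)
        )
        with pytest.raises(ValueError):
            cluster_samples(matrix, k=3)


class TestConcordance:
    def test_identical_profiles_agree_fully(self):
        p = np.array([0.1, 0.9, 0.5, 0.2])
        out = concordance(p, p.copy())
        assert out["agreement_percent"] == 100.0
        assert out["chance_percent"] == 25.0

    def test_fully_discordant_profiles_agree_nowhere(self):
        out = concordance(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert out["agreement_percent"] == 0.0

    def test_symmetric_and_order_invariant(self, rng):
        a, b = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        ab = concordance(a, b)["agreement_percent"]
        ba = concordance(b, a)["agreement_percent"]
        assert ab == ba
        perm = rng.permutation(12)
        assert concordance(a[perm], b[perm])["agreement_percent"] == ab

    def test_gene_map_aggregates_by_median(self):
        nodes = ["N1", "N2"]
        genes = ["g1a", "g1b", "g1c", "g2"]
        gmap = {"N1": ["g1a", "g1b", "g1c"], "N2": ["g2"]}
        model = np.array([1.0, 0.0])
        data = np.array([5.0, 9.0, 7.0, 0.0])  # median of N1 genes = 7
        out = concordance(model, data, node_gene_map=gmap, nodes=nodes, gene_index=genes)
        assert out["n_comparable"] == 2
        assert out["agreement_percent"] == 100.0

    def test_unmapped_nodes_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance(
                np.array([1.0]),
                np.array([1.0]),
                node_gene_map={"N1": ["missing"]},
                nodes=["N1"],
                gene_index=["other"],
            )

    def test_oscillatory_flag_moves_node_to_its_own_category(self):
        p = np.array([0.1, 0.9, 0.5])
        cats = discretize_profile(p, levels=4, oscillatory=[False, True, False])
        assert cats[1] == 3

    def test_random_categorical_profiles_agree_at_chance(self, rng):
        levels = 4
        draws = 2000
        agree = [
            np.mean(
                rng.integers(0, levels, size=55) == rng.integers(0, levels, size=55)
            )
            for _ in range(draws)
        ]
        assert np.mean(agree) * 100 == pytest.approx(100 / levels, abs=1.0)
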