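"""Subtree embeddings, pattern discovery, histograms, and the cosine kernel."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmegraph import (
    build_graph,
    cluster_subtrees,
    compute_embeddings,
    compute_signatures,
    kernel,
    kernel_matrix,
    neighborhood_membership,
    pattern_histogram,
    pattern_histograms,
)

from conftest import make_cells


def convolution_oracle(weights: np.ndarray, features: np.ndarray, h: int) -> np.ndarray:
    """Independent per-node sweep oracle: x_i <- x_i + sum_{j != i} x_j w_ij."""
    X = features.copy()
    n = weights.shape[0]
    for _ in range(h):
        new = np.empty_like(X)
        for i in range(n):
            acc = X[i].copy()  # self-loop weight is exactly 1
            for j in range(n):
                if j != i:
                    acc = acc + X[j] * weights[i, j]
            new[i] = acc
        X = new
    return X


def random_weighted_graph(rng, n, m=3):
    W = rng.uniform(0, 1, (n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    X0 = np.zeros((n, m))
    X0[np.arange(n), rng.integers(0, m, n)] = 1.0
    return W, X0


class TestComputeEmbeddings:
    def test_isolated_cell_keeps_one_hot(self, vocab2):
        cells = make_cells([("p", "i", 0.0, 0.0, "t_cell")], vocab2)
        g = build_graph(cells)
        for h in (1, 2, 5):
            assert np.array_equal(compute_embeddings(g, h), [[0.0, 1.0]])

    def test_two_cell_hand_values(self, two_cell_patient):
        w = np.exp(-1.0)
        g = build_graph(two_cell_patient)
        x1 = compute_embeddings(g, h=1)
        assert x1[0] == pytest.approx([1.0, w], abs=1e-12)
        x2 = compute_embeddings(g, h=2)
        assert x2[0] == pytest.approx([1.0 + w * w, 2 * w], abs=1e-12)

    def test_matrix_power_equals_iterative_oracle(self):
        from tmegraph.cellular_graph import CellularGraph
        from tmegraph.io import PhenotypeVocabulary

        rng = np.random.default_rng(42)
        vocab = PhenotypeVocabulary(
            ("a", "b", "c"), {"a": "tumor", "b": "immune", "c": "stromal"}
        )
        for _ in range(20):
            n = int(rng.integers(2, 30))
            W, X0 = random_weighted_graph(rng, n)
            g = CellularGraph(
                patient_id="p", weights=W, node_features=X0,
                phenotype_codes=X0.argmax(1), image_ids=np.repeat("i", n),
                coordinates=np.zeros((n, 2)), vocabulary=vocab, alpha=0.01,
            )
            h = int(rng.integers(1, 4))
            assert np.allclose(
                compute_embeddings(g, h), convolution_oracle(W, X0, h), atol=1e-9
            )

    def test_dense_and_sparse_paths_agree(self, vocab2):
        rng = np.random.default_rng(3)
        rows = [("p", "i", float(x), float(y), "tumor_ck")
                for x, y in rng.uniform(0, 100, (40, 2))]
        g = build_graph(make_cells(rows, vocab2))
        dense = compute_embeddings(g, 2, use_sparse=False)
        sparse = compute_embeddings(g, 2, use_sparse=True)
        assert np.allclose(dense, sparse, atol=1e-9)

    def test_mass_conservation(self, vocab3):
        """Row sums of embeddings equal row sums of A^h (one-hot features)."""
        rng = np.random.default_rng(4)
        rows = [("p", "i", float(x), float(y), vocab3.names[int(c)])
                for (x, y), c in zip(rng.uniform(0, 60, (25, 2)), rng.integers(0, 3, 25))]
        g = build_graph(make_cells(rows, vocab3))
        for h in (1, 2, 3):
            X = compute_embeddings(g, h)
            Ah = np.linalg.matrix_power(g.weights, h)
            assert np.allclose(X.sum(axis=1), Ah.sum(axis=1), atol=1e-9)


class TestNeighborhoodMembership:
    def test_isolated_cell_is_own_neighborhood(self, vocab2):
        g = build_graph(make_cells([("p", "i", 0.0, 0.0, "t_cell")], vocab2))
        members, sizes, radii = neighborhood_membership(g, h=2, tau=0.01)
        assert members[0].tolist() == [0]
        assert sizes[0] == 1 and radii[0] == 0.0

    def test_strictly_greater_than_tau_rule(self, vocab2):
        # distance chosen so (A^2)_01 = 2w + w^2... pick far cells: tiny influence
        cells = make_cells(
            [("p", "i", 0.0, 0.0, "tumor_ck"), ("p", "i", 40.0, 0.0, "t_cell")], vocab2
        )
        g = build_graph(cells)
        A2 = np.linalg.matrix_power(g.weights, 2)
        assert A2[0, 1] < 0.01  # premise of the test
        members, sizes, _ = neighborhood_membership(g, h=2, tau=0.01)
        assert sizes.tolist() == [1, 1]

    def test_matches_brute_force_on_uniform_disc(self, vocab2):
        rng = np.random.default_rng(5)
        r = 50 * np.sqrt(rng.uniform(0, 1, 100))
        th = rng.uniform(0, 2 * np.pi, 100)
        rows = [("p", "i", float(x), float(y), "tumor_ck")
                for x, y in zip(r * np.cos(th), r * np.sin(th))]
        g = build_graph(make_cells(rows, vocab2))
        members, sizes, _ = neighborhood_membership(g, h=2, tau=0.01)
        A2 = np.linalg.matrix_power(g.weights, 2)
        expected = (A2 > 0.01).sum(axis=1)
        assert np.array_equal(sizes, expected)
        for i in (0, 13, 99):
            assert np.array_equal(members[i], np.flatnonzero(A2[i] > 0.01))


class TestClusterSubtrees:
    def test_identical_embeddings_give_one_pattern(self):
        X = np.tile([1.0, 2.0, 0.5], (80, 1))
        labels, model = cluster_subtrees(X, k_pheno=10, seed=0)
        assert model.n_patterns == 1
        assert set(labels) == {1}

    def test_two_planted_blobs_recovered_exactly(self):
        # tight blobs (sigma 0.01, separation 100) in a 16-marker space: the
        # within-blob k-NN graph is unstructured, so Louvain keeps blobs whole
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0.0, 0.01, (200, 16)),
            rng.normal(100.0, 0.01, (200, 16)),
        ])
        planted = np.repeat([0, 1], 200)
        labels, model = cluster_subtrees(X, k_pheno=20, seed=0)
        assert model.n_patterns == 2
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_same_seed_reproduces_labels(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (300, 4))
        la, _ = cluster_subtrees(X, k_pheno=15, seed=9)
        lb, _ = cluster_subtrees(X, k_pheno=15, seed=9)
        assert np.array_equal(la, lb)

    def test_requires_more_rows_than_k(self):
        with pytest.raises(ValueError, match="k_pheno"):
            cluster_subtrees(np.zeros((10, 2)), k_pheno=10, seed=0)

    def test_signatures_are_member_means(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.01, (60, 2)), rng.normal(50, 0.01, (60, 2))])
        labels, model = cluster_subtrees(X, k_pheno=10, seed=0)
        for c in range(1, model.n_patterns + 1):
            assert np.allclose(
                model.signatures[c - 1], X[labels == c].mean(axis=0), atol=1e-9
            )


class TestSignatures:
    def test_singleton_and_hand_mean(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [3.0, 3.0]])
        sig = compute_signatures(X, np.array([1, 1, 2]))
        assert np.allclose(sig, [[0.5, 0.5], [3.0, 3.0]])

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 4))
        labels = rng.integers(1, 4, 30)
        sig = compute_signatures(X, labels)
        perm = {1: 3, 2: 1, 3: 2}
        sig_p = compute_signatures(X, np.array([perm[l] for l in labels]))
        for old, new in perm.items():
            assert np.allclose(sig[old - 1], sig_p[new - 1])

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError, match="no members"):
            compute_signatures(np.ones((2, 2)), np.array([1, 3]))


class TestHistogramsAndKernel:
    def test_hand_histograms(self):
        assert pattern_histogram(np.array([2, 2, 2, 2, 2]), 3).tolist() == [0, 5, 0]
        assert pattern_histogram(np.array([1, 1, 2, 3]), 3).tolist() == [2, 1, 1]

    def test_histogram_conservation_across_patients(self, small_cohort, small_config):
        from tmegraph.pipeline import cohort_embeddings, cohort_graphs

        graphs = cohort_graphs(small_cohort.cells, small_config)
        X, owners = cohort_embeddings(graphs, small_config)
        labels, model = cluster_subtrees(X, small_config.k_pheno, seed=7)
        H = pattern_histograms(labels, owners, model.n_patterns)
        counts = small_cohort.cells.cells_per_patient()
        assert (H.sum(axis=1) == counts.loc[H.index]).all()
        assert np.array_equal(
            H.sum(axis=0).to_numpy(),
            np.bincount(labels, minlength=model.n_patterns + 1)[1:],
        )

    def test_kernel_hand_values(self):
        assert kernel([2, 0], [2, 0]) == 1.0
        assert kernel([2, 0], [0, 3]) == 0.0
        assert kernel([2, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_kernel_rejects_zero_histogram(self):
        with pytest.raises(ValueError):
            kernel([0, 0], [1, 0])

    def test_kernel_matrix_properties(self):
        rng = np.random.default_rng(6)
        H = pd.DataFrame(rng.integers(0, 20, (15, 6)) + 1)
        K = kernel_matrix(H)
        Kv = K.to_numpy()
        assert np.allclose(Kv, Kv.T)
        assert np.allclose(np.diag(Kv), 1.0)
        assert np.linalg.eigvalsh(Kv).min() >= -1e-8
        assert Kv.min() >= 0.0 and Kv.max() <= 1.0


class TestPermutationInvariance:
    def test_row_order_does_not_change_histograms_or_kernel(self, small_cohort, small_config):
        from tmegraph.pipeline import cohort_embeddings, cohort_graphs

        cells = small_cohort.cells
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(cells))
        shuffled = type(cells)(
            cells.cells.iloc[perm].reset_index(drop=True), cells.vocabulary
        )
        X1, own1 = cohort_embeddings(cohort_graphs(cells, small_config), small_config)
        X2, own2 = cohort_embeddings(cohort_graphs(shuffled, small_config), small_config)
        labels1, model1 = cluster_subtrees(X1, small_config.k_pheno, seed=7)
        H1 = pattern_histograms(labels1, own1, model1.n_patterns)
        # map the shuffled cohort's embeddings onto the same model: histograms equal
        from tmegraph.mapping import map_subtrees_to_patterns

        labels2 = map_subtrees_to_patterns(X2, model1)
        H2 = pattern_histograms(labels2, own2, model1.n_patterns)
        H2 = H2.loc[H1.index]
        labels1_mapped = map_subtrees_to_patterns(X1, model1)
        H1_mapped = pattern_histograms(labels1_mapped, own1, model1.n_patterns)
        pd.testing.assert_frame_equal(H1_mapped, H2)
        K1 = kernel_matrix(H1_mapped)
        K2 = kernel_matrix(H2)
        assert np.allclose(K1.to_numpy(), K2.to_numpy(), atol=1e-12)
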