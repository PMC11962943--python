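"""Comparator representations: abundance, proximity, and the classic WL kernel."""

import itertools

import numpy as np
import pytest

from tmegraph import binarize_graph, build_graph, kernel
from tmegraph.baselines import (
    category_abundance,
    cell_abundance,
    pairwise_proximity,
    proximity_pair_names,
    wl_color_refinement,
    wl_features,
    wl_profiles,
)

from conftest import make_cells


class TestCellAbundance:
    def test_hand_histogram(self, vocab2):
        cells = make_cells(
            [("p", "i", float(k), 0.0, "tumor_ck") for k in range(3)], vocab2
        )
        assert cell_abundance(cells).tolist() == [3.0, 0.0]

    def test_sums_to_cell_count(self, small_cohort):
        for pid in small_cohort.cells.patient_ids[:3]:
            sub = small_cohort.cells.for_patient(pid)
            assert cell_abundance(sub).sum() == len(sub)


class TestPairwiseProximity:
    def test_coincident_pair_scores_one(self, vocab2):
        cells = make_cells(
            [("p", "i", 1.0, 1.0, "tumor_ck"), ("p", "i", 1.0, 1.0, "t_cell")], vocab2
        )
        assert pairwise_proximity(cells).tolist() == [1.0]

    def test_hand_mean_of_two_equal_terms(self, vocab2):
        cells = make_cells(
            [("p", "i", 0.0, 0.0, "tumor_ck"),
             ("p", "i", 10.0, 0.0, "t_cell"),
             ("p", "i", -10.0, 0.0, "t_cell")],
            vocab2,
        )
        assert pairwise_proximity(cells)[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_absent_pair_is_zero_with_warning(self, vocab3, caplog):
        cells = make_cells([("p", "i", 0.0, 0.0, "tumor_ck")], vocab3)
        with caplog.at_level("WARNING"):
            prox = pairwise_proximity(cells)
        assert prox.tolist() == [0.0, 0.0, 0.0]
        assert "proximity set to 0" in caplog.text

    def test_cross_image_pairs_excluded(self, vocab2):
        near = make_cells(
            [("p", "a", 0.0, 0.0, "tumor_ck"), ("p", "a", 5.0, 0.0, "t_cell")], vocab2
        )
        split = make_cells(
            [("p", "a", 0.0, 0.0, "tumor_ck"), ("p", "b", 5.0, 0.0, "t_cell")], vocab2
        )
        assert pairwise_proximity(near)[0] > 0.7
        assert pairwise_proximity(split)[0] == 0.0

    def test_bounds_and_permutation_invariance(self, vocab3):
        rng = np.random.default_rng(0)
        rows = [("p", "i", float(x), float(y), vocab3.names[int(c)])
                for (x, y), c in zip(rng.uniform(0, 80, (30, 2)), rng.integers(0, 3, 30))]
        base = pairwise_proximity(make_cells(rows, vocab3))
        assert (base >= 0).all() and (base <= 1).all()
        perm = rng.permutation(30)
        shuffled = pairwise_proximity(make_cells([rows[i] for i in perm], vocab3))
        assert np.allclose(base, shuffled, atol=1e-12)
        assert len(base) == len(proximity_pair_names(vocab3)) == 3


class TestCategoryAbundance:
    def test_counts_by_niche_category(self):
        labels = np.array([1, 1, 2, 3, 3, 3])
        cats = np.array(["tumor", "interface", "immune"], dtype=object)
        out = category_abundance(labels, cats)
        assert out.tolist() == [2.0, 3.0, 0.0, 1.0]  # tumor, immune, stromal, interface
        assert out.sum() == len(labels)


# ---------------------------------------------------------------------------
# classic WL refinement with an exhaustive rooted-subtree-isomorphism oracle


def unfolding_tree(adj: np.ndarray, labels: np.ndarray, v: int, depth: int):
    """Canonical form of the depth-``depth`` WL unfolding tree rooted at v."""
    if depth == 0:
        return (int(labels[v]),)
    children = sorted(
        unfolding_tree(adj, labels, int(u), depth - 1)
        for u in np.flatnonzero(adj[v])
    )
    return (int(labels[v]), tuple(children))


def all_graphs(n: int):
    """Every labeled graph on n nodes (all edge subsets)."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n), dtype=bool)
        for k, (i, j) in enumerate(pairs):
            if bits >> k & 1:
                adj[i, j] = adj[j, i] = True
        yield adj


class TestWLColorRefinement:
    def test_path_aba_hand_case(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        labels = np.array([0, 1, 0])
        (colors,), table = wl_color_refinement([(adj, labels)], h=1)
        assert colors[1, 0] == colors[1, 2] != colors[1, 1]
        feats = wl_features([colors], table, mode="accumulated")
        assert feats.tolist() == [[2.0, 1.0, 2.0, 1.0]]

    def test_isomorphic_graphs_share_color_multisets(self):
        rng = np.random.default_rng(1)
        n = 7
        adj = rng.uniform(size=(n, n)) < 0.4
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        labels = rng.integers(0, 2, n)
        perm = rng.permutation(n)
        adj_p = adj[np.ix_(perm, perm)]
        labels_p = labels[perm]
        (c1, c2), table = wl_color_refinement([(adj, labels), (adj_p, labels_p)], h=2)
        for t in range(3):
            assert sorted(c1[t]) == sorted(c2[t])

    def test_edgeless_graph_partition_stable(self):
        # relabeling mints fresh ids each iteration, but with no neighbors the
        # induced partition never refines past the initial labels
        adj = np.zeros((4, 4), dtype=bool)
        labels = np.array([0, 1, 0, 1])
        (colors,), _ = wl_color_refinement([(adj, labels)], h=2)
        for t in (1, 2):
            assert colors[t, 0] == colors[t, 2]
            assert colors[t, 1] == colors[t, 3]
            assert colors[t, 0] != colors[t, 1]

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_subtree_isomorphism_oracle_exhaustively(self, n):
        """WL colors coincide across a cohort exactly when unfolding trees match."""
        labels = np.array([k % 2 for k in range(n)])
        graphs = [(adj, labels) for adj in all_graphs(n)]
        colorings, _ = wl_color_refinement(graphs, h=2)
        for depth in (1, 2):
            canon = {}
            for (adj, labs), colors in zip(graphs, colorings):
                for v in range(n):
                    key = unfolding_tree(adj, labs, v, depth)
                    color = colors[depth, v]
                    assert canon.setdefault(key, color) == color
            # bijection: distinct trees never share a color
            assert len(set(canon.values())) == len(canon)


class TestWLFeatures:
    def test_identical_graphs_have_similarity_one_both_modes(self, vocab2):
        rng = np.random.default_rng(2)
        rows = [("p", "i", float(x), float(y), vocab2.names[int(c)])
                for (x, y), c in zip(rng.uniform(0, 40, (12, 2)), rng.integers(0, 2, 12))]
        g = build_graph(make_cells(rows, vocab2))
        for mode in ("accumulated", "last"):
            feats = wl_profiles([g, g], h=2, mode=mode)
            assert kernel(feats[0], feats[1]) == pytest.approx(1.0)

    def test_last_mode_is_diagonal_dominant_on_heterogeneous_cohort(self, small_cohort):
        from tmegraph.pipeline import cohort_graphs
        from tmegraph import RunConfig

        graphs = cohort_graphs(small_cohort.cells, RunConfig(min_cells=1))
        feats = wl_profiles(graphs, h=2, mode="last")
        # distinct continuous geometries share almost no depth-2 colors
        sims = [
            kernel(feats[i], feats[j])
            for i, j in itertools.combinations(range(len(graphs)), 2)
        ]
        assert np.mean(np.array(sims) < 0.2) > 0.9

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            wl_features([], None, mode="middle")
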