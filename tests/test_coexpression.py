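"""Similarity, soft thresholding, TOM, clustering, eigengenes, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from coexrules import (
    ModuleAssignment,
    adjacency,
    cut_modules,
    generate_test_graph,
    hierarchical_cluster,
    merge_close_modules,
    module_eigengene,
    scale_free_fit,
    select_beta,
    similarity,
    topological_overlap,
)


def _expr(rows: dict, n_samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


class TestSimilarity:
    def test_perfectly_anticorrelated_genes_score_one(self):
        x = np.arange(10.0)
        s = similarity(_expr({"a": x, "b": -x}))
        assert s.loc["a", "b"] == pytest.approx(1.0)

    def test_identical_genes_score_one(self):
        x = np.arange(10.0)
        s = similarity(_expr({"a": x, "b": x}))
        assert s.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(0)
        s = similarity(_expr({"a": rng.normal(size=1000), "b": rng.normal(size=1000)}))
        assert s.loc["a", "b"] < 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            similarity(_expr({"a": [1.0, 2.0], "b": [2.0, 1.0]}))

    def test_constant_gene_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            s = similarity(_expr({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]}))
        assert list(s.index) == ["a"]


class TestAdjacency:
    def test_power_one_is_identity(self):
        s = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]])
        assert adjacency(s, 1).equals(s)

    def test_worked_power(self):
        s = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]])
        assert adjacency(s, 12).iloc[0, 1] == pytest.approx(0.2824, abs=1e-4)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency(pd.DataFrame([[1.0]]), 0.5)

    def test_increasing_beta_weakly_decreases_offdiagonal(self):
        rng = np.random.default_rng(3)
        s = rng.random((10, 10))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        s = pd.DataFrame(s)
        prev = adjacency(s, 1)
        for beta in range(2, 8):
            nxt = adjacency(s, beta)
            assert (nxt.to_numpy() <= prev.to_numpy() + 1e-12).all()
            prev = nxt


class TestScaleFreeFit:
    def test_preferential_attachment_fits_power_law(self):
        g = generate_test_graph("preferential_attachment", 500, seed=1, m=2)
        assert scale_free_fit(g) > 0.8

    def test_poisson_graph_fits_worse(self):
        ba = generate_test_graph("preferential_attachment", 500, seed=1, m=2)
        er = generate_test_graph("erdos_renyi", 500, seed=1, p=0.05)
        assert scale_free_fit(er) < scale_free_fit(ba)

    def test_regular_graph_returns_nan(self):
        g = generate_test_graph("complete", 20)
        assert np.isnan(scale_free_fit(g))


@pytest.fixture(scope="module")
def expr(modular_dataset):
    cm, _ = modular_dataset
    return np.log2(cm.counts + 1.0)


class TestSelectBeta:
    def test_single_candidate_returned(self, expr):
        beta, table = select_beta(expr, candidates=[7])
        assert beta == 7
        assert len(table) == 1

    def test_table_has_one_row_per_candidate(self, expr):
        beta, table = select_beta(expr)
        assert list(table["beta"]) == list(range(1, 21))
        assert {"fit_index", "mean_connectivity"} <= set(table.columns)
        assert beta in range(1, 21)

    def test_trivially_met_target_returns_smallest(self, expr):
        beta, _ = select_beta(expr, target_fit=-1.0)
        assert beta == 1

    def test_empty_candidates_rejected(self, expr):
        with pytest.raises(ValueError):
            select_beta(expr, candidates=[])


class TestTopologicalOverlap:
    def test_clique_has_unit_overlap(self):
        a = np.ones((5, 5))
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(pd.DataFrame(a))
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_disconnected_pair_without_shared_neighbors_is_zero(self):
        a = np.zeros((4, 4))
        tom = topological_overlap(pd.DataFrame(a))
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_single_isolated_edge_has_unit_overlap(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        tom = topological_overlap(pd.DataFrame(a))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(pd.DataFrame(a))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.integers(min_value=2, max_value=12).map(lambda n: (n, n)),
            elements=st.floats(min_value=0.0, max_value=1.0),
        )
    )
    def test_symmetry_and_range_on_random_matrices(self, raw):
        a = (raw + raw.T) / 2
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(np.diag(tom), 1.0)


class TestHierarchicalCluster:
    def test_identical_genes_merge_first_at_zero(self):
        d = np.array([[0, 0, 0.9], [0, 0, 0.9], [0.9, 0.9, 0]], dtype=float)
        Z = hierarchical_cluster(pd.DataFrame(d))
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_average_linkage_heights(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]], dtype=float)
        Z = hierarchical_cluster(pd.DataFrame(d))
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)

    def test_single_observation_gives_empty_merge_list(self):
        Z = hierarchical_cluster(pd.DataFrame([[0.0]]))
        assert Z.shape == (0, 4)

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_cluster(pd.DataFrame(d))


class TestCutModules:
    def test_all_similar_genes_form_one_module(self):
        d = np.zeros((10, 10))
        Z = hierarchical_cluster(pd.DataFrame(d))
        ma = cut_modules(Z, [f"g{i}" for i in range(10)], min_module_size=3)
        assert ma.sizes().to_dict() == {1: 10}

    def test_oversized_minimum_leaves_all_unassigned(self):
        d = np.full((6, 6), 1e-6)
        np.fill_diagonal(d, 0.0)
        Z = hierarchical_cluster(pd.DataFrame(d))
        ma = cut_modules(Z, [f"g{i}" for i in range(6)], min_module_size=30)
        assert (ma.labels == 0).all()

    def test_labels_ranked_by_module_size(self):
        # two clean blocks of different sizes far below the top merge
        n1, n2 = 4, 8
        n = n1 + n2
        d = np.full((n, n), 1.0)
        d[:n1, :n1] = 0.05
        d[n1:, n1:] = 0.05
        np.fill_diagonal(d, 0.0)
        Z = hierarchical_cluster(pd.DataFrame(d))
        ma = cut_modules(Z, [f"g{i}" for i in range(n)], min_module_size=2)
        assert ma.sizes().to_dict() == {1: 8, 2: 4}
        assert ma.colors().iloc[-1] == "turquoise"  # largest module


class TestModuleEigengene:
    def _assignment(self, genes, label=1):
        return ModuleAssignment(pd.Series(label, index=pd.Index(genes), name="module"))

    def test_identical_profiles_fully_explained(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = _expr({"a": x, "b": x, "c": x})
        eg = module_eigengene(expr, self._assignment(["a", "b", "c"]))
        assert eg.explained_variance[1] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(
            eg.values.loc[1].to_numpy(), z / np.linalg.norm(z), atol=1e-12
        )

    def test_anticorrelated_pair_is_rank_one_and_deterministic(self):
        x = np.array([1.0, -2.0, 0.5, 3.0, -2.5])
        expr = _expr({"a": x, "b": -x})
        eg = module_eigengene(expr, self._assignment(["a", "b"]))
        # standardized profiles z and -z span a rank-1 cloud
        assert eg.explained_variance[1] == pytest.approx(1.0)
        # mean profile is zero: the sign convention falls back to a fixed rule
        again = module_eigengene(expr, self._assignment(["a", "b"]))
        np.testing.assert_allclose(eg.values.loc[1], again.values.loc[1])
        profile = eg.values.loc[1].to_numpy()
        assert profile[np.flatnonzero(profile)[0]] > 0

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(4)
        expr = _expr({f"g{i}": rng.normal(size=8) for i in range(5)})
        ma = self._assignment(list(expr.index))
        eg1 = module_eigengene(expr, ma)
        eg2 = module_eigengene(expr.iloc[::-1], ma)
        np.testing.assert_allclose(eg1.values.loc[1], eg2.values.loc[1], atol=1e-10)

    def test_singleton_module_uses_standardized_profile(self):
        x = np.array([2.0, 4.0, 6.0, 8.0])
        eg = module_eigengene(_expr({"a": x}), self._assignment(["a"]))
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(eg.values.loc[1], z / np.linalg.norm(z))

    def test_eigengene_correlates_positively_with_mean_profile(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=12)
        expr = _expr({f"g{i}": base + rng.normal(scale=0.3, size=12) for i in range(6)})
        eg = module_eigengene(expr, self._assignment(list(expr.index)))
        mean_profile = expr.mean(axis=0)
        assert np.corrcoef(eg.values.loc[1], mean_profile)[0, 1] > 0


class TestMergeCloseModules:
    def test_identical_modules_are_merged(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=10)
        rows = {f"a{i}": base + rng.normal(scale=0.05, size=10) for i in range(3)}
        rows |= {f"b{i}": base + rng.normal(scale=0.05, size=10) for i in range(3)}
        expr = _expr(rows)
        labels = pd.Series([1] * 3 + [2] * 3, index=expr.index, name="module")
        merged = merge_close_modules(expr, ModuleAssignment(labels), cut=0.25)
        assert merged.module_ids() == [1]

    def test_dissimilar_modules_left_alone(self):
        rng = np.random.default_rng(6)
        f1, f2 = rng.normal(size=10), rng.normal(size=10)
        rows = {f"a{i}": f1 + rng.normal(scale=0.05, size=10) for i in range(3)}
        rows |= {f"b{i}": f2 + rng.normal(scale=0.05, size=10) for i in range(3)}
        expr = _expr(rows)
        labels = pd.Series([1] * 3 + [2] * 3, index=expr.index, name="module")
        ma = ModuleAssignment(labels)
        merged = merge_close_modules(expr, ma, cut=0.25)
        assert merged.module_ids() == [1, 2]

    def test_zero_cut_never_merges(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=10)
        rows = {f"g{i}": base + rng.normal(scale=0.01, size=10) for i in range(4)}
        expr = _expr(rows)
        labels = pd.Series([1, 1, 2, 2], index=expr.index, name="module")
        merged = merge_close_modules(expr, ModuleAssignment(labels), cut=0.0)
        assert len(merged.module_ids()) == 2

    def test_idempotent_at_fixed_cut(self):
        rng = np.random.default_rng(8)
        rows = {f"g{i}": rng.normal(size=10) for i in range(9)}
        expr = _expr(rows)
        labels = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3], index=expr.index, name="module")
        once = merge_close_modules(expr, ModuleAssignment(labels), cut=0.25)
        twice = merge_close_modules(expr, once, cut=0.25)
        assert once.labels.equals(twice.labels)


class TestAdjacencySimilarityIdentity:
    def test_power_one_roundtrip_exact(self, modular_dataset):
        cm, _ = modular_dataset
        expr = np.log2(cm.counts.iloc[:60] + 1.0)
        s = similarity(expr)
        assert adjacency(s, 1).equals(s)
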