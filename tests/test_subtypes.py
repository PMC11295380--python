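"""Subcluster merging: profiles, top-SD genes, Spearman similarity, naming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from hccsubtypes import (hcluster_merge, mean_profiles, rank_markers,
                         spearman_matrix, top_sd_genes)
from hccsubtypes.subtypes import ClusterProfile, TranscriptomeSimilarityMerger


def _profile(values, genes=None, clusters=None) -> ClusterProfile:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{j}" for j in range(values.shape[1])]
    clusters = clusters if clusters is not None else list(range(values.shape[0]))
    means = pd.DataFrame(values, index=clusters, columns=genes)
    return ClusterProfile(means=means, sizes=pd.Series(1, index=clusters))


class TestMeanProfiles:
    def test_identical_cells_profile_equals_cell(self):
        expr = pd.DataFrame([[1.0, 2.0]] * 4, index=list("abcd"), columns=["X", "Y"])
        prof = mean_profiles(expr, pd.Series(0, index=expr.index))
        np.testing.assert_allclose(prof.means.loc[0], [1.0, 2.0])

    def test_two_cell_mean(self):
        expr = pd.DataFrame({"G": [1.0, 3.0]}, index=["a", "b"])
        prof = mean_profiles(expr, pd.Series([5, 5], index=expr.index))
        assert prof.means.loc[5, "G"] == 2.0
        assert prof.sizes[5] == 2

    def test_grouping_oracle(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(10, 4)),
                            index=[f"c{i}" for i in range(10)])
        labels = pd.Series(rng.integers(0, 3, 10), index=expr.index)
        prof = mean_profiles(expr, labels)
        for cl in labels.unique():
            np.testing.assert_allclose(prof.means.loc[cl],
                                       expr[labels == cl].mean(axis=0))

    def test_unlabeled_cell_rejected(self):
        expr = pd.DataFrame({"G": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="label"):
            mean_profiles(expr, pd.Series([0], index=["a"]))


class TestTopSDGenes:
    def test_constant_gene_ranks_last(self):
        prof = _profile([[1, 5, 0], [1, 9, 4], [1, 1, 8]])
        assert top_sd_genes(prof, 3)[-1] == "G0"

    def test_single_variable_gene_first(self):
        prof = _profile([[0, 0, 5], [0, 0, -5]])
        assert top_sd_genes(prof, 1) == ["G2"]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 20))
        prof = _profile(values)
        expected = sorted(range(20), key=lambda j: (-values[:, j].std(ddof=0), j))
        assert top_sd_genes(prof, 20) == [f"G{j}" for j in expected]

    def test_too_many_requested(self):
        with pytest.raises(ValueError, match="available"):
            top_sd_genes(_profile([[1, 2], [3, 4]]), 3)


class TestSpearman:
    def test_identical_profiles_rho_one(self):
        prof = _profile([[1, 2, 3, 4], [1, 2, 3, 4]])
        sim = spearman_matrix(prof, prof.means.columns.tolist())
        np.testing.assert_allclose(sim.to_numpy(), 1.0)

    def test_reversed_ranks_rho_minus_one(self):
        prof = _profile([[1, 2, 3, 4], [4, 3, 2, 1]])
        sim = spearman_matrix(prof, prof.means.columns.tolist())
        assert sim.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(4, 5))
        values[1, 2] = values[1, 0]  # inject a tie to exercise average ranks
        prof = _profile(values)
        sim = spearman_matrix(prof, prof.means.columns.tolist())
        expected = spearmanr(values.T).statistic
        np.testing.assert_allclose(sim.to_numpy(), expected, atol=1e-12)

    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_to_monotone_transform(self, transform):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(3, 8))
        fn = {"exp": np.exp, "cube": lambda x: x ** 3,
              "affine": lambda x: 2.5 * x + 1}[transform]
        a = spearman_matrix(_profile(values), [f"G{j}" for j in range(8)])
        b = spearman_matrix(_profile(fn(values)), [f"G{j}" for j in range(8)])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_constant_profile_recorded_zero(self):
        prof = _profile([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.warns(UserWarning, match="constant"):
            sim = spearman_matrix(prof, prof.means.columns.tolist())
        assert sim.iloc[0, 1] == 0.0
        assert sim.iloc[0, 0] == 1.0

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            spearman_matrix(_profile([[1, 2], [2, 1]]), ["G0", "G1"])


def _block_sim(names, within=0.9, between=0.1):
    n = len(names)
    sim = np.full((n, n), between)
    for block in ({0, 1, 2}, {3, 4}, {5}):
        for i in block:
            for j in block:
                sim[i, j] = within
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=names, columns=names)


def _naming_profile(names):
    """Marker means so block 1 -> metab, block 2 -> prol, block 3 -> emt."""
    genes = ["ARG1", "ALDOB", "TOP2A", "STMN1", "MKI67", "S100A6", "S100A11"]
    rows = []
    for i in range(len(names)):
        if i <= 2:
            rows.append([3, 3, 0, 0, 0, 0, 0])
        elif i <= 4:
            rows.append([0, 0, 3, 3, 3, 0, 0])
        else:
            rows.append([0, 0, 0, 0, 0, 3, 3])
    return ClusterProfile(means=pd.DataFrame(rows, index=names, columns=genes),
                          sizes=pd.Series(1, index=names))


class TestHclusterMerge:
    def test_blocks_recovered_and_named(self):
        names = list(range(6))
        labeling = hcluster_merge(_block_sim(names), _naming_profile(names), k=3)
        assert {labeling.cluster_to_subtype[i] for i in (0, 1, 2)} == {"metab"}
        assert {labeling.cluster_to_subtype[i] for i in (3, 4)} == {"prol"}
        assert labeling.cluster_to_subtype[5] == "emt"

    def test_exhaustive_partition_oracle(self):
        """The merged partition maximizes within-group similarity over all
        3-group partitions of the 6 subclusters."""
        import itertools
        names = list(range(6))
        sim = _block_sim(names).to_numpy()
        labeling = hcluster_merge(_block_sim(names), _naming_profile(names), k=3)

        def within_score(assignment):
            total = 0.0
            for i, j in itertools.combinations(range(6), 2):
                if assignment[i] == assignment[j]:
                    total += sim[i, j]
            return total

        best = max(
            (a for a in itertools.product(range(3), repeat=6) if len(set(a)) == 3),
            key=within_score)
        ours = [labeling.cluster_to_subtype[i] for i in names]
        grouped = {s: {i for i in names if ours[i] == s} for s in set(ours)}
        oracle = {g: {i for i in names if best[i] == g} for g in set(best)}
        assert set(map(frozenset, grouped.values())) == \
            set(map(frozenset, oracle.values()))

    def test_k1_single_group(self):
        names = list(range(6))
        labeling = hcluster_merge(_block_sim(names), profiles=None, k=1)
        assert len(set(labeling.cluster_to_subtype.values())) == 1

    def test_singletons_stay_apart(self):
        sim = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        merger = TranscriptomeSimilarityMerger(n_groups=3).fit(sim)
        assert merger.group_labels_.nunique() == 3

    def test_invariant_to_cluster_permutation(self):
        names = list(range(6))
        sim = _block_sim(names)
        prof = _naming_profile(names)
        base = hcluster_merge(sim, prof, k=3).cluster_to_subtype
        perm = [3, 5, 0, 1, 4, 2]
        sim_p = sim.iloc[perm, perm]
        prof_p = ClusterProfile(means=prof.means.iloc[perm], sizes=prof.sizes.iloc[perm])
        permuted = hcluster_merge(sim_p, prof_p, k=3).cluster_to_subtype
        assert permuted == base

    def test_naming_collision_raises(self):
        names = list(range(6))
        genes = ["ARG1", "ALDOB", "TOP2A", "STMN1", "MKI67", "S100A6", "S100A11"]
        rows = [[3, 3, 0, 0, 0, 3, 3]] * 3 + [[0, 0, 3, 3, 3, 0, 0]] * 2 + \
            [[0, 0, 0, 0, 0, 0, 0]]
        prof = ClusterProfile(
            means=pd.DataFrame(rows, index=names, columns=genes),
            sizes=pd.Series(1, index=names))
        with pytest.raises(ValueError, match="collision"):
            hcluster_merge(_block_sim(names), prof, k=3)


class TestRankMarkers:
    def _expr(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(1.0, 0.1, size=(12, 30)),
                            index=[f"c{i}" for i in range(12)],
                            columns=[f"G{j}" for j in range(30)])
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=expr.index)
        expr.loc[labels == "a", "G0"] += 5.0   # exclusive high marker for a
        expr["G1"] = 2.0                        # identical means -> excluded
        return expr, labels

    def test_exclusive_gene_ranked_first(self):
        expr, labels = self._expr()
        markers = rank_markers(expr, labels, min_avg_logfc=1.0)
        assert markers["a"].index[0] == "G0"

    def test_zero_logfc_excluded(self):
        expr, labels = self._expr()
        markers = rank_markers(expr, labels, min_avg_logfc=0.0)
        assert "G1" not in markers["a"].index
        assert "G1" not in markers["b"].index

    def test_brute_force_oracle(self):
        expr, labels = self._expr()
        markers = rank_markers(expr, labels, min_avg_logfc=-10.0, n_top=30)
        mask = (labels == "a").to_numpy()
        logfc = expr[mask].mean() - expr[~mask].mean()
        expected = logfc.sort_values(ascending=False, kind="stable")
        np.testing.assert_allclose(markers["a"].to_numpy(),
                                   expected.to_numpy(), atol=1e-12)

    def test_tiny_subtype_rejected(self):
        expr = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        labels = pd.Series(["x", "y", "y"], index=expr.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_markers(expr, labels)
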