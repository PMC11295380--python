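"""Pseudo-cell aggregation, recovery-curve AUC, and regulon specificity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hccsubtypes import (RegulonAUCScorer, RegulonConfig, auc_recovery,
                         make_pseudocells, rss)
from hccsubtypes.regulons import PseudocellAggregator


def brute_force_auc(expr: pd.Series, regulon, top_fraction):
    """Position-by-position integration of the step recovery curve."""
    members = set(regulon) & set(expr.index)
    ordered = expr.sort_values(ascending=False, kind="stable").index
    window = int(np.ceil(top_fraction * len(ordered)))
    area = cum = 0
    for pos in range(window):
        if ordered[pos] in members:
            cum += 1
        area += cum
    ideal = cum_i = 0
    for pos in range(window):
        cum_i = min(pos + 1, len(members))
        ideal += cum_i
    return area / ideal


def direct_jsd(p, q, base=2.0):
    """Elementwise KL evaluation of the Jensen-Shannon divergence."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * (np.log(a[mask] / b[mask]) / np.log(base))))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestPseudocells:
    def _expr(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, 6)),
                            index=[f"c{i}" for i in range(n)],
                            columns=[f"G{j}" for j in range(6)])

    def test_identical_cells_mean_is_member(self):
        expr = pd.DataFrame(np.tile([1.0, 2.0, 3.0], (20, 1)),
                            index=[f"c{i}" for i in range(20)])
        labels = pd.Series("metab", index=expr.index)
        matrix, pc_labels = make_pseudocells(expr, labels,
                                             RegulonConfig(pseudocell_size=20))
        assert matrix.shape == (1, 3)
        np.testing.assert_allclose(matrix.iloc[0], [1.0, 2.0, 3.0])
        assert pc_labels.iloc[0] == "metab"

    def test_trailing_chunk_dropped(self):
        expr = self._expr(39)
        labels = pd.Series("emt", index=expr.index)
        matrix, _ = make_pseudocells(expr, labels, RegulonConfig(pseudocell_size=20))
        assert matrix.shape[0] == 1

    def test_group_mean_oracle(self):
        expr = self._expr(50, seed=3)
        labels = pd.Series(["a"] * 25 + ["b"] * 25, index=expr.index)
        agg = PseudocellAggregator(size=10, random_state=5)
        matrix = agg.fit_transform(expr, labels)
        assert matrix.shape[0] == 4  # two full chunks per label
        for pc_id, members in agg.members_.items():
            np.testing.assert_allclose(matrix.loc[pc_id],
                                       expr.loc[members].mean(axis=0))
        all_members = [c for m in agg.members_.values() for c in m]
        assert len(all_members) == len(set(all_members))  # disjoint chunks

    def test_short_label_warns_and_contributes_none(self):
        expr = self._expr(25)
        labels = pd.Series(["a"] * 20 + ["b"] * 5, index=expr.index)
        with pytest.warns(UserWarning, match="'b'"):
            matrix, pc_labels = make_pseudocells(expr, labels,
                                                 RegulonConfig(pseudocell_size=10))
        assert set(pc_labels) == {"a"}

    def test_nothing_aggregatable_rejected(self):
        expr = self._expr(5)
        labels = pd.Series("a", index=expr.index)
        with pytest.raises(ValueError, match="pseudocell_size"):
            with pytest.warns(UserWarning):
                make_pseudocells(expr, labels, RegulonConfig(pseudocell_size=10))


class TestAUC:
    def _vector(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.permutation(n).astype(float),
                         index=[f"G{j}" for j in range(n)])

    def test_regulon_at_top_scores_one(self):
        expr = pd.Series(np.arange(100, 0, -1, dtype=float),
                         index=[f"G{j}" for j in range(100)])
        assert auc_recovery(expr, ["G0", "G1", "G2"]) == 1.0

    def test_regulon_outside_window_scores_zero(self):
        expr = pd.Series(np.arange(100, 0, -1, dtype=float),
                         index=[f"G{j}" for j in range(100)])
        assert auc_recovery(expr, ["G98", "G99"]) == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_brute_force_step_sum_oracle(self, seed):
        expr = self._vector(seed=seed)
        rng = np.random.default_rng(seed + 100)
        regulon = [f"G{j}" for j in rng.choice(100, size=5, replace=False)]
        cfg = RegulonConfig(auc_top_fraction=0.1)
        assert auc_recovery(expr, regulon, cfg) == \
            pytest.approx(brute_force_auc(expr, regulon, 0.1))

    @given(st.integers(0, 10_000))
    def test_monotone_transform_invariance_and_bounds(self, seed):
        expr = self._vector(n=60, seed=seed)
        regulon = ["G5", "G17", "G33"]
        a = auc_recovery(expr, regulon)
        b = auc_recovery(3.0 * expr + 7.0, regulon)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            auc_recovery(self._vector(), ["ZZZ"])

    def test_scorer_transform_shape(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.random((5, 40)),
                            columns=[f"G{j}" for j in range(40)])
        regulons = {"r1": ["G0", "G1"], "r2": ["G30", "G31", "G32"]}
        auc = RegulonAUCScorer(regulons, top_fraction=0.2).transform(expr)
        assert auc.shape == (5, 2)
        assert ((auc >= 0) & (auc <= 1)).all().all()


class TestRSS:
    def test_identical_distributions_score_one(self):
        activity = pd.DataFrame({"r": [0.25, 0.25, 0.0, 0.0]},
                                index=[f"pc{i}" for i in range(4)])
        labels = pd.Series(["a", "a", "b", "b"], index=activity.index)
        out = rss(activity, labels)
        assert out.loc["r", "a"] == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        activity = pd.DataFrame({"r": [0.5, 0.5, 0.0, 0.0]},
                                index=[f"pc{i}" for i in range(4)])
        labels = pd.Series(["a", "a", "b", "b"], index=activity.index)
        out = rss(activity, labels)
        assert out.loc["r", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_jsd_oracle(self):
        rng = np.random.default_rng(8)
        activity = pd.DataFrame({"r": rng.random(6)},
                                index=[f"pc{i}" for i in range(6)])
        labels = pd.Series(["a", "a", "b", "b", "b", "a"], index=activity.index)
        out = rss(activity, labels)
        P = activity["r"].to_numpy() / activity["r"].sum()
        for subtype in ("a", "b"):
            Q = (labels == subtype).to_numpy(dtype=float)
            Q /= Q.sum()
            expected = 1.0 - np.sqrt(direct_jsd(P, Q))
            assert out.loc["r", subtype] == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        activity = pd.DataFrame(rng.random((8, 3)) * rng.integers(1, 5),
                                columns=["r1", "r2", "r3"],
                                index=[f"pc{i}" for i in range(8)])
        labels = pd.Series(rng.choice(["a", "b"], 8), index=activity.index)
        if labels.nunique() < 2:
            labels.iloc[0] = "a" if labels.iloc[1] == "b" else "b"
        out = rss(activity, labels)
        assert ((out >= 0) & (out <= 1)).all().all()

    def test_all_zero_activity_warns_zero(self):
        activity = pd.DataFrame({"r": [0.0, 0.0]}, index=["p0", "p1"])
        labels = pd.Series(["a", "b"], index=activity.index)
        with pytest.warns(UserWarning, match="all-zero"):
            out = rss(activity, labels)
        assert (out.loc["r"] == 0).all()

    def test_unlabeled_pseudocell_rejected(self):
        activity = pd.DataFrame({"r": [0.1, 0.2]}, index=["p0", "p1"])
        labels = pd.Series(["a"], index=["p0"])
        with pytest.raises(ValueError, match="label"):
            rss(activity, labels)

    def test_program_regulons_peak_in_their_subtype(self, normed_expr):
        expr, _, truth = normed_expr
        cells = truth.cell_subtype.loc[expr.index]
        pseudo, pc_labels = make_pseudocells(
            expr, cells, RegulonConfig(pseudocell_size=20, seed=1))
        auc = RegulonAUCScorer(truth.program_genes, 0.1).transform(pseudo)
        out = rss(auc, pc_labels)
        for program in ("metab", "prol", "emt"):
            assert out.loc[program].idxmax() == program
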