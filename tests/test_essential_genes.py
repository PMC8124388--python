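import numpy as np
import pandas as pd
import pytest
from scipy import stats

from luadstrat import (
    DependencyMatrix,
    ExpressionMatrix,
    bh_adjust,
    build_panel,
    call_essential,
    median_pairwise_correlation,
    paired_moderated_ttest,
)


def _dep(rows: dict) -> DependencyMatrix:
    genes = list(rows)
    width = max(len(v) for v in rows.values())
    return DependencyMatrix(
        pd.DataFrame(
            [list(v) for v in rows.values()],
            index=genes,
            columns=[f"L{i}" for i in range(width)],
        )
    )


class TestCallEssential:
    def test_three_of_four_boundary_counts_as_75_percent(self):
        dep = _dep({"G": [-1.2, -1.1, -1.05, -0.2]})
        assert call_essential(dep) == ["G"]

    def test_all_zero_scores_not_essential(self):
        assert call_essential(_dep({"G": [0, 0, 0, 0]})) == []

    def test_exactly_minus_one_fails_strict_less_than(self):
        assert call_essential(_dep({"G": [-1.0, -1.0, -1.0, -1.0]})) == []

    def test_missing_scores_excluded_from_both_counts(self):
        # 3 of 4 non-missing lines below threshold -> essential
        dep = _dep({"G": [-1.2, -1.1, -1.05, -0.2, np.nan, np.nan]})
        assert call_essential(dep) == ["G"]

    def test_all_missing_gene_excluded_without_error(self):
        dep = _dep({"A": [-2.0, -2.0], "B": [np.nan, np.nan]})
        assert call_essential(dep) == ["A"]

    def test_output_sorted_by_ascending_median_score(self):
        dep = _dep({"MILD": [-1.1, -1.2, -1.1], "STRONG": [-3.0, -2.9, -3.1]})
        assert call_essential(dep) == ["STRONG", "MILD"]

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(-1, 0.5, size=(10, 8))
        df = pd.DataFrame(vals, index=[f"G{i}" for i in range(10)],
                          columns=[f"L{i}" for i in range(8)])
        a = call_essential(DependencyMatrix(df))
        b = call_essential(DependencyMatrix(df[df.columns[::-1]]))
        assert a == b


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # min over j>=i of p_j * m / j: all collapse to 0.04
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


def _paired_data(diffs: np.ndarray, seed=0):
    """Build tumor/normal matrices whose paired differences equal ``diffs``."""
    rng = np.random.default_rng(seed)
    n_genes, n_pairs = diffs.shape
    genes = [f"G{i}" for i in range(n_genes)]
    t_ids = [f"T{i}" for i in range(n_pairs)]
    n_ids = [f"N{i}" for i in range(n_pairs)]
    base = rng.normal(5, 1, size=diffs.shape)
    tumor = ExpressionMatrix(pd.DataFrame(base + diffs, index=genes, columns=t_ids))
    normal = ExpressionMatrix(pd.DataFrame(base, index=genes, columns=n_ids))
    return tumor, normal, list(zip(t_ids, n_ids))


class TestPairedModeratedT:
    def test_all_zero_differences_give_null_gene(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0, 1, size=(20, 10))
        diffs[0] = 0.0
        tumor, normal, pairs = _paired_data(diffs)
        res = paired_moderated_ttest(tumor, normal, pairs)
        row = res.table.iloc[0]
        assert row["log2fc"] == 0 and row["t"] == 0 and row["p"] == 1

    def test_identical_variances_reduce_to_ordinary_t(self):
        """Shrinkage fixed point: equal gene variances leave t unchanged."""
        rng = np.random.default_rng(3)
        n_pairs = 8
        base = rng.normal(0, 1, size=n_pairs)
        base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, var 1
        diffs = np.stack([base * 1.0 + mu for mu in np.linspace(-1, 1, 12)])
        tumor, normal, pairs = _paired_data(diffs)
        res = paired_moderated_ttest(tumor, normal, pairs)
        ordinary = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(n_pairs))
        np.testing.assert_allclose(res.table["t"], ordinary, rtol=1e-8)

    def test_non_bijective_pairing_rejected(self):
        tumor, normal, pairs = _paired_data(np.zeros((3, 4)))
        bad = pairs + [pairs[0]]
        with pytest.raises(ValueError, match="bijection"):
            paired_moderated_ttest(tumor, normal, bad)

    def test_planted_fold_changes_recovered(self):
        """Planted 1.5 log2FC at sd 0.3 over 50 pairs reaches q<0.01; noise does not."""
        rng = np.random.default_rng(4)
        n_planted, n_bg, n_pairs = 20, 400, 50
        diffs = rng.normal(0, 0.3, size=(n_planted + n_bg, n_pairs))
        diffs[:n_planted] += 1.5
        tumor, normal, pairs = _paired_data(diffs)
        res = paired_moderated_ttest(tumor, normal, pairs)
        planted = res.table.iloc[:n_planted]
        background = res.table.iloc[n_planted:]
        assert (planted["q"] < 0.01).all()
        assert (planted["log2fc"] > 1).all()
        assert (background["q"] < 0.01).mean() <= 0.02

    def test_null_pvalues_uniform(self):
        """Global null: moderated-t p-values pass a KS uniformity check."""
        rng = np.random.default_rng(5)
        diffs = rng.normal(0, 1, size=(2000, 30))
        tumor, normal, pairs = _paired_data(diffs)
        res = paired_moderated_ttest(tumor, normal, pairs)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01


class TestBuildPanel:
    def _deg(self, rows):
        t = pd.DataFrame(rows, index=["q", "log2fc"]).T
        t["t"] = 0.0
        t["p"] = t["q"]
        t["n_pairs"] = 10
        from luadstrat.essential_genes import DEGResult

        return DEGResult(table=t, prior_df=1.0, prior_var=1.0)

    def test_intersection_requires_every_cohort(self):
        deg1 = self._deg({"A": [0.001, 2.0], "B": [0.001, 2.0]})
        deg2 = self._deg({"A": [0.001, 2.0], "B": [0.5, 2.0]})
        panel = build_panel(["A", "B"], [deg1, deg2])
        assert panel.genes == ["A"]

    def test_strict_thresholds(self):
        # q exactly at q_max and log2fc exactly at minimum both fail
        deg = self._deg({"A": [0.01, 2.0], "B": [0.001, 1.0], "C": [0.001, 1.01]})
        panel = build_panel(["A", "B", "C"], [deg])
        assert panel.genes == ["C"]

    def test_degenerate_thresholds_recover_all_tested(self):
        deg = self._deg({"A": [0.9, -3.0], "B": [0.5, 0.0]})
        panel = build_panel(["A", "B", "Z"], [deg], q_max=1.01, log2fc_min=-np.inf)
        assert panel.genes == ["A", "B"]

    def test_empty_intersection_warns_not_raises(self):
        deg = self._deg({"A": [0.9, 0.0]})
        panel = build_panel(["A"], [deg])
        assert panel.genes == []


class TestMedianPairwiseCorrelation:
    def test_identical_genes_give_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame([x, x], index=["A", "B"], columns=[f"S{i}" for i in range(10)])
        assert median_pairwise_correlation(ExpressionMatrix(df), ["A", "B"]) == pytest.approx(1.0)

    def test_anticorrelated_genes_give_minus_one(self):
        x = np.arange(10.0)
        df = pd.DataFrame([x, -x], index=["A", "B"], columns=[f"S{i}" for i in range(10)])
        assert median_pairwise_correlation(ExpressionMatrix(df), ["A", "B"]) == pytest.approx(-1.0)

    def test_absent_gene_excluded_with_warning(self, tiny_expr):
        val = median_pairwise_correlation(tiny_expr, ["G0", "G1", "MISSING"])
        assert -1 <= val <= 1

    def test_requires_two_present_genes(self, tiny_expr):
        with pytest.raises(ValueError):
            median_pairwise_correlation(tiny_expr, ["G0", "MISSING"])
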