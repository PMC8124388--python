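import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from luadstrat import (
    DrugResponseTable,
    MutationTable,
    adjusted_linear_model,
    binarize_stage,
    compute_tmb,
    drug_response_compare,
    fisher_enrichment,
    kruskal_dunn,
    logistic_stage_model,
    screen_activities,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (fractions)."""
    from fractions import Fraction

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(x):
        return Fraction(
            math.comb(c1, x) * math.comb(n - c1, r1 - x), math.comb(n, r1)
        )

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs:
            total += px
    return float(total)


def _series(values, prefix="S"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestKruskalDunn:
    def test_hand_computed_h(self):
        v = _series([1, 2, 3, 4, 5, 6, 7, 8, 9])
        g = _series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = kruskal_dunn(v, g)
        assert res.h_statistic == pytest.approx(7.2)

    def test_identical_groups_are_null(self):
        v = _series([1.0, 2.0, 3.0] * 3)
        g = _series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = kruskal_dunn(v, g)
        # same values in every group: mean ranks equal, z = 0
        np.testing.assert_allclose(res.dunn["z"], 0.0, atol=1e-12)

    def test_constant_values_give_h_zero(self):
        v = _series([5.0] * 6)
        g = _series(["a"] * 3 + ["b"] * 3)
        res = kruskal_dunn(v, g)
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_two_groups_match_rank_sum_z_squared(self):
        rng = np.random.default_rng(0)
        v = _series(rng.normal(size=20))  # continuous, tie-free
        g = _series(["a"] * 10 + ["b"] * 10)
        res = kruskal_dunn(v, g)
        z = res.dunn["z"].iloc[0]
        assert z**2 == pytest.approx(res.h_statistic, rel=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        v = _series(rng.normal(size=30))
        g = _series(rng.choice(["a", "b", "c"], size=30))
        h1 = kruskal_dunn(v, g).h_statistic
        h2 = kruskal_dunn(np.exp(v), g).h_statistic
        assert h1 == pytest.approx(h2)

    def test_empty_group_after_missing_removal_is_error(self):
        v = _series([1.0, 2.0, np.nan, np.nan])
        g = _series(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="b"):
            kruskal_dunn(v, g)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        v = _series(np.concatenate([rng.normal(size=10), rng.normal(3, 1, 10),
                                    rng.normal(6, 1, 10)]))
        g = _series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        res = kruskal_dunn(v, g, holm=True)
        assert (res.dunn["p_holm"] >= res.dunn["p"] - 1e-15).all()


class TestFisher:
    def test_reference_table(self):
        x = _series([True] * 4 + [False] * 4)
        y = _series([True, True, True, False, True, False, False, False])
        res = fisher_enrichment(x, y)
        np.testing.assert_array_equal(res.table, [[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(0.485714285, abs=1e-6)
        assert res.odds_ratio == pytest.approx(9.0)

    def test_balanced_table_is_null(self):
        x = _series([True] * 10 + [False] * 10)
        y = _series(([True] * 5 + [False] * 5) * 2)
        res = fisher_enrichment(x, y)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_gives_flagged_infinite_or(self):
        x = _series([True] * 3 + [False] * 3)
        y = _series([True, True, True, False, False, False])
        res = fisher_enrichment(x, y)
        assert res.zero_cell and np.isinf(res.odds_ratio)
        assert 0 < res.p_value <= 1

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b + c + d == 0:
                continue
            x = _series([True] * (a + b) + [False] * (c + d))
            y = _series([True] * a + [False] * b + [True] * c + [False] * d)
            res = fisher_enrichment(x, y)
            assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)


class TestLogisticStage:
    def test_identical_split_gives_zero_log_odds(self):
        clusters = _series([1] * 20 + [3] * 20)
        stage = _series(([1] * 10 + [0] * 10) * 2)
        out = logistic_stage_model(clusters, stage, reference=3)
        assert out["log_odds"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_by_two_closed_form(self):
        # 20/10 high/low in cluster 1 vs 10/20 in cluster 3 -> log OR = ln 4
        clusters = _series([1] * 30 + [3] * 30)
        stage = _series([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
        out = logistic_stage_model(clusters, stage, reference=3)
        assert out.loc["cluster_1_vs_3", "log_odds"] == pytest.approx(
            math.log(4), abs=1e-4
        )

    def test_missing_reference_cluster_rejected(self):
        clusters = _series([1] * 10 + [2] * 10)
        stage = _series([0, 1] * 10)
        with pytest.raises(ValueError, match="reference"):
            logistic_stage_model(clusters, stage, reference=3)


class TestBinarizeStage:
    def test_standard_split(self):
        s = _series(["I", "IIB", "IIIA", "IV"])
        assert list(binarize_stage(s)) == [0, 0, 1, 1]

    def test_low_stage_cohort_falls_back_to_ii_vs_i(self):
        s = _series(["I", "IA", "II", "IIB"])
        assert list(binarize_stage(s)) == [0, 0, 1, 1]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="X9"):
            binarize_stage(_series(["I", "X9"]))


class TestAdjustedLinearModel:
    def test_cluster_effect_robust_to_stage(self):
        rng = np.random.default_rng(4)
        n = 300
        clusters = _series(rng.choice([1, 2, 3], size=n))
        stage = _series(rng.integers(0, 2, size=n))
        activity = _series(
            (clusters == 1) * 1.0 + rng.normal(0, 0.3, n) + 0.0 * stage
        )
        out = adjusted_linear_model(activity, clusters, stage, reference=3)
        assert out.loc["cluster_1_vs_3", "coef"] == pytest.approx(1.0, abs=0.15)

    def test_confounded_activity_absorbed_by_stage(self):
        rng = np.random.default_rng(5)
        n = 200
        clusters = _series(rng.choice([1, 2, 3], size=n))
        stage = _series(rng.integers(0, 2, size=n))
        activity = stage.astype(float)
        out = adjusted_linear_model(activity, clusters, stage, reference=3)
        assert abs(out.loc["cluster_1_vs_3", "coef"]) < 1e-8
        assert out.loc["stage_high", "coef"] == pytest.approx(1.0)

    def test_zero_variance_activity_returns_null_fit(self):
        clusters = _series([1, 1, 2, 2, 3, 3])
        stage = _series([0, 1, 0, 1, 0, 1])
        activity = _series([2.0] * 6)
        out = adjusted_linear_model(activity, clusters, stage, reference=3)
        assert (out["coef"] == 0).all()
        assert (out["p"] == 1).all()


class TestTmb:
    def _table(self, rows):
        return MutationTable(
            pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])
        )

    def test_count_over_exome_length(self):
        rows = [("P1", f"G{i}", "non_silent") for i in range(76)]
        res = compute_tmb(self._table(rows), ["P1"])
        assert res.table.loc["P1", "tmb"] == pytest.approx(2.0)
        assert res.table.loc["P1", "tmb"] * res.exome_mb == res.table.loc["P1", "n_non_silent"]

    def test_silent_records_excluded(self):
        rows = [("P1", f"G{i}", "non_silent") for i in range(38)]
        rows += [("P1", f"G{i}", "silent") for i in range(5)]
        res = compute_tmb(self._table(rows), ["P1"])
        assert res.table.loc["P1", "tmb"] == pytest.approx(1.0)

    def test_sample_without_records_gets_zero(self):
        res = compute_tmb(self._table([("P1", "G1", "non_silent")]), ["P1", "P2"])
        assert res.table.loc["P2", "tmb"] == 0.0

    def test_additive_over_concatenated_tables(self):
        t1 = self._table([("P1", "G1", "non_silent")] * 3)
        t2 = self._table([("P1", "G2", "non_silent")] * 4)
        merged = t1.concat(t2)
        a = compute_tmb(t1, ["P1"]).table.loc["P1", "n_non_silent"]
        b = compute_tmb(t2, ["P1"]).table.loc["P1", "n_non_silent"]
        m = compute_tmb(merged, ["P1"]).table.loc["P1", "n_non_silent"]
        assert m == a + b


class TestDrugCompare:
    def _drugs(self, data, lines):
        return DrugResponseTable(
            pd.DataFrame(data, index=[f"D{i}" for i in range(len(data))], columns=lines)
        )

    def test_under_tested_compound_excluded(self):
        lines = [f"L{i}" for i in range(10)]
        labels = pd.Series([1] * 5 + [2] * 5, index=lines)
        row_ok = list(np.linspace(0.2, 0.9, 10))
        row_under = row_ok.copy()
        for i in range(3):  # 70% tested < 75% threshold
            row_under[i] = np.nan
        out = drug_response_compare(self._drugs([row_ok, row_under], lines), labels)
        assert list(out["compound"]) == ["D0"]

    def test_all_missing_compound_excluded(self):
        lines = [f"L{i}" for i in range(8)]
        labels = pd.Series([1] * 4 + [2] * 4, index=lines)
        out = drug_response_compare(
            self._drugs([[np.nan] * 8, list(np.linspace(0.1, 0.8, 8))], lines), labels
        )
        assert list(out["compound"]) == ["D1"]

    def test_planted_sensitive_compound_found(self):
        from luadstrat import simulate_drug_response

        rng = np.random.default_rng(6)
        labels = pd.Series(rng.choice([1, 2, 3], size=46),
                           index=[f"L{i}" for i in range(46)])
        drugs = simulate_drug_response(labels, n_compounds=12, n_sensitive=2,
                                       effect=0.3, seed=7)
        out = drug_response_compare(drugs, labels)
        top2 = set(out.head(2)["compound"])
        assert top2 == {"DRUG000", "DRUG001"}
        assert out.head(2)["significant"].all()
        assert (out.head(2)["lowest_median_cluster"] == 1).all()


class TestScreenActivities:
    def test_keep_all_when_threshold_above_one(self, small_cohort):
        rng = np.random.default_rng(8)
        acts = pd.DataFrame(
            rng.normal(size=(5, len(small_cohort.true_labels))),
            index=[f"SIG{i}" for i in range(5)],
            columns=small_cohort.true_labels.index,
        )
        kept = screen_activities(acts, small_cohort.true_labels, p_max=1.01)
        assert len(kept) == 5

    def test_driven_signature_kept_null_mostly_dropped(self, small_cohort):
        labels = small_cohort.true_labels
        rng = np.random.default_rng(9)
        driven = (labels == 1) * 1.0 + rng.normal(0, 0.3, len(labels))
        noise = pd.DataFrame(
            rng.normal(size=(20, len(labels))),
            index=[f"N{i}" for i in range(20)], columns=labels.index,
        )
        acts = pd.concat([pd.DataFrame({"DRIVEN": driven}).T, noise])
        kept = screen_activities(acts, labels, p_max=1e-3)
        names = [r.feature for r in kept]
        assert "DRIVEN" in names
        assert len(names) <= 3
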