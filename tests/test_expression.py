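import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from tracekin import expression as ex
from tracekin.synthetic_data import CountSimConfig, simulate_counts


def small_matrix():
    counts = pd.DataFrame(
        {
            "s1": [10, 5, 3, 100, 7],
            "s2": [20, 10, 6, 200, 14],
        },
        index=["FCGR2A", "FCGR2B", "FCGR2C", "ACTB", "CD3E"],
    )
    lengths = pd.Series([4.0, 3.0, 3.0, 2.0, 1.0], index=counts.index)
    return ex.CountMatrix(counts, lengths, {"s1": "A", "s2": "B"})


class TestCountMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="unique"):
            ex.CountMatrix(
                pd.DataFrame([[1], [2]], index=["g", "g"], columns=["s"]),
                pd.Series([1.0, 1.0], index=["g", "g"]),
            )
        with pytest.raises(ValueError, match="positive"):
            ex.CountMatrix(
                pd.DataFrame([[1]], index=["g"], columns=["s"]),
                pd.Series([0.0], index=["g"]),
            )

    def test_tsv_round_trip(self, tmp_path):
        m = small_matrix()
        m.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        m.gene_lengths.rename("length_kb").to_csv(tmp_path / "lengths.tsv", sep="\t")
        back = ex.CountMatrix.from_tsv(tmp_path / "counts.tsv", tmp_path / "lengths.tsv")
        pd.testing.assert_frame_equal(back.counts, m.counts)


class TestGroupParalogs:
    def test_counts_and_lengths_sum(self):
        grouped = ex.group_paralogs(small_matrix(), {"FCGR2": ["FCGR2A", "FCGR2B", "FCGR2C"]})
        assert grouped.counts.loc["FCGR2", "s1"] == 18
        assert grouped.gene_lengths["FCGR2"] == pytest.approx(10.0)
        assert "FCGR2A" not in grouped.genes

    def test_missing_member_not_fatal(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="tracekin.expression"):
            grouped = ex.group_paralogs(small_matrix(), {"FCGR3": ["FCGR3A", "FCGR3B"]})
        assert "FCGR3" not in grouped.genes  # no members present
        assert any("not found" in r.message for r in caplog.records)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ex.group_paralogs(small_matrix(), {"X": ["FCGR2A"], "Y": ["FCGR2A", "ACTB"]})

    def test_commutes_with_tpm(self):
        m = small_matrix()
        groups = {"FCGR2": ["FCGR2A", "FCGR2B", "FCGR2C"]}
        via_group = ex.tpm(ex.group_paralogs(m, groups))
        # pre-summed fixture built by hand
        counts = pd.DataFrame(
            {"s1": [100, 7, 18], "s2": [200, 14, 36]}, index=["ACTB", "CD3E", "FCGR2"]
        )
        lengths = pd.Series([2.0, 1.0, 10.0], index=counts.index)
        direct = ex.tpm(ex.CountMatrix(counts, lengths))
        pd.testing.assert_frame_equal(
            via_group.sort_index(), direct.sort_index(), atol=1e-9
        )

    def test_commutes_with_normalized_per_kb(self):
        m = small_matrix()
        groups = {"FCGR2": ["FCGR2A", "FCGR2B", "FCGR2C"]}
        factors = pd.Series([1.0, 2.0], index=["s1", "s2"])
        grouped = ex.group_paralogs(m, groups)
        value = ex.normalized_per_kb(grouped, factors).loc["FCGR2"]
        expected = (m.counts.loc[["FCGR2A", "FCGR2B", "FCGR2C"]].sum() / factors) / 10.0
        np.testing.assert_allclose(value, expected, rtol=1e-12)


class TestSizeFactors:
    def test_identical_columns(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=list("xyz"))
        sf = ex.size_factors(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
        sf = ex.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_geometric_mean_near_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(200, 6)) + 1,
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(6)],
        )
        sf = ex.size_factors(counts)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=0.05)

    def test_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(100, size=(20, 4)) + 1
        counts = pd.DataFrame(arr, index=[f"g{i}" for i in range(20)],
                              columns=list("abcd"))
        sf = ex.size_factors(counts)
        geo = np.exp(np.log(arr).mean(axis=1))
        for j, s in enumerate("abcd"):
            assert sf[s] == pytest.approx(np.median(arr[:, j] / geo), rel=1e-12)

    def test_no_common_gene_error_and_pseudo_reference(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="pseudo"):
            ex.size_factors(counts)
        sf = ex.size_factors(counts, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestNormalization:
    def test_normalized_per_kb_hand_value(self):
        counts = pd.DataFrame({"s": [100]}, index=["g"])
        m = ex.CountMatrix(counts, pd.Series([2.0], index=["g"]))
        out = ex.normalized_per_kb(m, pd.Series([1.0], index=["s"]))
        assert out.loc["g", "s"] == pytest.approx(50.0)
        out2 = ex.normalized_per_kb(m, pd.Series([2.0], index=["s"]))
        assert out2.loc["g", "s"] == pytest.approx(25.0)

    def test_tpm_hand_fixture(self):
        counts = pd.DataFrame({"s": [10, 90]}, index=["g1", "g2"])
        m = ex.CountMatrix(counts, pd.Series([1.0, 3.0], index=counts.index))
        out = ex.tpm(m)
        np.testing.assert_allclose(out["s"], [250_000.0, 750_000.0])

    def test_tpm_single_gene(self):
        m = ex.CountMatrix(pd.DataFrame({"s": [7]}, index=["g"]), pd.Series([2.0], index=["g"]))
        assert ex.tpm(m).loc["g", "s"] == pytest.approx(1e6)

    def test_tpm_columns_sum_to_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(30, size=(100, 5)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(5)],
        )
        m = ex.CountMatrix(counts, pd.Series(rng.uniform(0.5, 5, 100), index=counts.index))
        np.testing.assert_allclose(ex.tpm(m).sum(axis=0), 1e6, atol=1e-3)

    def test_tpm_equal_lengths_proportional_to_counts(self):
        counts = pd.DataFrame({"s": [10, 30, 60]}, index=list("abc"))
        m = ex.CountMatrix(counts, pd.Series([2.0, 2.0, 2.0], index=counts.index))
        np.testing.assert_allclose(ex.tpm(m)["s"], [1e5, 3e5, 6e5])

    def test_tpm_zero_column_warns(self, caplog):
        import logging

        counts = pd.DataFrame({"s": [0, 0]}, index=["a", "b"])
        m = ex.CountMatrix(counts, pd.Series([1.0, 1.0], index=counts.index))
        with caplog.at_level(logging.WARNING, logger="tracekin.expression"):
            out = ex.tpm(m)
        assert (out["s"] == 0).all()
        assert any("all-zero" in r.message for r in caplog.records)


class TestExpressionCalls:
    def make_tpm(self, values):
        return pd.DataFrame({"s1": values, "s2": values},
                            index=[f"g{i}" for i in range(len(values))])

    def test_threshold_classes(self):
        t = self.make_tpm([1.3, 0.6, 0.3, 0.1])
        calls = ex.expression_calls(t, {"sub": ["s1", "s2"]})
        assert calls["call"].tolist() == ["expressed", "very_low", "below_ranking", "absent"]
        assert calls["basal_flag"].tolist() == [True, False, False, False]

    def test_inclusive_boundaries(self):
        t = self.make_tpm([1.0, 0.5, 0.25, 1.2])
        calls = ex.expression_calls(t, {"sub": ["s1", "s2"]})
        assert calls["call"].tolist() == [
            "expressed", "very_low", "below_ranking", "expressed",
        ]
        assert calls["basal_flag"].tolist() == [False, False, False, True]

    def test_basal_any_subset(self):
        t = pd.DataFrame({"a": [1.3], "b": [0.2]}, index=["g"])
        calls = ex.expression_calls(t, {"hi": ["a"], "lo": ["b"]})
        assert calls["basal_flag"].all()  # flagged in both rows (any-subset rule)
        lo = calls[calls["subset"] == "lo"].iloc[0]
        assert lo["call"] == "absent"

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ex.expression_calls(self.make_tpm([1.0]), {"sub": []})


class TestBH:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 100)
        np.testing.assert_allclose(
            ex.bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_idempotent_monotone(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 50)
        adj = ex.bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        np.testing.assert_allclose(ex.bh_adjust(adj), adj, atol=1e-12)


class TestDEG:
    def test_rule_classes(self):
        table = pd.DataFrame(
            {
                "log2_fold_change": [np.log2(1.6), np.log2(1.4), -np.log2(2.0), 0.1, -0.2],
                "p_raw": [0.001, 0.02, 0.001, 0.5, 0.09],
                "p_adjusted": [0.04, 0.04, 0.01, 0.9, 0.2],
            },
            index=list("abcde"),
        )
        out = ex.deg_classify(table)
        assert out["class"].tolist() == [
            "DEG_up",      # padj<0.05 and FC>=1.5
            "up_trend",    # padj<0.05 but FC<1.5 -> trend via p<0.10
            "DEG_down",    # down direction
            "ns",
            "down_trend",  # nominal p<0.10
        ]

    def test_builtin_requires_replicates(self):
        counts = pd.DataFrame({"a": [10], "b": [12]}, index=["g"])
        m = ex.CountMatrix(counts, pd.Series([1.0], index=["g"]),
                           {"a": "A", "b": "B"})
        with pytest.raises(ValueError, match="external"):
            ex.deg_classify(matrix=m, group_a="A", group_b="B")

    def test_synthetic_benchmark_fdr_and_sensitivity(self):
        cfg = CountSimConfig(
            n_genes=2000, group_sizes=(4, 4), de_fraction=0.10,
            fold_change=4.0, dispersion=0.1, seed=2024,
        )
        matrix, truth = simulate_counts(cfg)
        out = ex.deg_classify(matrix=matrix, group_a="A", group_b="B")
        called = out.index[out["class"].isin(["DEG_up", "DEG_down"])]
        true_de = set(truth.index[truth["is_de"]])
        fdr = np.mean([g not in true_de for g in called]) if len(called) else 0.0
        sensitivity = len(set(called) & true_de) / len(true_de)
        assert fdr <= 0.10
        assert sensitivity >= 0.6

    def test_direction_agrees_with_truth(self):
        cfg = CountSimConfig(
            n_genes=500, group_sizes=(4, 4), de_fraction=0.2,
            fold_change=6.0, dispersion=0.05, seed=7,
        )
        matrix, truth = simulate_counts(cfg)
        out = ex.deg_classify(matrix=matrix, group_a="A", group_b="B")
        up_truth = truth.index[truth["true_fold_change"] > 1]
        called_up = out.loc[out["class"] == "DEG_up"].index
        overlap = set(called_up) & set(up_truth)
        assert len(overlap) / max(len(called_up), 1) > 0.9


class TestScCpm:
    def test_hand_value(self):
        counts = pd.DataFrame(
            {"cell1": [3, 2, 9995]}, index=["FCGR2A", "FCGR2B", "OTHER"]
        )
        out = ex.sc_cpm(counts, {"FCGR2": ["FCGR2A", "FCGR2B", "FCGR2C"]})
        assert out.loc["cell1", "FCGR2"] == pytest.approx(500.0)

    def test_zero_group(self):
        counts = pd.DataFrame({"c": [100]}, index=["OTHER"])
        out = ex.sc_cpm(counts, {"FCGR3": ["FCGR3A"]})
        assert out.loc["c", "FCGR3"] == 0.0

    def test_zero_total_cells_dropped(self, caplog):
        import logging

        counts = pd.DataFrame({"c1": [10], "c2": [0]}, index=["g"])
        with caplog.at_level(logging.WARNING, logger="tracekin.expression"):
            out = ex.sc_cpm(counts, {"G": ["g"]})
        assert list(out.index) == ["c1"]

    def test_grouping_order_invariance(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(20, size=(6, 10)),
            index=["A", "B", "C", "D", "E", "F"],
            columns=[f"c{i}" for i in range(10)],
        ) + 1
        g1 = ex.sc_cpm(counts, {"S": ["A", "B", "C"]})
        g2 = ex.sc_cpm(counts, {"S": ["C", "A", "B"]})
        pd.testing.assert_frame_equal(g1, g2)

    def test_cpm_sums_to_million(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.poisson(40, size=(5, 4)) + 1,
            index=list("abcde"), columns=[f"c{i}" for i in range(4)],
        )
        out = ex.sc_cpm(counts, {"all": list("abcde")})
        np.testing.assert_allclose(out["all"], 1e6, atol=1e-3)
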