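import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import txrescue as tx
from txrescue import DataError, recovery


def classify_oracle(pct, lo=10.0, mid=50.0, hi=150.0):
    """Recovery bins by direct interval arithmetic."""
    if np.isnan(pct):
        return "undefined"
    if pct < lo:
        return "unrecovered"
    if lo <= pct < mid:
        return "partial"
    if mid <= pct <= hi:
        return "total"
    return "over"


class TestPercentRecovery:
    @pytest.mark.parametrize(
        "control,disease,treated,expected",
        [
            (200.0, 100.0, 100.0, 0.0),     # treated == disease
            (200.0, 100.0, 200.0, 100.0),   # treated == control
            (200.0, 100.0, 180.0, 80.0),
            (100.0, 200.0, 150.0, 50.0),    # down-regulated disease gene
            (100.0, 200.0, 260.0, -60.0),   # moved further from control
        ],
    )
    def test_direct_arithmetic(self, control, disease, treated, expected):
        assert recovery.percent_recovery(control, disease, treated) == pytest.approx(expected)

    def test_guard_yields_undefined_not_exception(self):
        assert np.isnan(recovery.percent_recovery(100.0, 100.5, 140.0))

    def test_negative_means_rejected(self):
        with pytest.raises(DataError):
            recovery.percent_recovery(-1.0, 5.0, 5.0)

    @given(k=st.floats(min_value=0.01, max_value=1e3))
    @settings(derandomize=True, max_examples=50)
    def test_affine_invariance_under_rescaling(self, k):
        base = recovery.percent_recovery(200.0, 100.0, 180.0)
        # eps guard scales with the data, so shrink it along with the means
        scaled = recovery.percent_recovery(200.0 * k, 100.0 * k, 180.0 * k, eps=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestClassifyRecovery:
    @pytest.mark.parametrize(
        "pct,expected",
        [(5.0, "unrecovered"), (80.0, "total"), (-30.0, "unrecovered"),
         (10.0, "partial"), (49.999, "partial"), (50.0, "total"),
         (150.0, "total"), (150.0001, "over"), (float("nan"), "undefined")],
    )
    def test_bin_boundaries(self, pct, expected):
        assert recovery.classify_recovery(pct) == expected

    @given(pct=st.floats(min_value=-200, max_value=300, allow_nan=False))
    @settings(derandomize=True, max_examples=300)
    def test_matches_interval_oracle_and_partitions_reals(self, pct):
        category = recovery.classify_recovery(pct)
        assert category == classify_oracle(pct)
        assert category in recovery.CATEGORIES


class TestRecoveryTable:
    def test_uses_normalized_group_means(self):
        norm = pd.DataFrame(
            {
                "c1": [200.0, 10.0], "c2": [200.0, 10.0],
                "d1": [100.0, 10.0], "d2": [100.0, 10.0],
                "t1": [180.0, 10.0], "t2": [180.0, 10.0],
            },
            index=pd.Index(["gA", "gB"], name="gene"),
        )
        design = pd.Series(
            ["CNT", "CNT", "DM1", "DM1", "T", "T"], index=norm.columns
        )
        table = recovery.recovery_table(norm, design, "CNT", "DM1", "T")
        assert table.loc["gA", "pct_recovery"] == pytest.approx(80.0)
        assert table.loc["gA", "category"] == "total"
        # control == disease trips the guard
        assert np.isnan(table.loc["gB", "pct_recovery"])
        assert table.loc["gB", "category"] == "undefined"

    def test_unknown_gene_rejected(self, small_cohort):
        _, matrix, _ = small_cohort
        _, norm = tx.normalize_counts(matrix)
        with pytest.raises(DataError, match="absent"):
            recovery.recovery_table(
                norm, matrix.design, "CNT", "DM1", "DM1_BlockmiR", genes=["nope"]
            )


class TestReversals:
    def _dge(self, genes, log2fc, padj):
        return pd.DataFrame(
            {"log2fc": log2fc, "padj": padj}, index=pd.Index(genes, name="gene")
        )

    def test_opposing_altered_gene_is_a_reversal(self):
        disease = recovery.disease_related_genes(
            self._dge(["g1", "g2"], [2.0, 2.0], [0.001, 0.001])
        )
        trt = self._dge(["g1", "g2"], [-1.5, 1.5], [0.001, 0.001])
        flags, summary = recovery.reversal_calls(disease, trt)
        assert bool(flags.loc["g1", "reversal"])       # down after up-in-disease
        assert not bool(flags.loc["g2", "reversal"])   # pushed further up
        assert summary["n_reversals"] == 1
        assert summary["reversal_fraction_pct"] == pytest.approx(50.0)

    def test_missing_genes_reported_not_dropped(self):
        disease = recovery.disease_related_genes(self._dge(["g1", "g2"], [2.0, -2.0], [0.001, 0.001]))
        trt = self._dge(["g1"], [-1.5], [0.001])
        _, summary = recovery.reversal_calls(disease, trt)
        assert summary["missing_genes"] == ["g2"]


class TestIntersectionRatio:
    def test_basic_cases(self):
        assert recovery.intersection_ratio({1, 2}, {1, 2}) == 1.0
        assert recovery.intersection_ratio({1}, {2}) == 0.0
        a = set(range(125))
        b = set(range(75, 200))
        assert recovery.intersection_ratio(a, b) == pytest.approx(50 / 200)

    def test_symmetry(self):
        a, b = {1, 2, 3}, {3, 4}
        assert recovery.intersection_ratio(a, b) == recovery.intersection_ratio(b, a)

    def test_empty_sets_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert recovery.intersection_ratio(set(), set()) == 0.0


class TestRecoverySummary:
    def _table(self, cats):
        genes = [f"g{i}" for i in range(len(cats))]
        return pd.DataFrame(
            {"category": cats, "pct_recovery": [80.0] * len(cats)},
            index=pd.Index(genes, name="gene"),
        )

    def test_single_gene_total(self):
        summary = recovery.recovery_summary({"arm": self._table(["total"])})
        assert summary["arms"]["arm"]["category_counts"] == {
            "unrecovered": 0, "partial": 0, "total": 1, "over": 0
        }

    def test_identical_arms_intersect_fully(self):
        t = self._table(["total", "partial", "unrecovered", "undefined"])
        summary = recovery.recovery_summary({"a": t, "b": t.copy()})
        pair = summary["pairs"]["a|b"]
        assert pair["recovered_intersection_ratio"] == 1.0
        assert pair["per_category_intersection_ratio"]["total"] == 1.0
        assert summary["arms"]["a"]["n_undefined"] == 1

    def test_mismatched_universes_rejected(self):
        t1, t2 = self._table(["total"]), self._table(["total", "over"])
        with pytest.raises(DataError, match="universe"):
            recovery.recovery_summary({"a": t1, "b": t2})


class TestHardTargets:
    def _dge(self, genes, log2fc, padj):
        return pd.DataFrame(
            {"log2fc": log2fc, "padj": padj}, index=pd.Index(genes, name="gene")
        )

    def test_counts_and_missing_targets(self):
        dges = {
            "block": self._dge(["t1", "t2", "x"], [0.1, 0.2, 3.0], [0.9, 0.8, 0.001]),
            "antago": self._dge(["t1", "t2", "x"], [2.0, -1.5, 3.0], [0.01, 0.02, 0.001]),
        }
        report = recovery.hard_target_report(dges, ["t1", "t2", "t_missing"])
        assert report["altered_counts"] == {"block": 0, "antago": 2}
        assert report["missing"] == ["t_missing"]
        assert report["n_present"] == 2

    def test_empty_intersection_rejected(self):
        dges = {"c": self._dge(["g1"], [0.0], [1.0])}
        with pytest.raises(DataError, match="no hard target"):
            recovery.hard_target_report(dges, ["absent"])

    def test_target_list_reader(self, tmp_path):
        path = tmp_path / "targets.txt"
        path.write_text("# miR-23b hard targets\nGeneA\n\nGeneB\n")
        assert recovery.read_target_list(path) == ["GeneA", "GeneB"]
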