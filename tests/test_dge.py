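import math
import statistics

import numpy as np
import pandas as pd
import pytest

import txrescue as tx
from txrescue import DataError, dge


# ------------------------------------------------------------------ oracles
def brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios recomputed with plain Python loops."""
    vals = counts.to_numpy(float)
    per_sample = [[] for _ in range(vals.shape[1])]
    for row in vals:
        if all(v > 0 for v in row):
            geo = math.exp(sum(math.log(v) for v in row) / len(row))
            for j, v in enumerate(row):
                per_sample[j].append(v / geo)
    sf = np.array([statistics.median(r) for r in per_sample])
    return sf / math.exp(np.mean(np.log(sf)))


def bh_step_up(pvalues):
    """Benjamini-Hochberg by direct step-up enumeration."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    previous = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        value = min(previous, p[i] * n / rank)
        adjusted[i] = value
        previous = value
    return adjusted


# ------------------------------------------------------------- size factors
class TestSizeFactors:
    def test_doubled_sample_doubles_its_factor(self, rng):
        base = rng.poisson(100, size=(200, 1))
        counts = pd.DataFrame(
            np.hstack([base, 2 * base, base]), columns=["a", "b", "c"]
        )
        sf = dge.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert sf["c"] / sf["a"] == pytest.approx(1.0)

    def test_identical_samples_share_one_factor(self, rng):
        col = rng.poisson(50, size=100)
        counts = pd.DataFrame({s: col for s in "abcd"})
        sf = dge.size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.1, size=(50, 4)), columns=list("abcd")
        )
        expected = brute_force_size_factors(counts)
        assert np.allclose(dge.size_factors(counts).to_numpy(), expected)

    def test_fallback_equals_total_count_ratios(self):
        # no gene positive in every sample -> total-count fallback
        counts = pd.DataFrame({"a": [10, 0, 30], "b": [0, 40, 0]})
        sf = dge.size_factors(counts)
        totals = counts.sum().to_numpy(float)
        expected = totals / math.exp(np.mean(np.log(totals)))
        assert np.allclose(sf.to_numpy(), expected)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DataError, match="all-zero"):
            dge.size_factors(pd.DataFrame(np.zeros((5, 3))))


# --------------------------------------------------------------- dispersion
class TestDispersion:
    def test_poisson_data_gives_near_zero_dispersion(self, rng):
        counts = pd.DataFrame(
            rng.poisson(200, size=(300, 20)),
            columns=[f"s{i}" for i in range(20)],
        )
        design = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.columns)
        disp = dge.estimate_dispersion(tx.CountMatrix(counts, design))
        assert float(disp.median()) < 0.02

    def test_recovers_known_dispersion(self):
        cfg = tx.SimConfig(
            n_genes=1000, frac_disease_genes=0.0, dispersion=0.2, arms=(),
            n_hard_targets=0, seed=3,
        )
        matrix, _ = tx.generate_counts(cfg)
        disp = dge.estimate_dispersion(matrix)
        assert 0.15 <= float(disp.median()) <= 0.25

    def test_constant_genes_sit_at_the_floor(self):
        counts = pd.DataFrame(
            {"a": [10, 40, 7], "b": [10, 40, 7], "c": [10, 40, 7], "d": [10, 40, 7]}
        )
        design = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        disp = dge.estimate_dispersion(tx.CountMatrix(counts, design))
        assert (disp == dge.DISPERSION_FLOOR).all()

    def test_requires_replicates(self):
        counts = pd.DataFrame({"a": [5, 8], "b": [6, 9]})
        design = pd.Series(["A", "B"], index=counts.columns)
        with pytest.raises(DataError, match="replicates"):
            dge.estimate_dispersion(tx.CountMatrix(counts, design))


# --------------------------------------------------------------- exact test
class TestDifferentialTest:
    def test_identical_groups_give_zero_log2fc_and_p_one(self, rng):
        block = rng.poisson(80, size=(60, 2))
        counts = pd.DataFrame(
            np.hstack([block, block]), columns=["a1", "a2", "b1", "b2"]
        )
        design = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        res = dge.test_differential(tx.CountMatrix(counts, design), "A", "B")
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_swapping_groups_negates_log2fc_and_keeps_p(self, toy_matrix):
        ab = dge.test_differential(toy_matrix, "A", "B", min_mean_count=0.0)
        ba = dge.test_differential(toy_matrix, "B", "A", min_mean_count=0.0)
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_scaling_one_sample_is_absorbed_by_its_size_factor(self, small_cohort):
        _, matrix, _ = small_cohort
        sub = matrix.subset_groups(["CNT", "DM1"])
        scaled_counts = sub.counts.copy()
        scaled_counts["CNT_s1"] = scaled_counts["CNT_s1"] * 3
        scaled = tx.CountMatrix(scaled_counts, sub.design)
        sf_orig = dge.size_factors(sub.counts)
        sf_scaled = dge.size_factors(scaled.counts)
        ratio = (sf_scaled / sf_orig).to_numpy()
        assert ratio[0] / ratio[1] == pytest.approx(3.0)
        # normalization absorbs the scaling, up to the pseudocount and the
        # global geometric-mean rescale, so fold changes agree closely
        res_a = dge.test_differential(sub, "CNT", "DM1")
        res_b = dge.test_differential(scaled, "CNT", "DM1")
        shared = res_a.index.intersection(res_b.index)
        assert len(shared) > 200
        assert np.allclose(
            res_a.loc[shared, "log2fc"], res_b.loc[shared, "log2fc"], atol=0.05
        )

    def test_detects_strong_effects(self, small_cohort):
        _, matrix, truth = small_cohort
        res = dge.test_differential(matrix, "CNT", "DM1")
        true_dis = truth.index[truth["is_disease_gene"] & (truth["delta_log2"].abs() >= 1.5)]
        tested = true_dis.intersection(res.index)
        recall = res.loc[tested, "altered"].mean()
        assert recall > 0.8

    def test_unknown_or_small_groups_rejected(self, toy_matrix):
        with pytest.raises(DataError):
            dge.test_differential(toy_matrix, "A", "Z")
        counts = toy_matrix.counts[["a1", "a2", "b1"]]
        design = toy_matrix.design.loc[["a1", "a2", "b1"]]
        with pytest.raises(DataError, match=">= 2 samples"):
            dge.test_differential(tx.CountMatrix(counts, design), "A", "B")


# ----------------------------------------------------------------------- BH
class TestAdjustPvalues:
    def test_closed_form_example(self):
        out = dge.adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert dge.adjust_pvalues([0.37])[0] == pytest.approx(0.37)

    def test_matches_step_up_enumeration(self, rng):
        p = rng.uniform(size=100)
        assert np.allclose(dge.adjust_pvalues(p), bh_step_up(p))

    def test_monotone_in_raw_p(self, rng):
        p = np.sort(rng.uniform(size=50))
        adj = dge.adjust_pvalues(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p).all() and (adj <= 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(DataError, match="NaN"):
            dge.adjust_pvalues([0.1, float("nan")])


class TestCallAltered:
    @pytest.mark.parametrize(
        "padj,log2fc,expected",
        [(0.04, 1.2, True), (0.04, 0.9, False), (0.06, 1.2, False), (0.04, -1.0, True)],
    )
    def test_threshold_application(self, padj, log2fc, expected):
        frame = pd.DataFrame({"padj": [padj], "log2fc": [log2fc]}, index=["g"])
        called = dge.call_altered(frame, alpha=0.05, lfc_threshold=1.0)
        assert ("g" in called) is expected
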