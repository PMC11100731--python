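"""ADT normalization, rank binning and the nonparametric test battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bmpcrep import (
    assign_bins,
    gene_bin_association,
    normalize_adt,
    rank_test,
    spearman_correlation,
)


class TestNormalizeAdt:
    def test_zero_mean_unit_sd(self, rng):
        counts = pd.Series(rng.integers(1, 500, 60).astype(float))
        z = normalize_adt(counts, pd.Series(["b1"] * 60))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_batch_independence(self, rng):
        counts = pd.Series(rng.integers(1, 500, 40).astype(float))
        batches = pd.Series(["a"] * 20 + ["b"] * 20)
        z = normalize_adt(counts, batches)
        # scaling one batch's counts leaves the other batch's z untouched
        scaled = counts.copy()
        scaled.iloc[:20] = scaled.iloc[:20] * 7 + 3
        z2 = normalize_adt(scaled, batches)
        pd.testing.assert_series_equal(z.iloc[20:], z2.iloc[20:])

    def test_two_cell_batch_sample_sd(self):
        # counts {0, e-1}: log1p = {0, 1}; sample (n-1) sd of a 2-point
        # sample is |x1-x2|/sqrt(2), so z = -+1/sqrt(2)
        counts = pd.Series([0.0, math.e - 1.0])
        z = normalize_adt(counts, pd.Series(["b", "b"]))
        assert z.tolist() == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_zero_variance_batch_named(self):
        counts = pd.Series([5.0, 5.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="flatbatch"):
            normalize_adt(counts, pd.Series(["flatbatch"] * 2 + ["ok"] * 2))


class TestAssignBins:
    def test_30_40_30_split(self, rng):
        vals = pd.Series(rng.permutation(10).astype(float),
                         index=[f"b{i}" for i in range(10)])
        bins = assign_bins(vals)
        assert bins.value_counts().to_dict() == {"mid": 4, "low": 3, "high": 3}
        assert set(vals[bins == "low"]) == {0.0, 1.0, 2.0}
        assert set(vals[bins == "high"]) == {7.0, 8.0, 9.0}

    def test_large_split(self, rng):
        vals = pd.Series(rng.permutation(1000).astype(float),
                         index=[f"b{i:04d}" for i in range(1000)])
        counts = assign_bins(vals).value_counts()
        assert counts["low"] == 300 and counts["mid"] == 400 and counts["high"] == 300

    def test_all_ties_split_deterministically(self):
        vals = pd.Series(1.0, index=[f"b{i}" for i in range(10)])
        bins = assign_bins(vals)
        assert bins.value_counts().to_dict() == {"mid": 4, "low": 3, "high": 3}
        # lexicographically smallest barcodes land in the low bin
        assert set(bins[bins == "low"].index) == {"b0", "b1", "b2"}

    def test_order_invariant(self, rng):
        vals = pd.Series(rng.normal(size=50), index=[f"b{i:02d}" for i in range(50)])
        a = assign_bins(vals)
        b = assign_bins(vals.sample(frac=1.0, random_state=3)).reindex(a.index)
        pd.testing.assert_series_equal(a, b)

    def test_monotone_transform_invariant(self, rng):
        vals = pd.Series(rng.normal(size=40), index=[f"b{i:02d}" for i in range(40)])
        a = assign_bins(vals)
        b = assign_bins(np.exp(vals) * 3 + 1)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            assign_bins(pd.Series([1.0, 2.0]))

    def test_bad_fractions_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            assign_bins(vals, fractions=(0.5, 0.4, 0.3))


class TestRankTest:
    def test_mann_whitney_extreme_exact(self):
        res = rank_test([[1, 2, 3], [4, 5, 6]], kind="mann_whitney")
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(0.1)
        assert res.method == "exact"
        assert res.posthoc is None

    def test_kruskal_statistic(self):
        res = rank_test([[1, 2], [3, 4], [5, 6]], kind="kruskal_wallis")
        assert res.statistic == pytest.approx(4.571, abs=5e-4)
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_friedman_consistent_ranks(self):
        # 3 treatments x 2 blocks, same ordering in both blocks
        res = rank_test([[1, 2], [5, 6], [9, 10]], kind="friedman")
        assert res.statistic == pytest.approx(4.0)
        assert res.method == "exact"
        assert res.posthoc is not None

    def test_exact_matches_scipy_mann_whitney(self, rng):
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (2, 7)]:
            x = rng.permutation(n1 + n2)[:n1].astype(float)
            y = np.setdiff1d(np.arange(n1 + n2), x).astype(float)
            res = rank_test([x, y], kind="mann_whitney")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.pvalue == pytest.approx(ref.pvalue)
            assert res.statistic == pytest.approx(ref.statistic)

    def test_large_samples_use_approximation(self, rng):
        res = rank_test([rng.normal(size=30), rng.normal(1, 1, 30)],
                        kind="mann_whitney")
        assert res.method == "asymptotic"

    def test_posthoc_pairs_cover_all_groups(self, rng):
        groups = {k: rng.normal(size=20) for k in "abcd"}
        res = rank_test(groups, kind="kruskal_wallis")
        pairs = set(map(tuple, res.posthoc[["group_a", "group_b"]].to_numpy()))
        assert pairs == set(itertools.combinations("abcd", 2))
        assert ((res.posthoc["p_adj"] >= res.posthoc["p"] - 1e-12).all())

    def test_wrong_group_counts_rejected(self):
        with pytest.raises(ValueError):
            rank_test([[1, 2]], kind="mann_whitney")
        with pytest.raises(ValueError):
            rank_test([[1, 2], [3, 4]], kind="kruskal_wallis")
        with pytest.raises(ValueError):
            rank_test([[1, 2], [3, 4], [5]], kind="friedman")


class TestSpearman:
    def test_monotone(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        rho, _ = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranks(self):
        rho, _ = spearman_correlation([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])


class TestGeneBinAssociation:
    def test_constant_gene_equal_medians(self):
        expr = pd.Series([2.0] * 30)
        groups = pd.Series(["low"] * 10 + ["mid"] * 10 + ["high"] * 10)
        res, summary = gene_bin_association(expr, groups)
        assert summary["median"].nunique() == 1
        assert res.pvalue > 0.9

    def test_disjoint_ranges_exact_extreme_p(self):
        # 3 vs 3 disjoint values: the most extreme configuration,
        # p = 2 / C(6,3) = 0.1 by enumeration
        expr = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        res, _ = gene_bin_association(expr, groups)
        assert res.kind == "mann_whitney"
        assert res.pvalue == pytest.approx(0.1)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            gene_bin_association(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


def test_planted_association_gene_higher_in_cd19_low(default_sim):
    """The planted gene shift surfaces as a higher CD19-low-bin median."""
    from bmpcrep import PipelineConfig, run_pipeline
    res = run_pipeline(PipelineConfig(), vdj=default_sim.vdj,
                       cells=default_sim.cells, meta=default_sim.meta)
    table = res.stats_tables["jchain_by_cd19_bin"].set_index("group")
    assert table.loc["low", "median"] > table.loc["high", "median"]
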