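"""Region classification, Fisher tests, and the matched permutation test."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telomethyl.positional_stats import (
    ChromosomeLayout,
    LayoutError,
    build_contingency,
    classify_gene_regions,
    fisher_enrichment,
    imprinted_permutation_test,
    nearest_counts,
)


class TestLayout:
    def test_file_round_trip(self, toy_layout, tmp_path):
        toy_layout.write(tmp_path / "chrom.sizes", tmp_path / "cen.bed")
        back = ChromosomeLayout.from_files(
            tmp_path / "chrom.sizes", tmp_path / "cen.bed"
        )
        pd.testing.assert_frame_equal(
            back.table.astype(float), toy_layout.table.astype(float)
        )

    @pytest.mark.parametrize(
        "spec", [{"c": (0,)}, {"c": (100, 50, 40)}, {"c": (100, -1, 10)},
                 {"c": (100, 10, 200)}]
    )
    def test_invalid_layouts_rejected(self, spec):
        with pytest.raises(LayoutError):
            ChromosomeLayout.from_dict(spec)


class TestClassifyRegions:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])

    def test_tss_at_zero_is_subtelomeric(self, toy_layout):
        out = classify_gene_regions(self._genes([("g", "chr1", 0)]), toy_layout)
        assert bool(out.loc[0, "subtelomeric"])

    def test_window_boundary_inclusive(self, toy_layout):
        # chr2 is 12 Mb: a TSS exactly 4 Mb from the right end is included
        out = classify_gene_regions(
            self._genes([("a", "chr2", 8_000_000), ("b", "chr2", 7_999_999)]),
            toy_layout,
        )
        assert bool(out.loc[0, "subtelomeric"])
        assert not bool(out.loc[1, "subtelomeric"])

    def test_missing_centromere_gives_na(self, toy_layout):
        out = classify_gene_regions(
            self._genes([("g", "chrNoCen", 100)]), toy_layout
        )
        assert pd.isna(out.loc[0, "centromeric"])
        assert bool(out.loc[0, "subtelomeric"])

    def test_out_of_bounds_tss_rejected(self, toy_layout):
        with pytest.raises(ValueError, match="bounds"):
            classify_gene_regions(
                self._genes([("g", "chr1", 10_000_000)]), toy_layout
            )

    def test_matches_bruteforce_distances(self, toy_layout, rng):
        rows = []
        for i in range(500):
            chrom = ["chr1", "chr2", "chrNoCen"][int(rng.integers(0, 3))]
            L = toy_layout.length(chrom)
            rows.append((f"g{i}", chrom, int(rng.integers(0, L))))
        out = classify_gene_regions(self._genes(rows), toy_layout).set_index("gene_id")
        for gid, chrom, tss in rows:
            L = toy_layout.length(chrom)
            assert bool(out.loc[gid, "subtelomeric"]) == (
                min(tss, L - tss) <= 4_000_000
            )
            if toy_layout.has_centromere(chrom):
                cs = toy_layout.table.at[chrom, "cen_start"]
                ce = toy_layout.table.at[chrom, "cen_end"]
                if cs <= tss < ce:
                    d = 0
                elif tss < cs:
                    d = cs - tss
                else:
                    d = tss - (ce - 1)
                assert bool(out.loc[gid, "centromeric"]) == (d <= 1_500_000)


def _enumerated_fisher_p(table, alternative):
    """Oracle: sum hypergeometric probabilities of as-or-more-extreme tables."""
    a, b, c, d = table.ravel()
    row1, col1, n = a + b, a + c, a + b + c + d
    dist = stats.hypergeom(n, row1, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    p_obs = dist.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = dist.pmf(x)
        if alternative == "greater" and x >= a:
            total += px
        elif alternative == "less" and x <= a:
            total += px
        elif alternative == "two-sided" and px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_zero_margin_gives_p_one(self):
        res = fisher_enrichment(np.array([[0, 0], [3, 5]]))
        assert res.p_value == 1.0 and np.isnan(res.odds_ratio)

    def test_diagonal_table(self):
        # [[5,0],[0,5]] two-sided: the two extreme tables out of C(10,5)
        res = fisher_enrichment(np.array([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / comb(10, 5), rel=1e-9)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_matches_enumeration_for_small_tables(self, rng, alternative):
        for _ in range(60):
            table = rng.integers(0, 11, size=(2, 2))
            if table.sum() == 0 or table.sum() > 40:
                continue
            res = fisher_enrichment(table, alternative)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                assert res.p_value == 1.0
                continue
            assert res.p_value == pytest.approx(
                _enumerated_fisher_p(table, alternative), rel=1e-6
            )

    def test_transpose_invariance(self, rng):
        table = np.array([[8, 3], [2, 12]])
        a = fisher_enrichment(table)
        b = fisher_enrichment(table.T)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_contingency_builder_margins(self):
        idx = [f"g{i}" for i in range(10)]
        in_class = pd.Series([True] * 4 + [False] * 6, index=idx)
        sig = pd.Series([True, False] * 5, index=idx)
        table = build_contingency(in_class, sig)
        assert table.sum() == 10
        assert table[0].sum() == 4


class TestNearestCounts:
    def test_conservation_and_zero_counts(self):
        cmap = pd.DataFrame(
            {"gene_id": ["A", "A", "B", None]},
            index=pd.Index([f"cg{i}" for i in range(4)], name="cpg_id"),
        )
        counts = nearest_counts(cmap, ["A", "B", "C"])
        assert counts["A"] == 2 and counts["B"] == 1 and counts["C"] == 0
        assert counts.sum() == cmap["gene_id"].notna().sum()

    def test_matches_groupby_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        assigned = rng.choice(genes, size=200)
        cmap = pd.DataFrame(
            {"gene_id": assigned},
            index=pd.Index([f"cg{i}" for i in range(200)], name="cpg_id"),
        )
        counts = nearest_counts(cmap, genes)
        oracle = pd.Series(assigned).value_counts()
        for g in genes:
            assert counts[g] == oracle.get(g, 0)


class TestPermutationTest:
    def test_zero_observed_gives_p_one(self):
        counts = pd.Series([2] * 10, index=[f"g{i}" for i in range(10)])
        res = imprinted_permutation_test(
            ["g0", "g1"], counts, imprinted_genes=set(), n_permutations=1000, seed=1
        )
        assert res.observed == 0 and res.p_value == 1.0

    def test_uniform_counts_match_exhaustive_enumeration(self):
        # universe of 8 genes with equal nearest counts, draw sets of 2:
        # exact p = hypergeometric tail over all C(8,2) sets
        counts = pd.Series([3] * 8, index=[f"g{i}" for i in range(8)])
        imprinted = {"g0", "g1", "g2"}
        res = imprinted_permutation_test(
            ["g0", "g1"], counts, imprinted, n_permutations=100_000, seed=3
        )
        exact = stats.hypergeom(8, 3, 2).sf(1)  # P(X >= 2)
        mc_sd = np.sqrt(exact * (1 - exact) / res.n_permutations)
        assert abs(res.p_value - exact) < 3 * mc_sd

    def test_uniform_counts_match_fisher_one_sided(self):
        counts = pd.Series([5] * 12, index=[f"g{i}" for i in range(12)])
        imprinted = {f"g{i}" for i in range(4)}
        sig = ["g0", "g1", "g5"]
        res = imprinted_permutation_test(
            sig, counts, imprinted, n_permutations=100_000, seed=4
        )
        table = np.array([[2, 2], [1, 7]])  # imprinted x significant
        fisher_p = fisher_enrichment(table, "greater").p_value
        mc_sd = np.sqrt(fisher_p * (1 - fisher_p) / res.n_permutations)
        assert abs(res.p_value - fisher_p) < 3 * mc_sd

    def test_two_strata_match_product_enumeration(self):
        # two exact strata (counts 1 and 9), one draw from each: the null is
        # the product of two one-draw hypergeometrics, enumerable directly
        genes = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        counts = pd.Series([1] * 6 + [9] * 6, index=genes)
        imprinted = {"a0", "a1", "b0"}
        sig = ["a0", "b5"]
        res = imprinted_permutation_test(
            sig, counts, imprinted, n_permutations=100_000, seed=5
        )
        # exact P(total >= observed): draws are independent Bernoulli with
        # success 2/6 and 1/6
        p_a, p_b = 2 / 6, 1 / 6
        observed = 1
        exact = 1 - (1 - p_a) * (1 - p_b)  # P(at least one imprinted)
        mc_sd = np.sqrt(exact * (1 - exact) / res.n_permutations)
        assert res.observed == observed
        assert abs(res.p_value - exact) < 3 * mc_sd

    def test_seed_invariance_within_monte_carlo_error(self):
        counts = pd.Series([3] * 8, index=[f"g{i}" for i in range(8)])
        imprinted = {"g0", "g1", "g2"}
        ps = [
            imprinted_permutation_test(
                ["g0", "g1"], counts, imprinted, n_permutations=100_000, seed=s
            ).p_value
            for s in (11, 12)
        ]
        exact = stats.hypergeom(8, 3, 2).sf(1)
        mc_sd = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(ps[0] - ps[1]) < 6 * mc_sd

    def test_matching_removes_nearest_count_bias(self, rng):
        # imprinted genes sit near ~2x as many CpGs; the matched null's mean
        # imprinted count must fall below the unmatched null's
        n, n_imp = 400, 40
        genes = [f"g{i}" for i in range(n)]
        imprinted = set(genes[:n_imp])
        counts = pd.Series(
            np.where(np.arange(n) < n_imp, rng.poisson(16, n), rng.poisson(8, n)),
            index=genes,
        )
        sig = genes[:5] + genes[n - 20:]  # high-count-heavy significant set
        matched = imprinted_permutation_test(
            sig, counts, imprinted, n_permutations=20_000, seed=6
        )
        unmatched = imprinted_permutation_test(
            sig, pd.Series(1, index=genes), imprinted,
            n_permutations=20_000, seed=6,
        )
        assert matched.null_mean > unmatched.null_mean  # sig set is count-biased
        # and the matched mean respects the expected stratified composition
        assert matched.null_mean < 2.5 * unmatched.null_mean

    def test_add_one_estimator_floor(self):
        counts = pd.Series([2] * 30, index=[f"g{i}" for i in range(30)])
        res = imprinted_permutation_test(
            ["g0"], counts, {"g0"}, n_permutations=1000, seed=7
        )
        assert res.p_value >= 1 / (res.n_permutations + 1)

    def test_foreign_significant_gene_rejected(self):
        counts = pd.Series([1] * 5, index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="absent"):
            imprinted_permutation_test(["zz"], counts, set(), 1000, seed=0)
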