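"""Odds-ratio enrichment: rank quantiles, contingency arithmetic,
brute-force agreement, block thinning and partitions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from clineseas.errors import DataError
from clineseas import enrichment
from clineseas.enrichment import (
    ContingencyCounts,
    block_downsample,
    block_downsampled_enrichment,
    gene_enrichment,
    genome_wide_enrichment,
    odds_ratio,
    partitioned_enrichment,
    rank_quantile,
)
from clineseas.matched_controls import ControlSets


class TestRankQuantile:
    def test_rank_arithmetic(self):
        got = rank_quantile([0.01, 0.5, 0.9, 0.2])
        np.testing.assert_allclose(got, [0.25, 0.75, 1.0, 0.5])

    def test_ties_share_the_maximum_rank(self):
        np.testing.assert_allclose(rank_quantile([0.3] * 4), [1.0] * 4)

    def test_fraction_at_or_below_cutoff_is_exact(self):
        rng = np.random.default_rng(0)
        q = rank_quantile(1 - rng.random(1000))
        assert int((q <= 0.05).sum()) == 50

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            rank_quantile([0.5, 0.0])
        with pytest.raises(DataError):
            rank_quantile([])


class TestOddsRatio:
    def test_equal_proportions_give_unity(self):
        res = odds_ratio(ContingencyCounts(5, 95, 5000, 95000))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.log2_odds_ratio == pytest.approx(0.0)
        assert not res.corrected

    def test_direct_arithmetic(self):
        res = odds_ratio(ContingencyCounts(10, 90, 5000, 95000))
        assert res.odds_ratio == pytest.approx(950000 / 450000)
        assert res.log2_odds_ratio == pytest.approx(np.log2(950000 / 450000))

    def test_zero_cell_haldane_anscombe(self):
        res = odds_ratio(ContingencyCounts(0, 100, 50, 950))
        assert res.corrected
        assert res.odds_ratio == pytest.approx((0.5 * 950.5) / (100.5 * 50.5))

    def test_empty_margin_is_an_error(self):
        with pytest.raises(DataError):
            ContingencyCounts(0, 0, 5, 5)


def brute_force_counts(snps, eqtl_ids, control_ids, pvalues, universe_ids, threshold):
    """Independent recount: rank quantiles by sorting, then direct filtering."""
    p = {s: pv for s, pv in zip(snps["snp_id"], pvalues)}
    uni = sorted(universe_ids, key=lambda s: p[s])
    n = len(uni)
    # max-rank tie sharing
    quant = {}
    for s in uni:
        quant[s] = sum(1 for t in uni if p[t] <= p[s]) / n
    a = sum(1 for s in eqtl_ids if quant[s] <= threshold)
    c = sum(1 for s in control_ids if quant[s] <= threshold)
    return a, len(eqtl_ids) - a, c, len(control_ids) - c


class TestGenomeWideAgainstBruteForce:
    @pytest.mark.parametrize("model", ["clinal", "seasonal"])
    @pytest.mark.parametrize("threshold", [0.01, 0.05, 0.25])
    def test_counts_and_or_match_exhaustive_recount(
        self, toy_panel, toy_controls, model, threshold
    ):
        snps, eqtls, _ = toy_panel
        cs = toy_controls
        results = genome_wide_enrichment(
            snps, eqtls, cs, model, grid=(threshold,), sex_classes=("all",)
        )
        (res,) = results
        universe = set(
            snps["snp_id"].to_numpy()[np.union1d(cs.eqtl_idx, cs.candidate_idx)]
        )
        pvals = snps[f"{model}_p"].to_numpy()
        for k in range(cs.n_sets):
            ctrl_ids = list(snps["snp_id"].to_numpy()[cs.control_idx[:, k]])
            a, b, c, d = brute_force_counts(
                snps, list(cs.eqtl_ids), ctrl_ids, pvals, universe, threshold
            )
            assert a == res.a_count and a + b == res.n_eqtls
            expected = odds_ratio(ContingencyCounts(a, b, c, d)).log2_odds_ratio
            assert res.null_log2_or[k] == pytest.approx(expected, abs=1e-12)

    def test_a_count_monotone_in_threshold(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        res = genome_wide_enrichment(
            snps, eqtls, toy_controls, "clinal",
            grid=(0.001, 0.01, 0.05, 0.1, 0.5), sex_classes=("all",),
        )
        counts = [r.a_count for r in res]
        assert counts == sorted(counts)

    def test_self_comparison_is_null(self, toy_panel):
        """eQTLs used as their own controls: log2 OR identically 0 and an
        empirical p-value at the null end."""
        snps, eqtls, inversions = toy_panel
        from clineseas.matched_controls import build_control_sets

        cs = build_control_sets(snps, inversions, n_sets=10, seed=1)
        mirror = ControlSets(
            eqtl_ids=cs.eqtl_ids,
            eqtl_idx=cs.eqtl_idx,
            control_idx=np.tile(cs.eqtl_idx[:, None], (1, 10)),
            candidate_idx=cs.candidate_idx,
            pool_sizes=cs.pool_sizes,
            n_sets=10,
            seed=1,
            with_replacement=cs.with_replacement,
            snp_ids=cs.snp_ids,
        )
        res = genome_wide_enrichment(
            snps, eqtls, mirror, "clinal", grid=(0.05,), sex_classes=("all",)
        )
        assert res[0].log2_or_mean == 0.0
        # all-tied comparison: emp_p = 2 * (1 - (1 + N/2)/(N + 1)) = N/(N+1)
        assert res[0].emp_p == pytest.approx(10 / 11)


class TestBlockDownsampling:
    def _eqtl_frame(self, positions, arm="2L"):
        return pd.DataFrame(
            {"snp_id": [f"{arm}:{p}" for p in positions], "arm": arm, "pos": positions}
        )

    def test_window_partition_retention(self):
        df = self._eqtl_frame([1_000, 5_000, 12_000])
        rng = np.random.default_rng(0)
        for _ in range(20):
            kept = set(block_downsample(df, rng, window=10_000))
            assert "2L:12000" in kept
            assert len(kept & {"2L:1000", "2L:5000"}) == 1
            assert len(kept) == 2

    def test_far_apart_eqtls_are_all_retained(self):
        df = self._eqtl_frame([1, 20_000, 40_001, 90_000])
        rng = np.random.default_rng(0)
        assert len(block_downsample(df, rng, window=10_000)) == 4

    def test_noop_when_all_eqtls_far_apart(self, toy_panel, toy_controls):
        """With every eQTL in its own window, thinned results equal the
        full analysis in every replicate."""
        snps, eqtls, _ = toy_panel
        full = genome_wide_enrichment(
            snps, eqtls, toy_controls, "clinal", grid=(0.05,), sex_classes=("all",)
        )[0]
        # toy positions are draws from 30 Mb, so collisions in 10-kb
        # windows are absent at this density for this seed
        eqtl_pos = snps.loc[snps["is_eqtl"]].sort_values(["arm", "pos"])
        gaps_ok = (
            eqtl_pos.groupby("arm")["pos"]
            .apply(lambda s: (np.diff(s) > 10_000).all() if len(s) > 1 else True)
            .all()
        )
        assert gaps_ok, "fixture no longer satisfies the far-apart premise"
        thinned = block_downsampled_enrichment(
            snps, eqtls, toy_controls, "clinal", grid=(0.05,),
            sex_classes=("all",), n_rep=5, seed=0,
        )[0]
        assert thinned.log2_or_mean == pytest.approx(full.log2_or_mean)
        assert thinned.a_count == full.a_count


class TestPartitionedEnrichment:
    def test_arm_counts_equal_region_sums(self, toy_panel, toy_controls):
        snps, eqtls, inversions = toy_panel
        results = partitioned_enrichment(
            snps, eqtls, toy_controls, inversions, "clinal", sex_classes=("all",)
        )
        by = {(r.stratum): r for r in results}
        for inv in inversions:
            regions = [f"{inv.name}:{reg}" for reg in ("breakpoint", "inside", "outside")]
            arm_res = by[inv.arm]
            assert arm_res.a_count == sum(by[r].a_count for r in regions)
            assert arm_res.n_eqtls == sum(by[r].n_eqtls for r in regions)

    def test_empty_stratum_marked_not_testable(self, toy_panel, toy_controls):
        snps, eqtls, inversions = toy_panel
        results = partitioned_enrichment(
            snps, eqtls, toy_controls, inversions, "clinal",
            sex_classes=("female",),
        )
        empties = [r for r in results if r.n_eqtls == 0]
        assert all(not r.testable and not r.adj_significant for r in empties)


class TestGeneEnrichment:
    def test_exact_binomial_excess_arithmetic(self):
        # 7 enriched of 8 significant genes, two-sided exact
        assert scipy.stats.binomtest(7, 8, 0.5).pvalue == pytest.approx(
            2 * (8 + 1) / 2**8
        )

    def test_gene_filter_and_summary_consistency(self, small_sim):
        data, cs = small_sim
        results, summary = gene_enrichment(
            data.snps, data.eqtls, cs, "clinal", threshold=0.05
        )
        # only genes with >= 1 eQTL at/below the cutoff are reported
        assert all(r.a_count >= 1 for r in results)
        assert summary.n_tested == len(results)
        sig = [r for r in results if r.emp_p <= 0.05]
        assert summary.n_significant == len(sig)
        assert summary.n_enriched == sum(r.log2_or_mean > 0 for r in sig)
        if summary.n_significant:
            expected = scipy.stats.binomtest(
                summary.n_enriched, summary.n_significant, 0.5
            ).pvalue
            assert summary.binomial_p == pytest.approx(expected)

    def test_enriched_panel_shows_gene_excess(self, small_sim):
        """With clinal enrichment injected at theta = 2, significantly
        enriched genes outnumber depleted ones."""
        data, cs = small_sim
        _, summary = gene_enrichment(data.snps, data.eqtls, cs, "clinal")
        assert summary.n_significant > 0
        assert summary.proportion_enriched > 0.5
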