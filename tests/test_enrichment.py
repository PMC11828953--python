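"""Context assignment, occurrence pools, permutation and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c4omics.enrichment import (
    assign_context,
    build_pool,
    fisher_enrichment,
    gene_windows,
    permutation_enrichment,
    run_enrichment,
    summarize_enriched,
)
from c4omics.io import CREOccurrence, GeneModel, GeneSet, OccurrencePool, RunConfig
from c4omics.simulate import SimConfig, gen_cre_pool


def occ(start, end, cre="m1", chrom="chr1"):
    return CREOccurrence(cre_id=cre, acr_id="a", chrom=chrom, start=start, end=end)


PLUS_GENE = GeneModel("gP", "chr1", 10_000, 13_000, "+", 10_000, 12_999)
MINUS_GENE = GeneModel("gM", "chr2", 50_000, 53_000, "-", 52_999, 50_000)


class TestAssignContext:
    def test_inside_gene_body_is_gacr(self):
        [o] = assign_context([occ(11_000, 11_008)], [PLUS_GENE])
        assert o.contexts == {"gACR"}
        assert o.gene_ids == {"gP"}

    def test_upstream_boundary_plus_strand(self):
        # ends 2,999 bp upstream of the start codon -> upACR
        [o] = assign_context([occ(10_000 - 3_007, 10_000 - 2_999)], [PLUS_GENE])
        assert "upACR" in o.contexts
        # ends 3,001 bp upstream -> outside the window
        [o] = assign_context([occ(10_000 - 3_009, 10_000 - 3_001)], [PLUS_GENE])
        assert o.contexts == set()

    def test_minus_strand_upstream_is_high_side(self):
        [o] = assign_context([occ(53_500, 53_508, chrom="chr2")], [MINUS_GENE])
        assert "upACR" in o.contexts
        [o] = assign_context([occ(49_500, 49_508, chrom="chr2")], [MINUS_GENE])
        assert "downACR" in o.contexts

    def test_unassigned_retained_with_empty_labels(self):
        [o] = assign_context([occ(1, 9)], [PLUS_GENE])
        assert o.contexts == set() and o.gene_ids == set()

    def test_agrees_with_bruteforce_all_pairs(self):
        rng = np.random.default_rng(31)
        genes = []
        pos = 5000
        for i in range(100):
            start = pos + int(rng.integers(0, 2000))
            end = start + int(rng.integers(500, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            sc, tc = (start, end - 1) if strand == "+" else (end - 1, start)
            genes.append(GeneModel(f"g{i}", "chr1", start, end, strand, sc, tc))
            pos = end + int(rng.integers(100, 4000))
        occs = [occ(int(s), int(s) + 8, cre=f"m{i % 5}")
                for i, s in enumerate(rng.integers(0, pos + 5000, size=1000))]
        got = assign_context([CREOccurrence(**{**o.__dict__}) for o in occs], genes)
        # O(n*m) oracle: direct interval intersection per (occurrence, gene, window)
        for o_fast, o in zip(got, occs):
            labels = set()
            gene_ids = set()
            for g in genes:
                for ctx, (a, b) in gene_windows(g, 3000).items():
                    if o.start < b and a < o.end:
                        labels.add(ctx)
                        gene_ids.add(g.gene_id)
            assert o_fast.contexts == labels
            assert o_fast.gene_ids == gene_ids


class TestBuildPool:
    def test_all_target_associated_k_equals_n(self):
        occs = assign_context([occ(11_000, 11_008), occ(11_100, 11_108)], [PLUS_GENE])
        pool = build_pool(occs, GeneSet("t", frozenset(["gP"])))
        assert pool.k == pool.N == 2

    def test_disjoint_target_raises(self):
        occs = assign_context([occ(11_000, 11_008)], [PLUS_GENE])
        with pytest.raises(ValueError, match="nothing to test"):
            build_pool(occs, GeneSet("t", frozenset(["absent"])))

    def test_multilabel_counted_once(self):
        g2 = GeneModel("gQ", "chr1", 11_004, 14_000, "+", 11_004, 13_999)
        occs = assign_context([occ(11_000, 11_008)], [PLUS_GENE, g2])
        pool = build_pool(occs, GeneSet("t", frozenset(["gP", "gQ"])))
        assert pool.k == 1


class TestPermutation:
    def test_single_cre_degenerate_pool(self):
        pool = OccurrencePool(["only"], n_c=[100], k_c=[10])
        res = permutation_enrichment(pool, B=200, seed=0)
        assert res["perm_p"].iloc[0] == pytest.approx(1.0)
        strict = permutation_enrichment(pool, B=200, seed=0, p_mode="strict_paper")
        assert strict["perm_p"].iloc[0] == 0.0  # the literal rule underflows

    def test_mean_matches_hypergeometric_expectation(self):
        cfg = SimConfig(seed=17, spike_multiplier=1.0, spiked_cre_ids=())
        pool, _ = gen_cre_pool(cfg)
        res = permutation_enrichment(pool, B=1000, seed=3)
        rel = np.abs(res["perm_mean"] - res["expected"]) / res["expected"]
        assert rel.max() < 0.02

    def test_conservation_every_permutation(self):
        pool = OccurrencePool([f"c{i}" for i in range(10)],
                              n_c=np.full(10, 100), k_c=np.full(10, 5))
        rng = np.random.default_rng(1)
        counts = rng.multivariate_hypergeometric(pool.n_c, pool.k, size=500)
        assert (counts.sum(axis=1) == pool.k).all()

    def test_seed_determinism(self):
        pool = OccurrencePool(["a", "b"], n_c=[500, 500], k_c=[30, 20])
        r1 = permutation_enrichment(pool, B=300, seed=9)
        r2 = permutation_enrichment(pool, B=300, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_monotone_in_observed_count(self):
        base = dict(n_c=[1000, 9000], B=2000)
        ps = []
        for k_c in (5, 20, 50):
            pool = OccurrencePool(["x", "y"], n_c=base["n_c"], k_c=[k_c, 100 - k_c])
            res = permutation_enrichment(pool, B=base["B"], seed=4)
            ps.append(res.set_index("cre_id").loc["x", "perm_p"])
        assert ps[0] >= ps[1] >= ps[2]


class TestFisher:
    def test_odds_ratio_one_when_proportional(self):
        pool = OccurrencePool(["a", "b"], n_c=[100, 900], k_c=[10, 90])
        res = fisher_enrichment(pool).set_index("cre_id")
        assert res.loc["a", "odds_ratio"] == pytest.approx(1.0)

    def test_p_equals_hypergeometric_tail_sum(self):
        # N=100, n_c=10, k=20, k_c=10: brute-force tail over x >= 10
        pool = OccurrencePool(["a", "b"], n_c=[10, 90], k_c=[10, 10])
        res = fisher_enrichment(pool).set_index("cre_id")
        from math import comb
        tail = sum(comb(10, x) * comb(90, 20 - x) for x in range(10, 11)) / comb(100, 20)
        assert res.loc["a", "fisher_p"] == pytest.approx(tail, rel=1e-10)
        # a less extreme observed count, tail over x >= 4
        pool = OccurrencePool(["a", "b"], n_c=[10, 90], k_c=[4, 16])
        res = fisher_enrichment(pool).set_index("cre_id")
        tail = sum(comb(10, x) * comb(90, 20 - x) for x in range(4, 11)) / comb(100, 20)
        assert res.loc["a", "fisher_p"] == pytest.approx(tail, rel=1e-10)

    def test_zero_cell_flagged_and_corrected(self):
        pool = OccurrencePool(["a", "b"], n_c=[10, 90], k_c=[0, 20])
        res = fisher_enrichment(pool).set_index("cre_id")
        assert bool(res.loc["a", "or_corrected"])
        assert np.isfinite(res.loc["a", "odds_ratio"])

    def test_monotone_in_observed_count(self):
        ps = []
        for k_c in (2, 10, 18):
            pool = OccurrencePool(["x", "y"], n_c=[1000, 9000], k_c=[k_c, 100 - k_c])
            ps.append(fisher_enrichment(pool).set_index("cre_id").loc["x", "fisher_p"])
        assert ps[0] > ps[1] > ps[2]


class TestSpikeRecovery:
    def test_spiked_cres_flagged_by_both_methods(self):
        cfg = SimConfig(seed=23)  # defaults: s=3 spike on 5 CREs
        pool, truth = gen_cre_pool(cfg)
        res = run_enrichment(pool, RunConfig(seed=23, b_permutations=1000))
        res = res.set_index("cre_id")
        spiked = truth.scalars["spiked_cres"]
        assert (res.loc[spiked, "perm_q"] < 0.05).mean() >= 0.9
        assert (res.loc[spiked, "fisher_q"] < 0.05).mean() >= 0.9

    def test_methods_agree_on_spiked_pool(self):
        cfg = SimConfig(seed=29)
        pool, _ = gen_cre_pool(cfg)
        res = run_enrichment(pool, RunConfig(seed=29, b_permutations=1000))
        rho = stats.spearmanr(-np.log10(res["perm_p"]),
                              -np.log10(res["fisher_p"])).statistic
        assert rho >= 0.9


class TestSummary:
    def test_empty_when_nothing_passes(self):
        res = pd.DataFrame({"cre_id": ["a"], "observed": [3], "perm_q": [0.9]})
        pool = OccurrencePool(["a"], n_c=[10], k_c=[3])
        out = summarize_enriched(res, pool)
        assert out.empty and list(out.columns) == ["cre_id", "family", "observed",
                                                   "log2_frequency"]

    def test_log2_frequency(self):
        res = pd.DataFrame({"cre_id": ["ERF_1"], "observed": [8], "perm_q": [0.01]})
        pool = OccurrencePool(["ERF_1"], n_c=[100], k_c=[8])
        out = summarize_enriched(res, pool)
        assert out.loc[0, "log2_frequency"] == 3.0
        assert out.loc[0, "family"] == "ERF"

    def test_erf_share_rises_under_erf_spike(self):
        # spike three ERF CREs: the ERF share among enriched CREs must exceed
        # the ERF share of the background CRE catalogue
        cfg = SimConfig(seed=31, spiked_cre_ids=("ERF_1", "ERF_2", "ERF_3"),
                        spike_multiplier=4.0)
        pool, _ = gen_cre_pool(cfg)
        res = run_enrichment(pool, RunConfig(seed=31))
        out = summarize_enriched(res, pool)
        assert not out.empty
        erf_share = (out["family"] == "ERF").mean()
        background_share = sum(c.startswith("ERF") for c in pool.cre_ids) / len(pool.cre_ids)
        assert erf_share > background_share
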