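"""PTR computation, SD classification, group statistics, resampling null."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from c4omics.io import AbundanceTable, RunConfig
from c4omics.ptr import (
    adjust_bh,
    classify_by_sd,
    compare_groups,
    compute_ptr,
    correlate_log,
    resample_null,
    zscore_matrix,
)
from c4omics.simulate import gen_multiomics


def _table(role, cols, index):
    return AbundanceTable(role, pd.DataFrame(cols, index=index))


class TestClassifyBySd:
    def test_element_two_sd_above_mean_is_high(self):
        vals = np.array([0.0] * 20 + [0.0], dtype=float)
        vals[:20] = np.linspace(-1, 1, 20)
        vals[-1] = vals[:20].mean() + 2 * np.concatenate([vals[:20], [vals[-1]]]).std(ddof=1)
        out = classify_by_sd(vals, m=1.0)
        assert out[-1] == "high"

    def test_element_at_mean_is_moderate(self):
        vals = np.array([-1.0, 0.0, 1.0])
        assert classify_by_sd(vals)[1] == "moderate"

    def test_identical_values_all_moderate(self):
        out = classify_by_sd(np.full(10, 3.3))
        assert (out == "moderate").all()

    def test_gaussian_tail_fractions(self):
        rng = np.random.default_rng(42)
        vals = rng.standard_normal(100_000)
        out = classify_by_sd(vals, m=1.0)
        # P(Z < -1) = P(Z > 1) = 0.1587
        assert (out == "low").mean() == pytest.approx(0.1587, abs=0.01)
        assert (out == "high").mean() == pytest.approx(0.1587, abs=0.01)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=500)
        out = classify_by_sd(vals)
        assert sum((out == c).sum() for c in ("low", "moderate", "high")) == 500


class TestComputePtr:
    def test_simple_ratio(self):
        rna = _table("rna", {"Ftri_R1": [100.0]}, ["g1"])
        prot = _table("protein", {"Ftri_R1": [200.0]}, ["g1"])
        # one gene cannot set SD thresholds; add a companion gene
        rna = _table("rna", {"Ftri_R1": [100.0, 50.0]}, ["g1", "g2"])
        prot = _table("protein", {"Ftri_R1": [200.0, 25.0]}, ["g1", "g2"])
        out = compute_ptr(rna, prot)
        row = out.data.set_index("gene_id").loc["g1"]
        assert row["ptr"] == 2.0

    def test_absent_protein_excluded(self):
        rna = _table("rna", {"Ftri_R1": [100.0, 50.0, 10.0]}, ["g1", "g2", "g3"])
        prot = _table("protein", {"Ftri_R1": [200.0, 25.0, np.nan]},
                      ["g1", "g2", "g3"])
        out = compute_ptr(rna, prot)
        assert "g3" not in set(out.data["gene_id"])
        assert out.n_excluded["Ftri"] == 1

    def test_rna_below_floor_excluded(self):
        rna = _table("rna", {"Ftri_R1": [100.0, 0.5]}, ["g1", "g2"])
        prot = _table("protein", {"Ftri_R1": [200.0, 25.0]}, ["g1", "g2"])
        out = compute_ptr(rna, prot, RunConfig(min_tpm=1.0))
        assert set(out.data["gene_id"]) == {"g1"}

    def test_noisefree_generator_ptr_exact(self, noisefree_multiomics):
        cfg, (tables, gene_sets, truth) = noisefree_multiomics
        out = compute_ptr(tables["rna"], tables["protein"])
        merged = out.data.set_index(["gene_id", "species"])["ptr"]
        for (gene, sp), ptr_val in merged.items():
            assert ptr_val == pytest.approx(truth.tables["ptr"].loc[gene, sp], rel=1e-9)


class TestCompareGroups:
    def test_identical_groups_nonsignificant(self):
        g = {"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]}
        comp = compare_groups(g)
        assert comp.pairwise["p_adj"].iloc[0] > 0.5

    def test_exact_ranksum_p_two_over_seventy(self):
        comp = compare_groups({"a": [1, 2, 3, 4], "b": [101, 102, 103, 104]})
        # two-sided exact p by enumeration of rank assignments: the observed
        # rank-sum split is the most extreme of C(8,4)=70 equally likely
        # assignments, achieved by 1 assignment per tail
        n_total = 0
        n_extreme = 0
        ranks = range(1, 9)
        obs = sum((1, 2, 3, 4))
        for combo in combinations(ranks, 4):
            n_total += 1
            if sum(combo) <= obs or sum(combo) >= sum(ranks) - obs:
                n_extreme += 1
        assert n_total == 70 and n_extreme == 2
        assert comp.pairwise["p_raw"].iloc[0] == pytest.approx(2 / 70)

    def test_group_too_small_named_in_error(self):
        with pytest.raises(ValueError, match="tiny"):
            compare_groups({"tiny": [1.0], "b": [1.0, 2.0]})

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        g = {"a": rng.normal(size=10), "b": rng.normal(1, 1, 10),
             "c": rng.normal(2, 1, 10)}
        c1 = compare_groups(g)
        c2 = compare_groups({k: g[k] for k in ["c", "a", "b"]})
        pd.testing.assert_frame_equal(c1.pairwise, c2.pairwise)

    def test_gating_flag(self):
        rng = np.random.default_rng(4)
        g = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        comp = compare_groups(g)
        if comp.anova_p >= 0.05:
            assert comp.gated
            assert (comp.pairwise["stars"] == "ns(gated)").all()


class TestAdjustBH:
    def test_closed_form(self):
        q = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert adjust_bh(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_definitional_stepup(self):
        # oracle: q_(i) = min_{j>=i} m * p_(j) / j
        rng = np.random.default_rng(12)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            ps = p[order]
            q_sorted = np.empty(m)
            running = np.inf
            for i in range(m - 1, -1, -1):
                running = min(running, m * ps[i] / (i + 1))
                q_sorted[i] = min(1.0, running)
            expected = np.empty(m)
            expected[order] = q_sorted
            assert np.allclose(adjust_bh(p), expected)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        assert (adjust_bh(p) >= p - 1e-12).all()


class TestZscore:
    def test_closed_form_row(self):
        z, flagged = zscore_matrix(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.iloc[0], [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert not flagged

    def test_constant_row_flagged_zeros(self):
        z, flagged = zscore_matrix(pd.DataFrame([[5.0, 5.0, 5.0]], index=["g1"]))
        assert (z.iloc[0] == 0).all()
        assert flagged == ["g1"]

    def test_rowwise_mean_zero_sd_one(self, rng):
        m = pd.DataFrame(rng.random((30, 5)) * 100)
        z, _ = zscore_matrix(m)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)


class TestCorrelateLog:
    def test_proportional_gives_r_one(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        r, n = correlate_log(x, 10 * x)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_independent_near_zero(self):
        rng = np.random.default_rng(21)
        x = 10 ** rng.normal(1, 0.5, 10_000)
        y = 10 ** rng.normal(1, 0.5, 10_000)
        r, _ = correlate_log(x, y)
        assert abs(r) < 0.05

    def test_matches_covariance_formula(self, rng):
        x = 10 ** rng.normal(0, 1, 200)
        y = 10 ** (0.5 * np.log10(x) + rng.normal(0, 0.3, 200))
        r, _ = correlate_log(x, y)
        lx, ly = np.log10(x), np.log10(y)
        num = ((lx - lx.mean()) * (ly - ly.mean())).sum()
        den = np.sqrt(((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, rel=1e-10)


class TestResampleNull:
    def test_count_and_determinism(self, small_multiomics):
        tables, _, _ = small_multiomics
        table = compute_ptr(tables["rna"], tables["protein"])
        draws1, _ = resample_null(table, n_genes=14, n_resamples=100, seed=9)
        draws2, _ = resample_null(table, n_genes=14, n_resamples=100, seed=9)
        assert draws1.shape[0] == 100
        pd.testing.assert_frame_equal(draws1, draws2)

    def test_resampled_mean_near_species_mean(self, small_multiomics):
        tables, _, _ = small_multiomics
        table = compute_ptr(tables["rna"], tables["protein"])
        draws, _ = resample_null(table, n_genes=14, n_resamples=100, seed=1)
        for sp in draws.columns:
            vals = table.species_values(sp)
            vals = vals[np.isfinite(vals)]
            se = vals.std(ddof=1) / np.sqrt(14)
            assert abs(draws[sp].mean() - vals.mean()) < 3 * se / np.sqrt(100) * 10

    def test_too_many_genes_rejected(self, small_multiomics):
        tables, _, _ = small_multiomics
        table = compute_ptr(tables["rna"], tables["protein"])
        with pytest.raises(ValueError):
            resample_null(table, n_genes=10_000)


class TestPatternRecovery:
    def test_c4_ptr_lower_in_c4_species(self):
        """F=10, G=3 drives the C4-set PTR down by G/F in the C4-type species;
        the gated ANOVA + rank-sum + BH pipeline must flag it against every
        non-C4 species while the untouched photorespiratory set stays flat."""
        from c4omics.simulate import SimConfig
        hits_c4, hits_resp = 0, 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SimConfig(seed=100 + seed, n_genes=600)
            tables, gene_sets, _ = gen_multiomics(cfg)
            table = compute_ptr(tables["rna"], tables["protein"])
            species = sorted(table.data["species"].unique())

            def set_comp(name):
                by_sp = {sp: table.species_values(sp, gene_sets[name].members).to_numpy()
                         for sp in species}
                return compare_groups(by_sp)

            comp = set_comp("c4")
            sig = all(
                comp.pair("Ftri", sp)["p_adj"] < 0.05 and not comp.gated
                for sp in species if sp != "Ftri"
            )
            medians = {sp: np.median(table.species_values(sp, gene_sets["c4"].members))
                       for sp in species}
            direction = all(medians["Ftri"] < medians[sp] for sp in species if sp != "Ftri")
            if sig and direction:
                hits_c4 += 1
            comp = set_comp("photorespiratory")
            flat = comp.gated or all(
                comp.pair("Ftri", sp)["p_adj"] >= 0.05
                for sp in species if sp != "Ftri"
            )
            if flat:
                hits_resp += 1
        assert hits_c4 >= n_seeds - 1
        assert hits_resp >= n_seeds - 1
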