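"""Window partition/variance shares, GRAMMAR-GC, region test, LD r2."""

import numpy as np
import pytest
from scipy import stats

import fattygs as fg
from fattygs.genio import GenotypeMatrix


def _geno(dosage, chrom=None, bp=None):
    dosage = np.asarray(dosage, dtype=np.float32)
    n, m = dosage.shape
    return GenotypeMatrix(
        ids=[f"i{k}" for k in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        chrom=np.ones(m, dtype=int) if chrom is None else np.asarray(chrom),
        bp=np.arange(1, m + 1) if bp is None else np.asarray(bp),
        dosage=dosage,
    )


class TestWindowPartition:
    def test_one_based_boundary(self):
        geno = _geno(np.zeros((2, 2)), bp=[100_000, 100_001])
        labels, windows = fg.window_partition(geno)
        assert labels[0] != labels[1]
        assert windows[labels[0]][1:3] == (1, 100_000)
        assert windows[labels[1]][1:3] == (100_001, 200_000)

    def test_spread_snps_get_distinct_windows(self):
        geno = _geno(np.zeros((2, 3)), bp=[50_000, 150_000, 250_000])
        labels, windows = fg.window_partition(geno)
        assert len(windows) == 3 and len(set(labels)) == 3

    def test_clustered_snps_share_a_window(self):
        geno = _geno(np.zeros((2, 5)), bp=[1_000, 20_000, 50_000, 80_000, 99_000])
        labels, windows = fg.window_partition(geno)
        assert len(windows) == 1 and windows[0][3] == 5


class TestWindowVariance:
    def test_single_qtl_dominates_its_window(self, small_sim, small_posterior):
        geno = small_sim["geno"]
        labels, windows = fg.window_partition(geno)
        res = fg.window_variance_proportions(small_posterior, geno, (labels, windows))
        props = np.array([w.var_proportion for w in res])
        qtl_windows = set(labels[small_sim["truth"].qtl_indices])
        assert props[list(qtl_windows)].sum() > 0.9

    def test_shares_sum_to_one(self, small_sim, small_posterior):
        res = fg.window_variance_proportions(small_posterior, small_sim["geno"])
        assert sum(w.var_proportion for w in res) == pytest.approx(1.0, abs=1e-6)

    def test_two_equal_qtl_split_the_variance(self):
        rng = np.random.default_rng(21)
        n = 800
        d = rng.binomial(2, 0.5, size=(n, 4)).astype(np.float32)
        geno = _geno(d, bp=[10, 20, 500_000, 500_010])
        alpha = np.array([1.0, 0.0, 1.0, 0.0])
        post = _fixed_posterior(geno, alpha)
        res = fg.window_variance_proportions(post, geno)
        props = sorted(w.var_proportion for w in res)
        assert props[-1] == pytest.approx(0.5, abs=0.1)
        assert props[-2] == pytest.approx(0.5, abs=0.1)

    def test_all_null_samples_give_zero_candidates(self):
        geno = _geno(np.random.default_rng(5).binomial(2, 0.4, (50, 6)).astype(np.float32))
        post = _fixed_posterior(geno, np.zeros(6))
        with pytest.warns(UserWarning):
            res = fg.window_variance_proportions(post, geno)
        assert fg.candidate_windows(res) == []


def _fixed_posterior(geno, alpha):
    samples = np.tile(alpha, (10, 1))
    return fg.BayesBPosterior(
        snp_ids=geno.snp_ids, alpha_hat=alpha, alpha_sd=np.zeros_like(alpha),
        delta_freq=(alpha != 0).astype(float), alpha_samples=samples,
        gv_samples=samples @ geno.imputed().T, sigma_e2_chain=np.ones(10),
        u_hat=0.0, accept_rate=1.0, n_retained=10,
        config=fg.BayesBConfig(n_iter=2, burn_in=1),
    )


class TestGrammar:
    def test_identity_kinship_matches_ols(self):
        # with G = I the two-stage scan reduces to simple regression
        rng = np.random.default_rng(30)
        n, m = 200, 40
        d = rng.binomial(2, 0.4, size=(n, m)).astype(np.float32)
        geno = _geno(d)
        y = rng.normal(size=n)
        adj = fg.AdjustedPhenotype(geno.ids, y, "y")
        grm = fg.GRM(ids=geno.ids, G=np.eye(n), denom=1.0)
        vc = fg.VarComp(traits=("y",), sigma_a2=0.3, sigma_e2=0.7, h2=0.3)
        res = fg.grammar_gc_scan(adj, geno, grm, vc)
        # residuals reduce to centered y scaled by a constant; score-test p
        # equals the OLS score-test p computed directly
        yc = y - y.mean()
        zc = geno.centered()
        chi2 = (zc.T @ yc) ** 2 / (np.sum(zc * zc, axis=0) * np.mean(yc**2))
        p_ols = stats.chi2.sf(chi2, 1)
        np.testing.assert_allclose(res.table["p_raw"], p_ols, atol=1e-6)

    def test_planted_qtl_attains_minimum_p(self):
        hits = 0
        for seed in range(5):
            cfg = fg.SimConfig(n_individuals=500, n_chromosomes=2, snps_per_chrom=200,
                               n_qtl=1, target_h2=0.3, seed=800 + seed)
            geno = fg.simulate_genotypes(cfg)
            table, truth = fg.simulate_phenotypes(geno, cfg)
            adj = fg.adjust_phenotypes(table, "sim_trait")
            res = fg.grammar_gc_scan(adj, geno, fg.build_grm(geno))
            top = int(res.table["p_gc"].idxmin())
            z = geno.centered()
            q = truth.qtl_indices[0]
            r2 = np.corrcoef(z[:, top], z[:, q])[0, 1] ** 2
            hits += (top == q) or (r2 > 0.8)
        assert hits >= 4

    def test_gc_preserves_ranking(self, small_sim, small_varcomp):
        res = fg.grammar_gc_scan(small_sim["adj"], small_sim["geno"],
                                 small_sim["grm"], small_varcomp)
        t = res.table.sort_values("chi2")
        assert np.all(np.diff(t["p_gc"]) <= 1e-12)

    def test_gc_conservative_when_lambda_above_one(self, small_sim, small_varcomp):
        res = fg.grammar_gc_scan(small_sim["adj"], small_sim["geno"],
                                 small_sim["grm"], small_varcomp)
        if res.lambda_gc > 1:
            assert np.all(res.table["p_gc"] >= res.table["p_raw"] - 1e-12)
        else:
            assert np.all(res.table["p_gc"] <= res.table["p_raw"] + 1e-12)

    def test_dense_panel_null_lambda_near_one(self):
        # the dense-panel regime (M >> n * h2): raw statistics nearly calibrated
        cfg = fg.SimConfig(n_individuals=250, n_chromosomes=5, snps_per_chrom=400,
                           ld_decay_rho=0.5, n_qtl=2000, target_h2=0.3, seed=901)
        geno = fg.simulate_genotypes(cfg)
        table, _ = fg.simulate_phenotypes(geno, cfg)
        adj = fg.adjust_phenotypes(table, "sim_trait")
        res = fg.grammar_gc_scan(adj, geno, fg.build_grm(geno))
        assert 0.8 <= res.lambda_gc <= 1.2


class TestThresholds:
    def test_published_counts(self):
        bonf, sugg = fg.significance_thresholds(595_715, 163_473)
        assert bonf == pytest.approx(8.39e-8, rel=5e-3)
        assert sugg == pytest.approx(3.06e-7, rel=5e-3)

    def test_single_snp(self):
        assert fg.significance_thresholds(1, 1) == (0.05, 0.05)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            fg.significance_thresholds(0, 10)


class TestRegionTest:
    def test_single_snp_region_matches_marginal(self, small_sim, small_varcomp):
        geno = small_sim["geno"]
        q = small_sim["truth"].qtl_indices[0]
        region = geno.subset(snps=[int(q)])
        res = fg.region_score_test(small_sim["adj"], region, small_sim["grm"],
                                   small_varcomp)
        marginal = res.snp_p_values[0]
        assert res.p_value == pytest.approx(marginal, rel=0.10)

    def test_qtl_window_is_significant(self):
        # a dense panel (so the polygenic stage absorbs little of the QTL)
        # with low-frequency variants, the regime beta(1, 25) weights target
        cfg = fg.SimConfig(n_individuals=1000, n_chromosomes=5, snps_per_chrom=400,
                           maf_range=(0.05, 0.12), seed=33)
        geno = fg.simulate_genotypes(cfg)
        p = geno.allele_freq()
        maf = np.minimum(p, 1 - p)
        q = int(np.argmin(np.abs(maf - 0.07)))  # a typical low-frequency causal SNP
        rng = np.random.default_rng(33)
        zq = geno.centered()[:, q]
        bv = zq * np.sqrt(0.3 / np.var(zq))
        y = bv + rng.normal(0, np.sqrt(0.7), size=geno.n_individuals)
        adj = fg.AdjustedPhenotype(geno.ids, y, "planted")
        grm = fg.build_grm(geno)
        labels, _ = fg.window_partition(geno)
        res = fg.region_score_test(adj, geno.subset(snps=labels == labels[q]), grm)
        assert res.p_value < 1e-4

    def test_null_regions_roughly_uniform(self):
        pvals = []
        for seed in range(25):
            cfg = fg.SimConfig(n_individuals=250, n_chromosomes=2, snps_per_chrom=120,
                               n_qtl=240, target_h2=0.3, seed=950 + seed)
            geno = fg.simulate_genotypes(cfg)
            table, _ = fg.simulate_phenotypes(geno, cfg)
            adj = fg.adjust_phenotypes(table, "sim_trait")
            grm = fg.build_grm(geno)
            region = geno.subset(snps=np.arange(10))
            pvals.append(fg.region_score_test(adj, region, grm).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_region_p_one(self, small_sim, small_varcomp):
        n = small_sim["geno"].n_individuals
        mono = _geno(np.full((n, 2), 2.0, dtype=np.float32))
        mono.ids = small_sim["geno"].ids
        with pytest.warns(UserWarning):
            res = fg.region_score_test(small_sim["adj"], mono, small_sim["grm"],
                                       small_varcomp)
        assert res.p_value == 1.0

    def test_burden_variant_runs(self, small_sim, small_varcomp):
        region = small_sim["geno"].subset(snps=np.arange(5))
        res = fg.region_score_test(small_sim["adj"], region, small_sim["grm"],
                                   small_varcomp, method="burden")
        assert 0 < res.p_value <= 1


class TestPairwiseR2:
    def test_duplicated_snp_gives_perfect_ld(self):
        rng = np.random.default_rng(40)
        col = rng.binomial(2, 0.4, size=500).astype(np.float32)
        r2 = fg.pairwise_r2(_geno(np.column_stack([col, col])))
        assert r2[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(41)
        d = rng.binomial(2, 0.3, size=(2000, 8)).astype(np.float32)
        r2 = fg.pairwise_r2(_geno(d))
        off = r2[np.triu_indices(8, 1)]
        assert off.mean() < 0.01

    def test_complete_coupling_haplotypes(self):
        # D' = 1 with p = q = 0.5: dosages identical by construction -> r2 = 1
        rng = np.random.default_rng(42)
        h1 = rng.binomial(1, 0.5, size=(400, 2)).sum(axis=1)
        d = np.column_stack([h1, h1]).astype(np.float32)
        r2 = fg.pairwise_r2(_geno(d))
        assert r2[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matrix_properties(self, small_sim):
        r2 = fg.pairwise_r2(small_sim["geno"].subset(snps=np.arange(10)))
        assert np.allclose(r2, r2.T)
        assert np.all((r2 >= 0) & (r2 <= 1.0 + 1e-12))
        assert np.allclose(np.diag(r2), 1.0)

    def test_monomorphic_column_zero_ld(self):
        rng = np.random.default_rng(43)
        poly = rng.binomial(2, 0.4, size=300).astype(np.float32)
        mono = np.full(300, 2.0, dtype=np.float32)
        r2 = fg.pairwise_r2(_geno(np.column_stack([poly, mono])))
        assert r2[0, 1] == 0.0
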