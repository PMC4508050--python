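"""QC filters, relatedness, PCA covariates and the association scan."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from gwasnet.data import GenotypeDataset
from gwasnet.glm import CHI2_NULL_MEDIAN, genomic_lambda, logistic_scan, score_scan
from gwasnet.qc import (QCThresholds, differential_missingness_test,
                        filter_samples, filter_snp_missingness, hwe_exact_test,
                        ibd_estimate, ld_prune, maf_filter, pca_covariates,
                        pi_hat_matrix, run_qc, select_pcs_by_lambda)
from gwasnet.simulate import SimulationConfig, _simulate_haplotypes, simulate_cohort


def make_dataset(genotypes, phenotype=None, study=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if phenotype is None:
        phenotype = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
    snp = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)], "chrom": "1",
        "pos": np.arange(1, m + 1) * 100, "a1": "A", "a2": "B"})
    return GenotypeDataset(
        genotypes=genotypes, phenotype=np.asarray(phenotype),
        study_indicator=np.array(["st"] * n) if study is None else study,
        snp_table=snp, sample_ids=np.array([f"i{i}" for i in range(n)]))


def random_genotypes(rng, n, m, maf=0.3):
    return rng.binomial(2, maf, size=(n, m)).astype(np.int8)


class TestSnpMissingness:
    def test_boundary_cases(self):
        rng = np.random.default_rng(0)
        g = random_genotypes(rng, 100, 3)
        g[:6, 1] = -1                      # 6% missing -> removed
        g[:5, 2] = -1                      # exactly 5% -> retained
        data = make_dataset(g)
        out, removed = filter_snp_missingness(data, QCThresholds())
        assert removed == ["s1"]
        assert list(out.snp_ids) == ["s0", "s2"]

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(1)
        g = random_genotypes(rng, 500, 1000)
        mask = rng.random(g.shape) < 0.05
        g[mask] = -1
        data = make_dataset(g)
        out, removed = filter_snp_missingness(data, QCThresholds())
        brute = {f"s{j}" for j in range(1000)
                 if (g[:, j] == -1).sum() / 500 > 0.05}
        assert set(removed) == brute

    def test_all_removed_raises(self):
        g = np.full((10, 3), -1, dtype=np.int8)
        g[0] = 1
        with pytest.raises(ValueError, match="all SNPs removed"):
            filter_snp_missingness(make_dataset(g), QCThresholds())


class TestSampleFilter:
    def test_identical_samples_zero_sd_removes_none(self):
        g = np.tile(np.array([0, 1, 2, 1, 0], dtype=np.int8), (10, 1))
        out, removed, stats = filter_samples(make_dataset(g), QCThresholds())
        assert removed == []
        assert stats["het_sd"] == 0.0

    def test_high_missingness_sample_removed(self):
        rng = np.random.default_rng(2)
        g = random_genotypes(rng, 50, 100)
        g[7, :10] = -1                     # 10% missing
        out, removed, _ = filter_samples(make_dataset(g), QCThresholds())
        assert "i7" in removed

    def test_het_outlier_flagged(self):
        rng = np.random.default_rng(3)
        g = random_genotypes(rng, 500, 400, maf=0.3)
        het = (g == 1).mean(axis=1)
        mu, sd = het.mean(), het.std()
        target = min(mu + 4 * sd, 1.0)
        n_het = int(round(target * 400))
        row = np.zeros(400, dtype=np.int8)
        row[:n_het] = 1
        g[123] = row
        data = make_dataset(g)
        out, removed, _ = filter_samples(data, QCThresholds())
        assert "i123" in removed
        # independent recount: every removed sample violates a rule
        het_all = data.heterozygosity_rate()
        mu2, sd2 = het_all.mean(), het_all.std()
        miss = data.sample_missing_rate()
        for sid in removed:
            i = int(sid[1:])
            assert miss[i] > 0.05 or abs(het_all[i] - mu2) > 3 * sd2


class TestLdPrune:
    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(4)
        data = make_dataset(random_genotypes(rng, 400, 60))
        assert len(ld_prune(data)) == 60

    def test_duplicated_snp_one_retained(self):
        rng = np.random.default_rng(5)
        g = random_genotypes(rng, 200, 10)
        g[:, 7] = g[:, 3]
        kept = ld_prune(make_dataset(g))
        assert ("s3" in kept) != ("s7" in kept)
        assert len(kept) == 9

    def test_perfect_ld_blocks_collapse_to_one_each(self):
        rng = np.random.default_rng(6)
        base = random_genotypes(rng, 300, 10)
        g = np.repeat(base, 20, axis=1)            # 10 blocks of 20 copies
        data = make_dataset(g)
        kept = ld_prune(data, r2_max=0.2, window=50, step=5)
        assert len(kept) == 10
        # brute-force: no retained pair within a window exceeds the cap
        idx = data.snp_index(kept)
        X = data.dosage()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if idx[b] - idx[a] < 50:
                    r = np.corrcoef(X[:, idx[a]], X[:, idx[b]])[0, 1]
                    assert r * r <= 0.2 + 1e-9

    def test_window_too_small_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            ld_prune(make_dataset(random_genotypes(rng, 50, 10)), window=1)


class TestIBD:
    def test_self_pi_hat_exactly_one(self):
        rng = np.random.default_rng(8)
        data = make_dataset(random_genotypes(rng, 30, 500))
        pi = pi_hat_matrix(data)
        assert np.all(np.diag(pi) == 1.0)

    def test_duplicate_pair_near_one_and_removed(self):
        rng = np.random.default_rng(9)
        g = random_genotypes(rng, 40, 2000)
        g[11] = g[5]
        g[11, :20] = -1                    # lower call rate member
        data = make_dataset(g)
        pi = pi_hat_matrix(data)
        assert pi[5, 11] > 0.9
        pairs, removed = ibd_estimate(data, list(data.snp_ids), QCThresholds())
        assert "i11" in removed and "i5" not in removed

    def test_unrelated_pair_near_zero(self):
        rng = np.random.default_rng(10)
        data = make_dataset(random_genotypes(rng, 30, 5000))
        pi = pi_hat_matrix(data)
        off = pi[np.triu_indices(30, k=1)]
        assert np.all(off < 0.1)

    def test_parent_offspring_near_half(self):
        cfg = SimulationConfig(n_cases=10, n_controls=10, n_snps=5000,
                               n_genes=500, ld_rho=0.0, planted_or=1.0,
                               missing_rate=0.0, snp_keep_fraction=1.0, seed=11)
        rng = np.random.default_rng(12)
        from scipy.special import ndtri
        maf = np.random.default_rng([cfg.seed, 101]).uniform(0.1, 0.5, 5000)
        thr = ndtri(maf)
        # 2 related + 40 unrelated samples (stable allele-frequency estimates)
        hap = _simulate_haplotypes(cfg, rng, 86, thr)
        parent = hap[0].astype(np.int8) + hap[1]
        child = hap[0].astype(np.int8) + hap[2]   # shares one haplotype
        others = hap[6:].reshape(40, 2, -1).sum(axis=1).astype(np.int8)
        g = np.vstack([parent, child, others])
        data = make_dataset(g)
        pi = pi_hat_matrix(data)
        assert abs(pi[0, 1] - 0.5) < 0.1


class TestDifferentialMissingness:
    def test_no_missing_gives_p_one(self):
        rng = np.random.default_rng(13)
        data = make_dataset(random_genotypes(rng, 100, 5))
        assert np.all(differential_missingness_test(data) == 1.0)

    def test_case_only_missingness_detected(self):
        rng = np.random.default_rng(14)
        g = random_genotypes(rng, 1000, 3)
        pheno = np.r_[np.ones(500, dtype=int), np.zeros(500, dtype=int)]
        g[:250, 1] = -1                     # 50% of cases, 0% of controls
        data = make_dataset(g, pheno)
        p = differential_missingness_test(data)
        assert p[1] < 1e-5
        # agrees with a direct 2x2 chi-square computation
        a, b, c, d = 250, 250, 0, 500
        n = a + b + c + d
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert np.isclose(p[1], chi2.sf(stat, 1), rtol=1e-10)

    def test_mcar_rarely_removed(self):
        rng = np.random.default_rng(15)
        g = random_genotypes(rng, 400, 10_000)
        g[rng.random(g.shape) < 0.02] = -1
        data = make_dataset(g)
        p = differential_missingness_test(data)
        assert (p < 1e-5).sum() <= 2


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_balanced_case_matches_enumeration(self):
        # exact-integer oracle at (25, 50, 25)
        p_obs = hwe_exact_test(25, 50, 25)
        assert np.isclose(p_obs, _hwe_oracle(25, 50, 25), atol=1e-12)

    def test_all_homozygote_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_random_spot_checks_vs_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(200):
            n = int(rng.integers(1, 150))
            na = int(rng.integers(0, 2 * n + 1))
            rare = min(na, 2 * n - na)
            h = int(rng.integers(0, rare + 1))
            if (h - rare) % 2:
                h = max(h - 1, rare % 2)
            naa = (na - h) // 2
            nbb = n - naa - h
            assert np.isclose(hwe_exact_test(naa, h, nbb),
                              _hwe_oracle(naa, h, nbb), atol=1e-12)


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    rare = min(na, 2 * n - na)
    if rare == 0:
        return 1.0
    # conditional weight of het count h: multinomial(n; hom_r, h, hom_c) * 2^h
    weights = {h: (math.factorial(n) * 2 ** h)
               // (math.factorial((rare - h) // 2)
                   * math.factorial(h)
                   * math.factorial(n - h - (rare - h) // 2))
               for h in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    acc = sum(w for w in weights.values() if w <= w_obs)
    return acc / total


class TestPCA:
    def test_scores_orthonormal(self):
        rng = np.random.default_rng(17)
        data = make_dataset(random_genotypes(rng, 120, 300))
        pcs = pca_covariates(data, list(data.snp_ids), n_pcs=10)
        gram = pcs.T @ pcs
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_pc1_separates_subpopulations(self):
        rng = np.random.default_rng(18)
        m = 600
        maf_a = rng.uniform(0.1, 0.5, m)
        shift = rng.choice([-0.12, 0.12], m)
        maf_b = np.clip(maf_a + shift, 0.05, 0.95)
        ga = rng.binomial(2, maf_a, size=(150, m)).astype(np.int8)
        gb = rng.binomial(2, maf_b, size=(150, m)).astype(np.int8)
        data = make_dataset(np.vstack([ga, gb]))
        pcs = pca_covariates(data, list(data.snp_ids), n_pcs=5)
        pop = np.r_[np.zeros(150), np.ones(150)]
        r = np.corrcoef(pcs[:, 0], pop)[0, 1]
        assert abs(r) > 0.9

    def test_rank_limited_returns_fewer_pcs(self):
        rng = np.random.default_rng(19)
        data = make_dataset(random_genotypes(rng, 8, 50))
        with pytest.warns(UserWarning, match="rank"):
            pcs = pca_covariates(data, list(data.snp_ids), n_pcs=20)
        assert pcs.shape[1] < 20


class TestLambdaScreening:
    def test_lambda_definition_on_chi2_draws(self):
        rng = np.random.default_rng(20)
        draws = rng.chisquare(1, size=10_000)
        assert abs(genomic_lambda(draws) - 1.0) < 0.02
        assert np.isclose(CHI2_NULL_MEDIAN, 0.4549, atol=1e-4)

    def test_homogeneous_population_all_lambdas_near_one(self):
        rng = np.random.default_rng(21)
        data = make_dataset(random_genotypes(rng, 300, 1500))
        pcs = pca_covariates(data, list(data.snp_ids), n_pcs=5)
        chosen, lambdas = select_pcs_by_lambda(data, pcs, n_select=3)
        assert np.all(np.abs(lambdas - 1.0) < 0.12)
        assert chosen == sorted(chosen) and len(chosen) == 3

    def test_confounding_pc_gives_smallest_lambda(self):
        rng = np.random.default_rng(22)
        m = 2000
        maf_a = rng.uniform(0.15, 0.5, m)
        maf_b = np.clip(maf_a + rng.choice([-0.1, 0.1], m), 0.05, 0.95)
        na, nb = 300, 300
        g = np.vstack([rng.binomial(2, maf_a, size=(na, m)),
                       rng.binomial(2, maf_b, size=(nb, m))]).astype(np.int8)
        # phenotype confounded with ancestry: 70% of cases from pool B
        pheno = np.zeros(na + nb, dtype=int)
        pheno[rng.choice(na, 90, replace=False)] = 1
        pheno[na + rng.choice(nb, 210, replace=False)] = 1
        data = make_dataset(g, pheno)
        raw = score_scan(data.dosage(), data.phenotype)
        lam_raw = genomic_lambda(raw["chisq"])
        assert lam_raw > 1.15
        pcs = pca_covariates(data, list(data.snp_ids), n_pcs=5)
        chosen, lambdas = select_pcs_by_lambda(data, pcs, n_select=1)
        pop = np.r_[np.zeros(na), np.ones(nb)]
        ancestry_pc = int(np.argmax([abs(np.corrcoef(pcs[:, j], pop)[0, 1])
                                     for j in range(5)]))
        assert chosen == [ancestry_pc]
        assert lambdas[ancestry_pc] < lam_raw - 0.1


class TestLogisticScan:
    def test_matches_statsmodels_per_snp(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(23)
        n, m = 300, 20
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        cov = rng.standard_normal((n, 2))
        eta = 0.4 * G[:, 0] - 0.3 * cov[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = logistic_scan(G, y, covariates=cov)
        for j in range(m):
            X = np.column_stack([np.ones(n), cov, G[:, j]])
            fit = sm.Logit(y, X).fit(disp=0)
            assert np.isclose(res["beta"][j], fit.params[-1], atol=1e-5)
            assert np.isclose(res["se"][j], fit.bse[-1], rtol=1e-4)

    def test_missing_genotypes_excluded_per_snp(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(24)
        n = 400
        G = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        G[rng.random((n, 3)) < 0.1] = np.nan
        y = (rng.random(n) < 0.5).astype(float)
        res = logistic_scan(G, y)
        j = 1
        ok = ~np.isnan(G[:, j])
        fit = sm.Logit(y[ok], np.column_stack([np.ones(ok.sum()), G[ok, j]])).fit(disp=0)
        assert np.isclose(res["beta"][j], fit.params[-1], atol=1e-5)

    def test_monomorphic_snp_flagged_not_crashing(self):
        rng = np.random.default_rng(25)
        G = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        G[:, 1] = 1.0
        y = (rng.random(100) < 0.5).astype(float)
        res = logistic_scan(G, y)
        assert not res["converged"][1]
        assert np.isnan(res["p"][1])

    def test_power_at_planted_snps(self):
        cfg = SimulationConfig(n_cases=1000, n_controls=1000, n_snps=1000,
                               n_genes=100, planted_or=1.6,
                               maf_range=(0.3, 0.3), n_planted_modules=2,
                               planted_module_size=4, missing_rate=0.0,
                               snp_keep_fraction=1.0, seed=26)
        from gwasnet.simulate import (causal_snp_indices, plant_modules,
                                      simulate_ppi)
        ppi = simulate_ppi(cfg.n_genes, 3, seed=cfg.seed)
        planted = [g for mod in plant_modules(ppi, cfg) for g in mod]
        data = simulate_cohort(cfg, 0, planted)
        res = logistic_scan(data.dosage(impute=False), data.phenotype)
        causal = causal_snp_indices(cfg, planted)
        assert np.median(res["p"][causal]) < 1e-3

    def test_wald_close_to_score_test(self):
        rng = np.random.default_rng(27)
        G = rng.binomial(2, 0.3, size=(800, 200)).astype(float)
        y = (rng.random(800) < 0.5).astype(float)
        wald = logistic_scan(G, y)["chisq"]
        score = score_scan(G, y)["chisq"]
        informative = score > 0.5
        ratio = wald[informative] / score[informative]
        assert np.all(np.abs(ratio - 1) < 0.1)


class TestNullCalibration:
    def test_null_pvalues_uniform(self, null_scan):
        _, scan = null_scan
        p = scan["p"][np.isfinite(scan["p"])]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_null_lambda_near_one(self, null_scan):
        _, scan = null_scan
        lam = genomic_lambda(scan["chisq"])
        assert 0.95 < lam < 1.05


class TestPipeline:
    def test_filter_order_and_idempotence(self):
        # stable regime: enough SNPs for tight PI_HAT estimates and low
        # missingness so no SNP sits on the 5% boundary when denominators
        # change after a sample removal
        cfg = SimulationConfig(n_cases=150, n_controls=150, n_snps=10_000,
                               n_genes=1000, missing_rate=0.01,
                               snp_keep_fraction=1.0, seed=30)
        data = simulate_cohort(cfg, 0)
        thr = QCThresholds()
        res1 = run_qc(data, thr)
        res2 = run_qc(res1.data, thr)
        assert np.array_equal(res1.data.genotypes, res2.data.genotypes)
        assert list(res1.data.sample_ids) == list(res2.data.sample_ids)
        assert list(res1.data.snp_ids) == list(res2.data.snp_ids)
        rep = res1.report
        assert rep["n_snps_out"] <= rep["n_snps_in"]
        assert res1.lam > 0

    def test_maf_filter_threshold(self):
        rng = np.random.default_rng(29)
        g = np.column_stack([
            rng.binomial(2, 0.30, 400),
            rng.binomial(2, 0.02, 400),     # rare -> removed
            rng.binomial(2, 0.50, 400),
        ]).astype(np.int8)
        data = make_dataset(g)
        keep = maf_filter(data, QCThresholds())
        assert keep[0] and keep[2] and not keep[1]
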