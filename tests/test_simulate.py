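import numpy as np
import pytest
from scipy import stats

import epitwas as et


def _adjacent_corr(dosages, lag=1):
    cs = []
    for j in range(dosages.shape[1] - lag):
        a, b = dosages[:, j], dosages[:, j + lag]
        if a.std() > 0 and b.std() > 0:
            cs.append(np.corrcoef(a, b)[0, 1])
    return np.array(cs)


class TestSimulateGenotypes:
    def test_no_ld_limit(self):
        cfg = et.SimulationConfig(n_samples=800, n_snps_per_gene=40,
                                  ld_decay=0.0, seed=1)
        G = et.simulate_genotypes(cfg)
        # independence limit: mean |cor| within sampling error 3/sqrt(n)
        assert np.abs(_adjacent_corr(G.dosages)).mean() < 3 / np.sqrt(800)

    def test_seed_determinism(self):
        cfg = et.SimulationConfig(n_samples=100, seed=42)
        a = et.simulate_genotypes(cfg)
        b = et.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_ld_decays_with_lag(self):
        """Oracle: empirical correlation of the generated haplotype chain."""
        cfg = et.SimulationConfig(n_samples=500, n_snps_per_gene=40,
                                  ld_decay=0.9, seed=2)
        G = et.simulate_genotypes(cfg)
        r2_adj = (_adjacent_corr(G.dosages, 1) ** 2).mean()
        r2_lag10 = (_adjacent_corr(G.dosages, 10) ** 2).mean()
        assert r2_adj > r2_lag10

    def test_adjacent_correlation_matches_ld_decay(self):
        cfg = et.SimulationConfig(n_samples=2000, n_snps_per_gene=60,
                                  maf_range=(0.3, 0.3), ld_decay=0.6, seed=3)
        G = et.simulate_genotypes(cfg)
        assert _adjacent_corr(G.dosages).mean() == pytest.approx(0.6, abs=0.05)

    def test_maf_within_range(self):
        cfg = et.SimulationConfig(n_samples=2000, n_snps_per_gene=50,
                                  maf_range=(0.2, 0.4), seed=4)
        G = et.simulate_genotypes(cfg)
        freqs = G.dosages.mean(axis=0) / 2
        assert (freqs > 0.12).all() and (freqs < 0.48).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            et.SimulationConfig(n_snps_per_gene=0)
        with pytest.raises(ValueError):
            et.SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            et.SimulationConfig(ld_decay=1.0)


class TestGeneArchitecture:
    def test_exact_causal_count_and_normal_effects(self):
        cfg = et.SimulationConfig(n_snps_per_gene=50, n_causal_per_gene=7, seed=5)
        G = et.simulate_genotypes(cfg)
        beta, ann = et.simulate_gene_architecture(cfg, G.snps)
        assert np.count_nonzero(beta) == 7
        assert ann.matrix.shape == (50, 1)

    def test_no_enrichment_equal_rates(self):
        cfg = et.SimulationConfig(n_snps_per_gene=40, annotation_enrichment=1.0,
                                  seed=6)
        rng = np.random.default_rng(6)
        G = et.simulate_genotypes(cfg)
        rates_c, rates_n = [], []
        for _ in range(200):
            beta, ann = et.simulate_gene_architecture(cfg, G.snps, rng=rng)
            causal = beta != 0
            rates_c.append(ann.matrix[causal, 0].mean())
            rates_n.append(ann.matrix[~causal, 0].mean())
        assert np.mean(rates_c) == pytest.approx(np.mean(rates_n), abs=0.03)

    def test_pure_null_gene(self):
        cfg = et.SimulationConfig(n_snps_per_gene=20, n_causal_per_gene=0, seed=7)
        G = et.simulate_genotypes(cfg)
        beta, _ = et.simulate_gene_architecture(cfg, G.snps)
        assert not beta.any()

    def test_enrichment_recovered_by_logistic_fit(self):
        """Oracle: direct logistic regression of causal flag on annotation."""
        import statsmodels.api as sm

        cfg = et.SimulationConfig(n_snps_per_gene=30, annotation_enrichment=5.0,
                                  seed=8)
        rng = np.random.default_rng(8)
        G = et.simulate_genotypes(cfg)
        causal, annot = [], []
        for _ in range(2000):
            beta, ann = et.simulate_gene_architecture(cfg, G.snps, rng=rng)
            causal.append(beta != 0)
            annot.append(ann.matrix[:, 0])
        y = np.concatenate(causal).astype(float)
        x = sm.add_constant(np.concatenate(annot).astype(float))
        fit = sm.Logit(y, x).fit(disp=0)
        # coefficient approximates the generative log-odds multiplier log(5)
        assert fit.params[1] == pytest.approx(np.log(5), abs=0.15)

    def test_too_many_causal_rejected(self):
        with pytest.raises(ValueError):
            et.SimulationConfig(n_snps_per_gene=5, n_causal_per_gene=6)


class TestSimulateExpression:
    def test_noiseless_limit(self, gene_block):
        G, beta, _, _ = gene_block
        y = et.simulate_expression(G, beta, 0.0)
        np.testing.assert_allclose(y, G.dosages @ beta)

    def test_null_gene_sd_matches_noise_sd(self):
        cfg = et.SimulationConfig(n_samples=5000, n_snps_per_gene=5, seed=9)
        G = et.simulate_genotypes(cfg)
        y = et.simulate_expression(G, np.zeros(5), 1.0, noise_sd=0.3, seed=9)
        assert y.std() == pytest.approx(0.3, rel=0.05)

    def test_variance_monotone_in_level(self, gene_block):
        """Oracle: var(y) = var(X beta) + level^2 * noise_sd^2, averaged over
        50 replicates per level."""
        G, beta, _, _ = gene_block
        levels = [0.1, 0.4, 0.7, 1.0]
        var_by_level = []
        for lv in levels:
            vs = [np.var(et.simulate_expression(G, beta, lv, 0.3, seed=s))
                  for s in range(50)]
            var_by_level.append(np.mean(vs))
        assert np.all(np.diff(var_by_level) > 0)
        analytic = np.var(G.dosages @ beta) + np.array(levels) ** 2 * 0.09
        np.testing.assert_allclose(var_by_level, analytic, rtol=0.1)

    def test_negative_level_rejected(self, gene_block):
        G, beta, *_ = gene_block
        with pytest.raises(ValueError):
            et.simulate_expression(G, beta, -0.5)


class TestSimulateGwasZ:
    def test_null_marginals_standard_normal(self):
        z = et.simulate_gwas_z(np.eye(4), n_reps=1250, seed=10)
        flat = np.array([r.z for gs in z for r in gs.records])
        assert stats.kstest(flat, "norm").pvalue > 0.01

    def test_lambda_zero_is_null(self):
        ld = np.array([[1, 0.3], [0.3, 1]])
        a = et.simulate_gwas_z(ld, causal_w=np.array([1.0, 0.0]), lam=0.0,
                               n_reps=3, seed=11)
        b = et.simulate_gwas_z(ld, lam=0.0, n_reps=3, seed=11)
        np.testing.assert_allclose([r.z for r in a[0].records],
                                   [r.z for r in b[0].records])

    def test_pairwise_correlation_matches_ld(self):
        """Oracle: MVN sampling check on a 2-SNP r=0.5 system."""
        ld = np.array([[1.0, 0.5], [0.5, 1.0]])
        sims = et.simulate_gwas_z(ld, n_reps=4000, seed=12)
        z = np.array([[r.z for r in gs.records] for gs in sims])
        assert np.corrcoef(z.T)[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_non_psd_repaired(self):
        bad = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        with pytest.warns(UserWarning, match="repair"):
            sims = et.simulate_gwas_z(bad, n_reps=1, seed=13)
        assert np.isfinite([r.z for r in sims[0].records]).all()


class TestDrugLibrary:
    def test_permutation_ranks(self):
        lib = et.simulate_drug_library(50, 10, seed=14)
        for c in lib.columns:
            assert sorted(lib[c]) == list(range(1, 51))

    def test_null_mean_cs_near_zero(self):
        lib = et.simulate_drug_library(100, 200, seed=15)
        q = et.QuerySignature("t", {f"g{i:04d}" for i in range(8)},
                              {f"g{i:04d}" for i in range(8, 16)})
        cs = [et.connectivity_score(q, lib[c]) for c in lib.columns]
        assert abs(np.mean(cs)) < 0.05

    def test_planted_reverser_strongly_negative(self):
        up = {f"g{i:04d}" for i in range(6)}
        down = {f"g{i:04d}" for i in range(6, 12)}
        lib = et.simulate_drug_library(
            100, 5, planted_query={"up": list(up), "down": list(down),
                                   "compound": "cmpd0002", "mode": "reverse"},
            seed=16)
        q = et.QuerySignature("t", up, down)
        assert et.connectivity_score(q, lib["cmpd0002"]) < -0.8

    def test_mimic_strength_monotone(self):
        """Oracle: direct CS computation on constructed lists."""
        up = [f"g{i:04d}" for i in range(6)]
        down = [f"g{i:04d}" for i in range(6, 12)]
        q = et.QuerySignature("t", set(up), set(down))
        means = []
        for s in (0.0, 0.5, 1.0):
            cs = []
            for seed in range(10):
                lib = et.simulate_drug_library(
                    60, 1, planted_query={"up": up, "down": down,
                                          "compound": "cmpd0000",
                                          "strength": s, "mode": "mimic"},
                    seed=seed)
                cs.append(et.connectivity_score(q, lib["cmpd0000"]))
            means.append(np.mean(cs))
        assert means[0] < means[1] <= means[2]

    def test_planted_set_too_large_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            et.simulate_drug_library(
                10, 1, planted_query={"up": [f"g{i:04d}" for i in range(11)],
                                      "compound": "cmpd0000"}, seed=0)
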