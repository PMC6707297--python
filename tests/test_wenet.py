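import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epitwas as et
from epitwas._solver import cd_single, enet_objective, standardize
from epitwas.io_formats import Gene, GenotypeMatrix, Snp


def prox_grad_enet(Xs, yc, v, alpha, lam, n_iter=100_000, tol=1e-13):
    """Independent oracle: FISTA on the weighted elastic-net objective.

    Shares nothing with the coordinate-descent code path beyond the objective
    definition.
    """
    n, p = Xs.shape
    L = np.linalg.eigvalsh(Xs.T @ Xs / n).max() + lam * (1 - alpha) * v.max() + 1e-12
    step = 1.0 / L
    beta = np.zeros(p)
    zeta = beta.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = -Xs.T @ (yc - Xs @ zeta) / n + lam * (1 - alpha) * v * zeta
        u = zeta - step * grad
        thr = step * lam * alpha * v
        new = np.sign(u) * np.maximum(np.abs(u) - thr, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        zeta = new + (t - 1) / t_new * (new - beta)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta, t = new, t_new
    return beta


def _instance(rng, n=50, p=10):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: p // 3] = rng.standard_normal(p // 3)
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestCoordinateDescent:
    def test_matches_proximal_gradient_oracle(self):
        """With uniform penalty factors, CD coefficients agree with an
        independent FISTA solver within 1e-6 on 20 random instances."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            X, y = _instance(rng)
            Xs, _, _ = standardize(X)
            yc = y - y.mean()
            v = np.ones(X.shape[1])
            lam = rng.uniform(0.01, 0.5)
            alpha = rng.uniform(0.1, 1.0)
            b_cd, _, conv = cd_single(Xs, yc, v, alpha, lam, tol=1e-12,
                                      max_iter=10_000)
            assert conv
            b_pg = prox_grad_enet(Xs, yc, v, alpha, lam)
            np.testing.assert_allclose(b_cd, b_pg, atol=1e-6)

    def test_matches_oracle_with_penalty_factors(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X, y = _instance(rng)
            Xs, _, _ = standardize(X)
            yc = y - y.mean()
            v = rng.uniform(0.1, 1.0, X.shape[1])
            b_cd, _, _ = cd_single(Xs, yc, v, 0.5, 0.1, tol=1e-12,
                                   max_iter=10_000)
            b_pg = prox_grad_enet(Xs, yc, v, 0.5, 0.1)
            np.testing.assert_allclose(b_cd, b_pg, atol=1e-6)

    def test_objective_monotone_per_sweep(self):
        rng = np.random.default_rng(2)
        X, y = _instance(rng, n=80, p=15)
        fit = et.fit_weighted_enet(X, y, np.ones(15), lam=0.05)
        trace = np.array(fit.objective_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_full_shrinkage_at_large_lambda(self):
        rng = np.random.default_rng(3)
        X, y = _instance(rng)
        fit = et.fit_weighted_enet(X, y, np.ones(10), lam=1e6)
        assert not fit.coef.any()
        np.testing.assert_allclose(fit.predict(X), y.mean())

    def test_duplicate_snp_low_penalty_copy_preferred(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(2, 0.4, 200).astype(float)
        X = np.column_stack([x, x])
        y = x + rng.standard_normal(200) * 0.1
        fit = et.fit_weighted_enet(X, y, np.array([0.1, 1.0]), lam=0.2)
        assert abs(fit.coef[0]) >= abs(fit.coef[1])

    def test_constant_y_gives_intercept_only(self):
        X = np.random.default_rng(5).standard_normal((30, 4))
        fit = et.fit_weighted_enet(X, np.full(30, 2.5), np.ones(4))
        assert not fit.coef.any()
        assert fit.intercept == pytest.approx(2.5)

    def test_invalid_penalty_factors_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            et.fit_weighted_enet(X, np.zeros(10), np.array([0.5, 1.5]))

    def test_column_order_invariance(self):
        rng = np.random.default_rng(6)
        X, y = _instance(rng, n=60, p=8)
        v = rng.uniform(0.2, 1.0, 8)
        fit = et.fit_weighted_enet(X, y, v, lam=0.05, tol=1e-12)
        perm = rng.permutation(8)
        fit_p = et.fit_weighted_enet(X[:, perm], y, v[perm], lam=0.05, tol=1e-12)
        np.testing.assert_allclose(fit_p.coef, fit.coef[perm], atol=1e-8)


class TestNestedCv:
    def test_noiseless_signal_recovered(self):
        cfg = et.SimulationConfig(n_samples=500, n_snps_per_gene=20,
                                  n_causal_per_gene=1, effect_sd=0.5, seed=7)
        G = et.simulate_genotypes(cfg)
        beta, _ = et.simulate_gene_architecture(cfg, G.snps)
        y = G.dosages @ beta  # no noise
        _, perf = et.nested_cv_train(G.dosages, y, np.ones(20), seed=0)
        assert perf.r2_cv > 0.95

    def test_null_gene_calibration(self):
        """Oracle: null-simulation calibration of perf_p across 300 genes."""
        rng = np.random.default_rng(8)
        r2s, ps = [], []
        for _ in range(300):
            X = rng.binomial(2, 0.3, (60, 8)).astype(float)
            y = rng.standard_normal(60)
            _, perf = et.nested_cv_train(X, y, np.ones(8), n_lambda=30,
                                         seed=int(rng.integers(1 << 30)))
            r2s.append(perf.r2_cv)
            ps.append(perf.perf_p)
        assert np.mean(r2s) < 0.05
        # one-sided p should not pile up near 0 under the null
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_r2_decreases_with_noise_level(self):
        cfg = et.SimulationConfig(n_samples=300, n_snps_per_gene=15,
                                  effect_sd=0.2, seed=9)
        G = et.simulate_genotypes(cfg)
        beta, _ = et.simulate_gene_architecture(cfg, G.snps)
        r2 = []
        for level in (0.1, 0.5, 1.0):
            vals = []
            for rep in range(5):
                y = et.simulate_expression(G, beta, level, seed=100 + rep)
                _, perf = et.nested_cv_train(G.dosages, y, np.ones(15),
                                             n_lambda=40, seed=1)
                vals.append(perf.r2_cv)
            r2.append(np.mean(vals))
        assert r2[0] > r2[1] > r2[2]

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError, match="25"):
            et.nested_cv_train(np.zeros((10, 2)), np.zeros(10), np.ones(2))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(10)
        X, y = _instance(rng, n=100, p=10)
        f1, p1 = et.nested_cv_train(X, y, np.ones(10), seed=3)
        f2, p2 = et.nested_cv_train(X, y, np.ones(10), seed=3)
        np.testing.assert_array_equal(f1.coef, f2.coef)
        assert p1.r2_cv == p2.r2_cv


def _panel_to_matrices(panel):
    """Stack per-gene blocks into joint genotype/expression containers."""
    all_snps, cols = [], []
    for g in panel:
        all_snps.extend(g["G"].snps)
        cols.append(g["G"].dosages)
    G = GenotypeMatrix(np.hstack(cols), all_snps, panel[0]["G"].samples)
    genes = [Gene(g["gene_id"], g["G"].snps[0].chrom, g["G"].snps[0].pos)
             for g in panel]
    E = et.ExpressionMatrix(np.column_stack([g["y"] for g in panel]), genes,
                            panel[0]["G"].samples)
    return G, E


@pytest.fixture(scope="module")
def mini_panel():
    cfg = et.SimulationConfig(n_samples=150, n_snps_per_gene=10,
                              n_causal_per_gene=2, effect_sd=0.4, seed=11)
    return et.simulate_gene_panel(cfg, 10, seed=11, level=0.5)


class TestTrainTissueModels:
    def test_absent_rescaler_equals_identity_rescaler(self, mini_panel):
        G, E = _panel_to_matrices(mini_panel)
        priors = pd.DataFrame({
            "gene_id": [g["gene_id"] for g in mini_panel for _ in g["G"].snps],
            "snp_id": [s.id for g in mini_panel for s in g["G"].snps],
            "prior": 0.5,
        })
        ident = et.BezierRescaler(w_min=1.0, x1=0.5, y1=1.0)
        db_none, perf_none = et.train_tissue_models(G, E, None, None, seed=1,
                                                    n_lambda=30)
        db_id, perf_id = et.train_tissue_models(G, E, priors, ident, seed=1,
                                                n_lambda=30)
        pd.testing.assert_frame_equal(db_none.weights, db_id.weights)
        pd.testing.assert_frame_equal(perf_none, perf_id)

    def test_all_null_expression_yields_no_models(self):
        cfg = et.SimulationConfig(n_samples=120, n_snps_per_gene=8,
                                  n_causal_per_gene=0, seed=12)
        panel = et.simulate_gene_panel(cfg, 15, seed=12, level=1.0)
        G, E = _panel_to_matrices(panel)
        db, perf = et.train_tissue_models(G, E, None, None, seed=2, n_lambda=30)
        assert len(db.performance) <= 1  # FDR control on pure-null genes

    def test_signal_genes_retained(self, mini_panel):
        G, E = _panel_to_matrices(mini_panel)
        db, perf = et.train_tissue_models(G, E, None, None, seed=3, n_lambda=30)
        assert len(db.performance) >= 5
        db.validate()


class TestPredictGrex:
    def test_self_prediction_correlates(self):
        cfg = et.SimulationConfig(n_samples=200, n_snps_per_gene=10,
                                  n_causal_per_gene=2, effect_sd=0.5, seed=13)
        panel = et.simulate_gene_panel(cfg, 5, seed=13, level=0.0)
        G, E = _panel_to_matrices(panel)
        db, _ = et.train_tissue_models(G, E, None, None, seed=4, n_lambda=30,
                                       q_threshold=0.05)
        grex, flags = et.predict_grex(db, G)
        for gid in grex.columns:
            y = E.gene_vector(gid)
            assert np.corrcoef(grex[gid], y)[0, 1] > 0.9

    def test_allele_swap_invariance(self):
        cfg = et.SimulationConfig(n_samples=150, n_snps_per_gene=6,
                                  n_causal_per_gene=2, effect_sd=0.5, seed=14)
        panel = et.simulate_gene_panel(cfg, 3, seed=14, level=0.1)
        G, E = _panel_to_matrices(panel)
        db, _ = et.train_tissue_models(G, E, None, None, seed=5, n_lambda=30,
                                       q_threshold=0.1)
        if db.weights.empty:
            pytest.skip("no models survived on this tiny panel")
        flipped = GenotypeMatrix(
            2.0 - G.dosages,
            [Snp(s.id, s.chrom, s.pos, s.other_allele, s.effect_allele)
             for s in G.snps],
            G.samples)
        a, _ = et.predict_grex(db, G)
        b, _ = et.predict_grex(db, flipped)
        # swapped alleles with flipped dosages encode identical genotypes
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_empty_model_gives_empty_matrix(self):
        db = et.ModelDb(pd.DataFrame(columns=et.ModelDb.WEIGHT_COLS),
                        pd.DataFrame(columns=et.ModelDb.PERF_COLS))
        cfg = et.SimulationConfig(n_samples=20, n_snps_per_gene=3, seed=15)
        G = et.simulate_genotypes(cfg)
        grex, _ = et.predict_grex(db, G)
        assert grex.shape == (20, 0)


class TestCompareMethods:
    def test_sign_test_closed_form(self):
        """Oracle: binomial closed form, 10/10 positives -> (1/2)^10."""
        rep = et.compare_methods(np.arange(1, 11, dtype=float), np.zeros(10))
        assert rep["sign_p"] == pytest.approx(0.5**10)

    def test_all_zero_deltas_degenerate(self):
        rep = et.compare_methods(np.ones(5), np.ones(5))
        assert rep["degenerate"] and rep["sign_p"] == 1.0 and rep["ratio"] == 1.0

    def test_chi2_percentage_increase(self):
        zb = np.array([1.5, 2.0, -3.0, 1.2])
        rep = et.compare_methods(1.1 * zb, zb, kind="z")
        assert rep["chi2_pct_increase"] == pytest.approx(21.0)

    def test_chi2_restricted_to_pairs_above_one(self):
        za = np.array([1.1 * 2.0, 0.5])  # second pair has chi2 < 1 both ways
        zb = np.array([2.0, 0.4])
        rep = et.compare_methods(za, zb, kind="z")
        assert rep["n_chi2_pairs"] == 1
        assert rep["chi2_pct_increase"] == pytest.approx(21.0)
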