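"""Weighted elastic net training, nested cross-validation and imputation.

Per-SNP penalty factors v_s in (0, 1] downweight the shrinkage applied to
prioritized SNPs; with all factors equal to 1 the model is the plain elastic
net (the uniform-penalty baseline mode).  The cross-validation metric R^2_CV
is the squared Pearson correlation between concatenated out-of-fold
predictions and observed expression (0 if the correlation is non-positive or
the prediction constant), with a one-sided correlation-test p-value attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from ._solver import cd_path, cd_single, lambda_path, standardize
from .cis_eqtl import define_cis_window
from .io_formats import ExpressionMatrix, GenotypeMatrix, ModelDb, harmonize_alleles
from .rescale import BezierRescaler, bezier_penalty

DEFAULT_ALPHA = 0.5  # elastic-net mixing, the published baseline choice
SOLVER_TOL = 1e-7
SOLVER_MAX_ITER = 2000


@dataclass
class WenetFit:
    intercept: float
    coef: np.ndarray  # original (dosage) scale
    penalty_factors: np.ndarray
    alpha: float
    lam: float
    lambda_path: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    converged: bool = True
    objective_trace: Optional[list] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))


@dataclass
class ModelPerformance:
    r2_cv: float
    perf_p: float
    perf_q: Optional[float] = None
    r2_pp: Optional[float] = None
    n_snps_selected: int = 0
    n_folds_used: int = 0


def fit_weighted_enet(X: np.ndarray, y: np.ndarray, v: np.ndarray,
                      alpha: float = DEFAULT_ALPHA, lam: Optional[float] = None,
                      tol: float = 1e-8, max_iter: int = 5000) -> WenetFit:
    """Single weighted elastic-net fit by cyclic coordinate descent.

    Predictors are standardized internally and the solution mapped back to
    the original scale with an intercept.  ``lam`` defaults to the midpoint
    of the automatic lambda path.  The per-sweep objective trace is recorded
    on the fit (it is non-increasing by construction of the coordinate
    updates).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("penalty factors must lie in [0, 1]")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    Xs, x_mean, x_sd = standardize(X)
    ybar = y.mean()
    yc = y - ybar
    if np.allclose(yc, 0):
        return WenetFit(ybar, np.zeros(X.shape[1]), v, alpha, 0.0,
                        np.array([0.0]), x_mean, x_sd, objective_trace=[0.0])
    path = lambda_path(Xs.T @ yc / len(y), v, alpha)
    if lam is None:
        lam = float(path[len(path) // 2])
    beta_std, trace, converged = cd_single(Xs, yc, v, alpha, lam, tol, max_iter)
    if not converged:
        warnings.warn("coordinate descent hit max_iter without converging")
    coef = beta_std / x_sd
    intercept = ybar - float(x_mean @ coef)
    return WenetFit(intercept, coef, v, alpha, lam, path, x_mean, x_sd,
                    converged=converged, objective_trace=trace)


def _path_fit(X_tr, y_tr, v, alpha, lambdas):
    """Coefficient path on the training slice, returned on the original scale
    as (B_orig [n_lambda x p], intercepts [n_lambda])."""
    Xs, mean, sd = standardize(X_tr)
    yc = y_tr - y_tr.mean()
    n = len(y_tr)
    gram = Xs.T @ Xs / n
    xty = Xs.T @ yc / n
    betas = cd_path(gram, xty, v, alpha, lambdas, SOLVER_TOL, SOLVER_MAX_ITER)
    B = betas / sd
    icept = y_tr.mean() - B @ mean
    return B, icept


def _inner_cv_lambda(X, y, v, alpha, lambdas, inner_folds, seed):
    """Pick the lambda index minimizing mean inner-fold MSE."""
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    mse = np.zeros(len(lambdas))
    used = 0
    for tr, te in kf.split(X):
        if np.std(y[tr]) <= 0:
            continue
        B, icept = _path_fit(X[tr], y[tr], v, alpha, lambdas)
        preds = X[te] @ B.T + icept
        mse += ((preds - y[te][:, None]) ** 2).mean(axis=0)
        used += 1
    if used == 0:
        return len(lambdas) // 2
    return int(np.argmin(mse / used))


def nested_cv_train(X: np.ndarray, y: np.ndarray, v: np.ndarray,
                    alpha: float = DEFAULT_ALPHA, outer_folds: int = 5,
                    inner_folds: int = 5, n_lambda: int = 100,
                    lambda_min_ratio: float = 1e-3, seed: int = 0
                    ) -> tuple[WenetFit, ModelPerformance]:
    """Nested cross-validation: lambda by inner CV, performance on outer folds.

    The outer folds are held out in turn; within each outer training set the
    inner CV picks lambda by minimum mean squared error.  R^2_CV and its
    one-sided correlation-test p come from the concatenated out-of-fold
    predictions; the returned model is refit on all samples at the lambda
    chosen by a full inner CV.  Fold assignment depends only on ``seed`` so
    paired runs with different penalty factors share folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(y)
    if n < 25:
        raise ValueError("nested CV needs at least 25 samples")

    Xs_full, _, _ = standardize(X)
    lambdas = lambda_path(Xs_full.T @ (y - y.mean()) / n, v, alpha,
                          n_lambda, lambda_min_ratio)

    oof_pred = np.full(n, np.nan)
    kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    used = 0
    for tr, te in kf.split(X):
        if np.std(y[tr]) <= 0:
            warnings.warn("outer fold with constant training y skipped")
            continue
        li = _inner_cv_lambda(X[tr], y[tr], v, alpha, lambdas, inner_folds, seed)
        B, icept = _path_fit(X[tr], y[tr], v, alpha, lambdas)
        oof_pred[te] = X[te] @ B[li] + icept[li]
        used += 1

    mask = np.isfinite(oof_pred)
    if mask.sum() >= 3 and np.std(oof_pred[mask]) > 0 and np.std(y[mask]) > 0:
        res = stats.pearsonr(oof_pred[mask], y[mask], alternative="greater")
        r, perf_p = float(res.statistic), float(res.pvalue)
        r2_cv = r * r if r > 0 else 0.0
    else:
        r2_cv, perf_p = 0.0, 1.0

    li_full = _inner_cv_lambda(X, y, v, alpha, lambdas, inner_folds, seed)
    B, icept = _path_fit(X, y, v, alpha, lambdas)
    fit = WenetFit(float(icept[li_full]), B[li_full].copy(), v, alpha,
                   float(lambdas[li_full]), lambdas,
                   X.mean(axis=0), X.std(axis=0))
    perf = ModelPerformance(r2_cv=r2_cv, perf_p=perf_p,
                            n_snps_selected=fit.n_selected, n_folds_used=used)
    return fit, perf


def train_tissue_models(genotypes: GenotypeMatrix, expression: ExpressionMatrix,
                        priors: Optional[pd.DataFrame] = None,
                        rescaler: Optional[BezierRescaler] = None,
                        alpha: float = DEFAULT_ALPHA, seed: int = 0,
                        q_threshold: float = 0.01, cis_radius: int = 1_000_000,
                        tissue: str = "synthetic",
                        **cv_kwargs) -> tuple[ModelDb, pd.DataFrame]:
    """Train per-gene prediction models and keep those passing the pred.perf gate.

    With ``rescaler`` (and a prior table with columns gene_id, snp_id, prior)
    each gene's cis-SNPs get Bezier-mapped penalty factors; with rescaler or
    priors absent all factors are 1 (uniform-penalty baseline mode).  BH
    q-values are computed across all trained genes and only genes with
    perf_q <= q_threshold enter the returned ModelDb.  Also returns the full
    per-gene performance table (including filtered-out genes).
    """
    prior_map = {}
    if priors is not None:
        for r in priors.itertuples():
            prior_map[(r.gene_id, r.snp_id)] = r.prior

    weight_rows, perf_rows = [], []
    n_empty = 0
    for gi, gene in enumerate(expression.genes):
        idx = define_cis_window(gene, genotypes.snps, cis_radius)
        if not idx:
            n_empty += 1
            continue
        sub = genotypes.subset_snps(idx)
        y = expression.values[:, gi]
        if rescaler is not None and priors is not None:
            pr = np.array([prior_map.get((gene.id, s.id), 0.0) for s in sub.snps])
            v = bezier_penalty(rescaler, pr)
        else:
            v = np.ones(sub.n_snps)
        fit, perf = nested_cv_train(sub.dosages, y, v, alpha=alpha, seed=seed,
                                    **cv_kwargs)
        perf_rows.append({"gene_id": gene.id, "r2_cv": perf.r2_cv,
                          "perf_p": perf.perf_p,
                          "n_snps_selected": perf.n_snps_selected})
        for j, s in enumerate(sub.snps):
            if fit.coef[j] != 0.0:
                weight_rows.append({"gene_id": gene.id, "snp_id": s.id,
                                    "chrom": s.chrom, "pos": s.pos,
                                    "effect_allele": s.effect_allele,
                                    "other_allele": s.other_allele,
                                    "weight": fit.coef[j]})
    if n_empty:
        warnings.warn(f"{n_empty} genes had empty cis windows and were skipped")

    perf_df = pd.DataFrame(perf_rows, columns=["gene_id", "r2_cv", "perf_p",
                                               "n_snps_selected"])
    if len(perf_df):
        perf_df["perf_q"] = multipletests(perf_df["perf_p"], method="fdr_bh")[1]
    else:
        perf_df["perf_q"] = []
    keep = set(perf_df.loc[perf_df["perf_q"] <= q_threshold, "gene_id"])

    weights = pd.DataFrame([r for r in weight_rows if r["gene_id"] in keep],
                           columns=ModelDb.WEIGHT_COLS)
    performance = perf_df[perf_df["gene_id"].isin(keep)][
        ["gene_id", "r2_cv", "perf_p", "perf_q", "n_snps_selected"]
    ].reset_index(drop=True)
    db = ModelDb(weights, performance, tissue=tissue, seed=seed)
    return db, perf_df


def predict_grex(db: ModelDb, G: GenotypeMatrix) -> tuple[pd.DataFrame, dict]:
    """Impute genetically regulated expression: GReX = sum_s w_s * dosage_s.

    Allele harmonization follows the loader policy (exact match uses the
    dosage; swapped alleles use 2 - dosage; any other mismatch drops the SNP
    with a counter).  Missing model SNPs contribute 0; genes with under half
    of their model SNPs usable are flagged.
    """
    snp_idx = {s.id: j for j, s in enumerate(G.snps)}
    cols, flags = {}, {"low_coverage_genes": [], "n_missing_snps": 0,
                       "n_allele_mismatch": 0}
    for gene_id, grp in db.weights.groupby("gene_id", sort=False):
        grex = np.zeros(G.n_samples)
        n_used = 0
        for r in grp.itertuples():
            j = snp_idx.get(r.snp_id)
            if j is None:
                flags["n_missing_snps"] += 1
                continue
            s = G.snps[j]
            flip = harmonize_alleles(r.effect_allele, r.other_allele,
                                     s.effect_allele, s.other_allele)
            if flip is None:
                flags["n_allele_mismatch"] += 1
                continue
            dose = G.dosages[:, j] if flip == 1 else 2.0 - G.dosages[:, j]
            grex += r.weight * dose
            n_used += 1
        if n_used < 0.5 * len(grp):
            warnings.warn(f"gene {gene_id}: only {n_used}/{len(grp)} model SNPs usable")
            flags["low_coverage_genes"].append(gene_id)
        cols[gene_id] = grex
    out = pd.DataFrame(cols, index=pd.Index(G.samples, name="sample"))
    return out, flags


def compare_methods(a, b, kind: str = "performance") -> dict:
    """Paired method comparison with a one-sided sign test.

    ``kind='performance'``: a, b are paired per-gene metrics (e.g. R^2_CV);
    ``kind='z'``: a, b are paired association z-scores, and the report also
    carries the mean percentage chi-square (z^2) increase restricted to pairs
    where both chi-squares are >= 1.  The sign test uses the closed-form
    binomial with zero deltas discarded, alternative: a > b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have the same shape")
    delta = a - b
    nz = delta[delta != 0]
    n_pos = int((nz > 0).sum())
    n_neg = int((nz < 0).sum())
    if len(nz) == 0:
        report = {"n_pos": 0, "n_neg": 0, "ratio": 1.0, "sign_p": 1.0,
                  "mean_delta": 0.0, "degenerate": True}
    else:
        p = stats.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="greater").pvalue
        ratio = n_pos / n_neg if n_neg else float("inf")
        report = {"n_pos": n_pos, "n_neg": n_neg, "ratio": ratio,
                  "sign_p": float(p), "mean_delta": float(delta.mean()),
                  "degenerate": False}
    if kind == "z":
        chi_a, chi_b = a**2, b**2
        both = (chi_a >= 1) & (chi_b >= 1)
        if both.any():
            report["chi2_pct_increase"] = float(
                100.0 * np.mean((chi_a[both] - chi_b[both]) / chi_b[both])
            )
            report["n_chi2_pairs"] = int(both.sum())
        else:
            report["chi2_pct_increase"] = float("nan")
            report["n_chi2_pairs"] = 0
    return report
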