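"""Empirical-Bayes SNP priors from eQTL evidence plus epigenomic annotations.

Model: per gene, one latent causal cis-SNP.  The prior over cis-SNPs is a
within-gene softmax of a linear score in the binary annotation features,
prior_s = softmax(gamma . A_s); single-SNP association evidence enters as a
Wakefield approximate Bayes factor computed from the marginal eQTL scan.  The
annotation weights gamma are estimated by EM:

  E-step: q_s = softmax(gamma . A_s + log ABF_s) within each gene
  M-step: gamma maximizes the expected complete-data log-likelihood, a
          conditional-logit objective (concave; solved exactly by BFGS with
          analytic gradient)

The log marginal likelihood sum_g [lse(gamma.A + logABF) - lse(gamma.A)] is
non-decreasing across iterations and is asserted per iteration.

The intercept of the annotation score cancels within each gene's softmax
(conditional-logit non-identifiability), so ``alpha0`` is carried for
interface completeness but stays 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .simulate import AnnotationSet


def wakefield_abf(z, se, prior_var: float = 0.1) -> np.ndarray:
    """Log approximate Bayes factor for a single-SNP association.

    log ABF = 0.5 log(se^2/(se^2+W)) + W z^2 / (2 (se^2 + W)), with W the
    prior variance of the effect.  W = 0 degenerates to ABF = 1.
    """
    if prior_var < 0:
        raise ValueError("prior variance must be non-negative")
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    s2 = se**2
    return 0.5 * np.log(s2 / (s2 + prior_var)) + prior_var * z**2 / (2 * (s2 + prior_var))


@dataclass
class AnnotationModel:
    alpha0: float
    gamma: np.ndarray
    features: list[str]
    n_iter: int
    log_marginal_likelihood: float
    likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = True
    dropped_features: list[str] = field(default_factory=list)


def _group_index(eqtl: pd.DataFrame) -> list[np.ndarray]:
    return [np.asarray(idx) for idx in eqtl.groupby("gene_id", sort=False).indices.values()]


def _log_marginal(gamma, A, log_abf, groups) -> float:
    score = A @ gamma
    tot = 0.0
    for idx in groups:
        tot += logsumexp(score[idx] + log_abf[idx]) - logsumexp(score[idx])
    return tot


def fit_annotation_model(eqtl: pd.DataFrame, ann: AnnotationSet, prior_var: float = 0.1,
                         tol: float = 1e-6, max_iter: int = 100, seed: int = 0
                         ) -> AnnotationModel:
    """EM fit of the annotation weights on a stacked multi-gene eQTL table.

    ``eqtl`` must have columns gene_id, snp_id, t_stat (or z), se; rows of
    ``ann.matrix`` align with rows of ``eqtl``.  Constant annotation columns
    are dropped with a warning.
    """
    eqtl = eqtl.reset_index(drop=True)
    A = np.asarray(ann.matrix, dtype=float)
    if A.shape[0] != len(eqtl):
        raise ValueError("annotation rows must align with eQTL rows")
    keep = [k for k in range(A.shape[1]) if A[:, k].std() > 0]
    dropped = [ann.features[k] for k in range(A.shape[1]) if k not in keep]
    if dropped:
        warnings.warn(f"dropping constant annotation columns: {dropped}")
    A = A[:, keep]
    features = [ann.features[k] for k in keep]

    z = eqtl["t_stat"].to_numpy() if "t_stat" in eqtl.columns else eqtl["z"].to_numpy()
    log_abf = wakefield_abf(z, eqtl["se"].to_numpy(), prior_var)
    groups = _group_index(eqtl)

    K = A.shape[1]
    gamma = np.zeros(K)
    trace = [_log_marginal(gamma, A, log_abf, groups)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: within-gene posterior over the causal SNP
        score = A @ gamma
        q = np.empty(len(eqtl))
        for idx in groups:
            s = score[idx] + log_abf[idx]
            q[idx] = np.exp(s - logsumexp(s))

        # M-step: conditional-logit maximization
        def neg_ecll(g):
            sc = A @ g
            val = float(q @ sc)
            grad = A.T @ q
            for idx in groups:
                lse = logsumexp(sc[idx])
                val -= lse
                w = np.exp(sc[idx] - lse)
                grad -= A[idx].T @ w
            return -val, -grad

        res = minimize(neg_ecll, gamma, jac=True, method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 200})
        gamma = res.x

        lml = _log_marginal(gamma, A, log_abf, groups)
        if lml < trace[-1] - 1e-8:
            raise AssertionError(
                f"EM log-marginal-likelihood decreased at iteration {it}: "
                f"{trace[-1]:.10g} -> {lml:.10g}"
            )
        trace.append(lml)
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning last iterate")

    return AnnotationModel(
        alpha0=0.0, gamma=gamma, features=features, n_iter=it,
        log_marginal_likelihood=trace[-1], likelihood_trace=trace,
        converged=converged, dropped_features=dropped,
    )


def snp_priors(model: AnnotationModel, eqtl: pd.DataFrame, ann: AnnotationSet,
               normalize_per_gene: bool = True, prior_var: float = 0.1) -> pd.DataFrame:
    """Per gene-SNP prior table from a fitted annotation model.

    The raw prior is the within-gene posterior causal probability (softmax of
    annotation score + log ABF).  With ``normalize_per_gene`` the posteriors
    are min-max rescaled to [0, 1] within each gene so the downstream penalty
    mapping's domain is covered regardless of cis-window size; a constant
    posterior vector maps to all-zeros.
    """
    eqtl = eqtl.reset_index(drop=True)
    A = np.asarray(ann.matrix, dtype=float)
    # align with fitted (non-constant) features by name
    full = list(ann.features)
    cols = [full.index(f) for f in model.features]
    A = A[:, cols] if cols else np.zeros((len(eqtl), 0))

    z = eqtl["t_stat"].to_numpy() if "t_stat" in eqtl.columns else eqtl["z"].to_numpy()
    # prior_var should match the value used in fit_annotation_model
    log_abf = wakefield_abf(z, eqtl["se"].to_numpy(), prior_var)
    score = (A @ model.gamma) if A.shape[1] else np.zeros(len(eqtl))

    pi = np.empty(len(eqtl))
    for idx in _group_index(eqtl):
        s = score[idx] + log_abf[idx]
        post = np.exp(s - logsumexp(s))
        if normalize_per_gene:
            rng = post.max() - post.min()
            post = (post - post.min()) / rng if rng > 0 else np.zeros_like(post)
        pi[idx] = post
    return pd.DataFrame(
        {"gene_id": eqtl["gene_id"], "snp_id": eqtl["snp_id"], "prior": pi}
    )
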