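"""Per-gene marginal cis-eQTL scan.

Produces the per-SNP summary statistics (slope, SE, t, p) that feed the
annotation prior model.  Each SNP is tested in its own simple linear
regression with intercept; the scan takes expression as given (any covariate
adjustment is expected to have happened upstream, but a covariate hook is
provided).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix


def define_cis_window(gene, snps: list, radius: int = 1_000_000) -> list[int]:
    """Indices of SNPs on the gene's chromosome with |pos - tss| <= radius."""
    return [
        i for i, s in enumerate(snps)
        if s.chrom == gene.chrom and abs(s.pos - gene.tss) <= radius
    ]


def marginal_eqtl_scan(G: GenotypeMatrix, y: np.ndarray, gene_id: str = "gene",
                       covariates: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-SNP OLS scan of expression on dosage.

    Returns a DataFrame with columns gene_id, snp_id, beta_hat, se, t_stat, p,
    monomorphic.  Zero-variance SNPs are emitted with beta 0, p 1 and the
    monomorphic flag set.  With covariates given, both y and each dosage
    column are residualized on them (with intercept) first.
    """
    y = np.asarray(y, dtype=float)
    n = G.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.shape[0] != n:
        raise ValueError("y length does not match genotype samples")

    X = G.dosages
    if covariates is not None:
        C = np.column_stack([np.ones(n), covariates])
        proj = C @ np.linalg.pinv(C)
        y = y - proj @ y
        X = X - proj @ X

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    mono = sxx <= 1e-12
    sxy = Xc.T @ yc

    beta = np.zeros(G.n_snps)
    np.divide(sxy, sxx, out=beta, where=~mono)
    # residual variance of y on x with intercept, df = n - 2
    syy = float(yc @ yc)
    rss = syy - beta * sxy
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.clip(rss, 0, None) / df / np.where(mono, 1.0, sxx))
    # a perfect fit has rss ~ 0; floor the SE so t blows up and p underflows
    se = np.where(~mono & (se <= 0), 1e-12 * np.maximum(np.abs(beta), 1.0), se)
    se = np.where(mono, np.nan, se)
    t = np.where(np.isfinite(se), beta / se, 0.0)
    p = np.where(np.isfinite(se), 2 * stats.t.sf(np.abs(t), df), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "snp_id": G.snp_ids(),
            "beta_hat": np.where(mono, 0.0, beta),
            "se": np.where(np.isfinite(se), se, 1.0),
            "t_stat": np.where(np.isfinite(se), t, 0.0),
            "p": np.where(mono, 1.0, p),
            "monomorphic": mono,
        }
    )
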