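"""Fisher-based gene-set enrichment and the tissue-specificity statistic.

The tissue-specificity score for a tissue x trait table of significant
gene-trait association counts is the Pearson standardized residual

    r_ij = (n_ij - mu_ij) / sqrt(mu_ij (1 - p_i+)(1 - p_+j))

where mu_ij is the expected count under independence and p_i+, p_+j are the
marginal row/column proportions, together with the chi-square test of
independence on the same table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_gmt(path) -> dict[str, set]:
    """Gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def fisher_gsea(query, gene_sets: dict, background, min_query: int = 10
                ) -> pd.DataFrame:
    """One-sided Fisher enrichment of a query gene list against gene sets.

    Sets are intersected with the background; the query must be a subset of
    the background.  Queries smaller than ``min_query`` return an empty
    result (the trait gate).  BH adjustment is across sets.
    """
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be drawn from the background")
    if len(query) < min_query:
        return pd.DataFrame(columns=["set", "overlap", "set_size", "odds_ratio",
                                     "p", "q"])
    rows = []
    for name, genes in gene_sets.items():
        s = genes & background
        k = len(query & s)
        table = [[k, len(query) - k],
                 [len(s) - k, len(background) - len(query) - len(s) + k]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"set": name, "overlap": k, "set_size": len(s),
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


@dataclass
class ContingencyEnrichment:
    observed: pd.DataFrame
    expected: pd.DataFrame
    std_residuals: pd.DataFrame
    chi2: float
    p: float
    dof: int
    dropped_columns: list


def tissue_specificity(counts: pd.DataFrame, min_expected: float = 1.0
                       ) -> ContingencyEnrichment:
    """Standardized-residual enrichment on a tissue x trait count table.

    Columns (traits) with any expected cell <= ``min_expected`` are dropped
    (strictly-greater-than-1 gate), iterating until all remaining columns
    pass; the chi-square test of independence and the residuals are computed
    on the remainder.
    """
    obs = counts.astype(float)
    if (obs < 0).any().any():
        raise ValueError("counts must be non-negative")
    dropped: list = []
    while True:
        tot = obs.to_numpy().sum()
        if tot <= 0 or obs.shape[1] < 2:
            break
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / tot
        bad = [c for j, c in enumerate(obs.columns)
               if (exp[:, j] <= min_expected).any()]
        if not bad:
            break
        dropped.extend(bad)
        obs = obs.drop(columns=bad)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("fewer than 2 rows or columns remain after filtering")

    n = obs.to_numpy()
    tot = n.sum()
    row = n.sum(axis=1)
    col = n.sum(axis=0)
    mu = np.outer(row, col) / tot
    p_i = row / tot
    p_j = col / tot
    denom = np.sqrt(mu * (1 - p_i)[:, None] * (1 - p_j)[None, :])
    resid = (n - mu) / denom
    chi2 = float(((n - mu) ** 2 / mu).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    return ContingencyEnrichment(
        observed=obs,
        expected=pd.DataFrame(mu, index=obs.index, columns=obs.columns),
        std_residuals=pd.DataFrame(resid, index=obs.index, columns=obs.columns),
        chi2=chi2, p=p, dof=dof, dropped_columns=dropped,
    )
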