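"""Trait-trait GReX correlation, shared-gene networks, bi-directional
regression causal graphs, and agonistic-gene pathway dissection.

All operations consume per-trait association tables (columns gene_id,
tissue, z, p, q, and perf_q where gated) keyed by trait name.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_gsea


def _mean_z_table(assocs: dict[str, pd.DataFrame], p_gate: float) -> dict[str, pd.Series]:
    out = {}
    for trait, df in assocs.items():
        gated = df[df["p"] <= p_gate]
        out[trait] = gated.groupby("gene_id")["z"].mean()
    return out


def grex_trait_correlation(assocs: dict[str, pd.DataFrame], p_gate: float = 0.05,
                           min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation of trait z-scores over shared genes.

    Genes pass an unadjusted p <= ``p_gate`` filter per trait; each pair is
    correlated over its complete cases (genes gated in both traits) and the
    p-values are Holm-adjusted across pairs.  Pairs with fewer than
    ``min_shared`` shared genes are reported with NaN correlation.
    """
    ztab = _mean_z_table(assocs, p_gate)
    traits = sorted(ztab)
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            shared = ztab[a].index.intersection(ztab[b].index)
            if len(shared) < min_shared:
                rows.append({"trait_a": a, "trait_b": b, "n_shared": len(shared),
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(ztab[a].loc[shared], ztab[b].loc[shared])
            rows.append({"trait_a": a, "trait_b": b, "n_shared": len(shared),
                         "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_holm"] = np.nan
    if ok.any():
        df.loc[ok, "p_holm"] = multipletests(df.loc[ok, "p"], method="holm")[1]
    return df


def shared_gene_network(assocs: dict[str, pd.DataFrame],
                        categories: Optional[dict[str, str]] = None,
                        perf_q_max: float = 0.005, fdr_max: float = 0.005,
                        min_genes_per_trait: int = 0) -> pd.DataFrame:
    """Edge list of shared significant genes between trait pairs.

    Genes require perf_q <= ``perf_q_max`` (when the column is present) and
    q <= ``fdr_max``.  For pairs within the same category, only genes with
    |z| >= the trait's mean |z| among its retained genes count (high-effect
    gate).  Traits with fewer retained genes than ``min_genes_per_trait``
    are excluded.
    """
    categories = categories or {}
    sig = {}
    for trait, df in assocs.items():
        f = df[df["q"] <= fdr_max]
        if "perf_q" in f.columns:
            f = f[f["perf_q"] <= perf_q_max]
        z = f.groupby("gene_id")["z"].mean()
        if len(z) >= min_genes_per_trait:
            sig[trait] = z
    traits = sorted(sig)
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            za, zb = sig[a], sig[b]
            shared = set(za.index) & set(zb.index)
            same_cat = categories.get(a) is not None and categories.get(a) == categories.get(b)
            if same_cat:
                ga = set(za.index[np.abs(za) >= np.abs(za).mean()])
                gb = set(zb.index[np.abs(zb) >= np.abs(zb).mean()])
                shared &= ga & gb
            if shared:
                rows.append({"trait_a": a, "trait_b": b, "n_shared": len(shared),
                             "same_category": same_cat,
                             "genes": ",".join(sorted(shared))})
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "n_shared",
                                       "same_category", "genes"])


def _directed_fit(z_from: pd.Series, z_to: pd.Series, sig_genes: set):
    """Regress z_to on z_from over the 'from' trait's significant genes."""
    genes = sorted(set(sig_genes) & set(z_from.index) & set(z_to.index))
    if len(genes) < 3:
        return None
    res = stats.linregress(z_from.loc[genes], z_to.loc[genes])
    return {"slope": float(res.slope), "p": float(res.pvalue),
            "df": len(genes) - 2, "n_genes": len(genes)}


def bidirectional_regression(assocs: dict[str, pd.DataFrame], trait_a: str,
                             trait_b: str, sig_fdr: float = 0.01,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Bi-directional regression between two traits' gene z-scores, per tissue.

    For each tissue, z_B is regressed on z_A over A's significant genes
    (FDR <= ``sig_fdr``) and vice versa; a directed edge is emitted when its
    regression p <= ``alpha``.  When both directions pass in a tissue, only
    the one with the higher degrees of freedom is kept; the edge sign is the
    sign of the slope (negative = protective).  Returns one row per surviving
    direction with the supporting tissue count.
    """
    A, B = assocs[trait_a], assocs[trait_b]
    tissues = sorted(set(A["tissue"]) & set(B["tissue"]))
    hits = []
    for tis in tissues:
        a = A[A["tissue"] == tis].set_index("gene_id")
        b = B[B["tissue"] == tis].set_index("gene_id")
        sig_a = set(a.index[a["q"] <= sig_fdr])
        sig_b = set(b.index[b["q"] <= sig_fdr])
        fwd = _directed_fit(a["z"], b["z"], sig_a)
        rev = _directed_fit(b["z"], a["z"], sig_b)
        fwd_ok = fwd is not None and fwd["p"] <= alpha
        rev_ok = rev is not None and rev["p"] <= alpha
        if fwd_ok and rev_ok:
            if fwd["df"] >= rev["df"]:
                rev_ok = False
            else:
                fwd_ok = False
        if fwd_ok:
            hits.append({"from": trait_a, "to": trait_b, "tissue": tis, **fwd})
        if rev_ok:
            hits.append({"from": trait_b, "to": trait_a, "tissue": tis, **rev})
    df = pd.DataFrame(hits, columns=["from", "to", "tissue", "slope", "p",
                                     "df", "n_genes"])
    if df.empty:
        return pd.DataFrame(columns=["from", "to", "slope", "p", "df",
                                     "n_genes", "sign", "n_tissues"])
    agg = []
    for (src, dst), grp in df.groupby(["from", "to"]):
        best = grp.loc[grp["p"].idxmin()]
        agg.append({"from": src, "to": dst, "slope": best["slope"],
                    "p": best["p"], "df": int(best["df"]),
                    "n_genes": int(best["n_genes"]),
                    "sign": int(np.sign(best["slope"])),
                    "n_tissues": len(grp)})
    return pd.DataFrame(agg)


def agonistic_gene_pathways(assocs: dict[str, pd.DataFrame], focal: str,
                            edges: pd.DataFrame, gene_sets: dict,
                            background, p_gate: float = 0.05,
                            min_query: int = 5) -> dict[str, pd.DataFrame]:
    """Pathway enrichment of agonistic genes per upstream trait of ``focal``.

    For each trait with an edge into the focal trait, agonistic genes are
    those with unadjusted p <= ``p_gate`` in both traits whose predicted
    direction agrees (or opposes, for protective / negative-slope edges)
    with the focal trait.  Each list is passed to the one-sided Fisher GSEA.
    """
    up_edges = edges[edges["to"] == focal]
    ztab = _mean_z_table(assocs, p_gate)
    zf = ztab[focal]
    out = {}
    for _, r in up_edges.iterrows():
        zu = ztab[r["from"]]
        shared = zu.index.intersection(zf.index)
        if r["sign"] >= 0:
            agon = [g for g in shared if np.sign(zu[g]) == np.sign(zf[g])]
        else:
            agon = [g for g in shared if np.sign(zu[g]) == -np.sign(zf[g])]
        agon = [g for g in agon if g in background]
        if not agon:
            continue
        res = fisher_gsea(agon, gene_sets, background, min_query=min_query)
        out[r["from"]] = res.sort_values(
            ["q", "odds_ratio"], ascending=[True, False]).reset_index(drop=True)
    return out
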