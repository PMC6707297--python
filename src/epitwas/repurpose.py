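"""GReX-signature computational drug repurposing.

A compound signature is a ranked gene list (rank 1 = most up-regulated,
derived from ranked log2 fold change); a query signature is a pair of up-
and down-regulated trait gene sets.  For each query component a running-sum
(KS) enrichment score in [-1, 1] is computed against the compound's list and
combined into a connectivity score CS = (ES_Pos - ES_Neg) / 2: positive CS
means the compound mimics the trait signature, negative CS that it reverses
it.  Significance comes from per-compound rank-shuffle permutations with
two-tailed add-one p-values and BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class QuerySignature:
    trait: str
    up: set
    down: set

    def __post_init__(self) -> None:
        self.up, self.down = set(self.up), set(self.down)
        if len(self.up) < 5 or len(self.down) < 5:
            raise ValueError("query needs at least 5 up and 5 down genes")
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")


def make_query_signature(assocs: pd.DataFrame, trait: str, fdr: float = 0.1
                         ) -> QuerySignature:
    """Build a query from a multi-tissue association table (gene_id, z, q).

    Records passing the FDR gate are grouped by gene and summarized as the
    mean z across tissues; the sign of the mean z assigns up/down.
    """
    sig = assocs[assocs["q"] < fdr]
    mean_z = sig.groupby("gene_id")["z"].mean()
    up = set(mean_z[mean_z > 0].index)
    down = set(mean_z[mean_z < 0].index)
    return QuerySignature(trait, up, down)


def merge_prl(replicates: list[pd.Series]) -> pd.Series:
    """Merge replicate ranked lists for one compound by mean rank.

    Each replicate maps gene -> rank over the same universe.  Genes are
    re-ranked by mean rank; exact ties break lexicographically by gene id
    (a fully tied input therefore comes back in id-sorted order).
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    universe = set(replicates[0].index)
    for r in replicates[1:]:
        if set(r.index) != universe:
            raise ValueError("replicates must share the same gene universe")
    mean_rank = pd.concat(replicates, axis=1).mean(axis=1)
    order = mean_rank.sort_index().sort_values(kind="stable").index
    out = pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")
    return out.sort_index()


def _es_from_positions(positions: np.ndarray, n: int) -> float:
    """KS running-sum extremum from sorted 1-based tag positions."""
    t = len(positions)
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - positions / n))
    b = float(np.max(positions / n - (j - 1) / t))
    return a if a > b else -b


def ks_enrichment_score(tags, signature: pd.Series) -> float:
    """Signed KS enrichment of a tag gene set within a ranked signature.

    ``signature`` maps gene -> rank (1 = top).  ES is in [-1, 1]; positive
    when tags concentrate near the top of the list.
    """
    tags = set(tags)
    if not tags:
        raise ValueError("empty tag set")
    missing = tags - set(signature.index)
    if missing:
        raise ValueError(f"tags not in the signature universe: {sorted(missing)[:5]}")
    positions = np.sort(signature.loc[sorted(tags)].to_numpy())
    return _es_from_positions(positions, len(signature))


def connectivity_score(query: QuerySignature, signature: pd.Series) -> float:
    """CS = (ES of up-set - ES of down-set) / 2, in [-1, 1]."""
    es_pos = ks_enrichment_score(query.up, signature)
    es_neg = ks_enrichment_score(query.down, signature)
    return (es_pos - es_neg) / 2


def _null_cs(rng: np.random.Generator, n: int, t_up: int, t_down: int,
             n_perm: int) -> np.ndarray:
    """CS under per-compound rank shuffling: tag positions become a uniform
    draw of t_up + t_down distinct ranks split between the two components."""
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(n, size=t_up + t_down, replace=False) + 1
        es_u = _es_from_positions(np.sort(pos[:t_up]), n)
        es_d = _es_from_positions(np.sort(pos[t_up:]), n)
        out[i] = (es_u - es_d) / 2
    return out


def permutation_pvalues(query: QuerySignature, signatures: pd.DataFrame,
                        n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Connectivity results for a query against a signature library.

    ``signatures`` is a gene x compound table of ranks.  The null for each
    compound shuffles that compound's ranked list; perm_p is the two-tailed
    add-one estimator (1 + #{|null| >= |cs|}) / (n_perm + 1), BH-adjusted
    across compounds.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    n = signatures.shape[0]
    rows = []
    root = np.random.default_rng(seed)
    for ci, comp in enumerate(signatures.columns):
        sig = signatures[comp]
        es_pos = ks_enrichment_score(query.up, sig)
        es_neg = ks_enrichment_score(query.down, sig)
        cs = (es_pos - es_neg) / 2
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        null = _null_cs(rng, n, len(query.up), len(query.down), n_perm)
        perm_p = (1 + int((np.abs(null) >= abs(cs)).sum())) / (n_perm + 1)
        rows.append({"compound": comp, "es_pos": es_pos, "es_neg": es_neg,
                     "cs": cs, "perm_p": perm_p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["perm_p"], method="fdr_bh")[1]
    return df


def chemogenomic_enrichment(compound_cs: pd.Series, feature_sets: dict,
                            n_perm: int = 1000, seed: int = 0,
                            min_members: int = 3) -> pd.DataFrame:
    """Signed KS enrichment of compound features along the CS-sorted list.

    ``compound_cs`` maps compound -> CS; compounds are sorted by CS
    (descending, mimics first).  Each feature's member compounds are scored
    like a tag set; the null draws random same-size compound sets.  Features
    with fewer than ``min_members`` members in the library are skipped.
    """
    order = compound_cs.sort_values(ascending=False, kind="stable").index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    n = len(ranks)
    root = np.random.default_rng(seed)
    rows, n_skipped = [], 0
    for name, members in feature_sets.items():
        members = set(members) & set(ranks.index)
        if len(members) < min_members:
            n_skipped += 1
            continue
        es = _es_from_positions(np.sort(ranks.loc[sorted(members)].to_numpy()), n)
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        null = np.array([
            _es_from_positions(
                np.sort(rng.choice(n, size=len(members), replace=False) + 1), n)
            for _ in range(n_perm)
        ])
        p = (1 + int((np.abs(null) >= abs(es)).sum())) / (n_perm + 1)
        rows.append({"feature": name, "n_members": len(members), "es": es, "p": p})
    df = pd.DataFrame(rows, columns=["feature", "n_members", "es", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df.attrs["n_skipped"] = n_skipped
    return df


def target_disease_fisher(target_sets: dict, disease_sets: dict,
                          background_size: int = 2802,
                          background: Optional[set] = None) -> pd.DataFrame:
    """Two-sided Fisher tests of trait drug-target sets vs disease gene sets.

    Target sets with fewer than 3 members are skipped.  The background
    defaults to the stated drug-target universe size; passing an explicit
    ``background`` set overrides it and every tested set must lie within it.
    """
    rows = []
    for trait, targets in target_sets.items():
        targets = set(targets)
        if len(targets) < 3:
            continue
        for disease, genes in disease_sets.items():
            genes = set(genes)
            if background is not None:
                if not (targets <= background and genes <= background):
                    raise ValueError("sets must be subsets of the background")
                N = len(background)
            else:
                N = background_size
            if len(targets | genes) > N:
                raise ValueError("background smaller than the union of sets")
            k = len(targets & genes)
            table = [[k, len(targets) - k],
                     [len(genes) - k, N - len(targets) - len(genes) + k]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({"trait": trait, "disease_set": disease, "overlap": k,
                         "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows, columns=["trait", "disease_set", "overlap",
                                     "odds_ratio", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
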