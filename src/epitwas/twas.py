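"""Summary-statistic gene-trait association (TWAS) from model weights,
GWAS z-scores and an LD reference, with FDR, MHC masking, LD clumping /
novelty calls and cross-tissue direction labels.

The gene z-score follows the summary-level imputation statistic:

    z_g = sum_l w_l sigma_l z_l / sigma_g,
    sigma_g^2 = sum_lm w_l w_m sigma_l sigma_m Sigma_lm

with sigma_l the reference dosage SD of SNP l and Sigma the reference SNP
correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenotypeMatrix, GwasSummary, ModelDb, harmonize_alleles

MHC_MASK = ("6", 25_000_000, 35_000_000)


@dataclass
class LdReference:
    """SNP correlation matrix and dosage SDs from a reference panel."""

    corr: np.ndarray
    sd: np.ndarray
    snp_ids: list[str]
    snps: Optional[list] = None

    @classmethod
    def from_genotypes(cls, G: GenotypeMatrix) -> "LdReference":
        X = G.dosages
        sd = X.std(axis=0)
        ok = sd > 0
        Xn = np.where(ok, (X - X.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
        corr = Xn.T @ Xn / X.shape[0]
        np.fill_diagonal(corr, 1.0)
        return cls(corr, sd, G.snp_ids(), snps=list(G.snps))

    def index(self, snp_id: str) -> Optional[int]:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            return None


def twas_zscore(weights: pd.DataFrame, gwas: GwasSummary, ld: LdReference
                ) -> Optional[float]:
    """Gene association z-score from model weights and GWAS summary stats.

    ``weights`` is the per-gene slice of a ModelDb weights table.  SNPs are
    harmonized against the GWAS alleles (swapped alleles flip z); SNPs absent
    from the GWAS or LD reference, or with mismatched alleles, are dropped.
    Returns None when no usable SNP remains or the predictor variance is
    degenerate.
    """
    gdict = gwas.as_dict()
    w_list, z_list, idx_list = [], [], []
    for r in weights.itertuples():
        rec = gdict.get(r.snp_id)
        j = ld.index(r.snp_id)
        if rec is None or j is None:
            continue
        flip = harmonize_alleles(rec.effect_allele, rec.other_allele,
                                 r.effect_allele, r.other_allele)
        if flip is None:
            continue
        w_list.append(r.weight)
        z_list.append(flip * rec.z)
        idx_list.append(j)
    if not w_list:
        return None
    w = np.array(w_list)
    z = np.array(z_list)
    sig = ld.sd[idx_list]
    Sigma = ld.corr[np.ix_(idx_list, idx_list)]
    var_g = float((w * sig) @ Sigma @ (w * sig))
    sigma_g = np.sqrt(max(var_g, 0.0))
    if sigma_g < 1e-8:
        return None
    return float((w * sig) @ z / sigma_g)


def twas_scan(db: ModelDb, gwas: GwasSummary, ld: LdReference,
              tissue: Optional[str] = None, trait: str = "trait") -> pd.DataFrame:
    """Run twas_zscore for every gene in the model database."""
    rows = []
    n_skipped = 0
    for gene_id, grp in db.weights.groupby("gene_id", sort=False):
        zg = twas_zscore(grp, gwas, ld)
        if zg is None:
            n_skipped += 1
            continue
        rows.append({"gene_id": gene_id, "tissue": tissue or db.tissue,
                     "trait": trait, "z": zg,
                     "p": float(2 * stats.norm.sf(abs(zg))),
                     "n_model_snps_used": len(grp)})
    if n_skipped:
        warnings.warn(f"{n_skipped} genes skipped (no usable SNPs or zero variance)")
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "trait", "z", "p",
                                       "n_model_snps_used"])


def _genes_in_mask(db: ModelDb, mask) -> set:
    chrom, lo, hi = mask
    w = db.weights
    hit = w[(w["chrom"].astype(str) == str(chrom)) & (w["pos"] >= lo) & (w["pos"] <= hi)]
    return set(hit["gene_id"])


def significant_gtas(assocs: pd.DataFrame, db: Optional[ModelDb] = None,
                     fdr: float = 0.01, mhc_mask=MHC_MASK) -> pd.DataFrame:
    """BH-adjust one trait's associations and flag q <= fdr as significant.

    Genes with any model SNP inside the MHC mask (chr6:25-35 Mb by default)
    are removed before adjustment; pass ``mhc_mask=None`` to disable.  BH is
    computed jointly over all tissue x gene records of the trait.
    """
    out = assocs.copy()
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    if db is not None and mhc_mask is not None:
        masked = _genes_in_mask(db, mhc_mask)
        out = out[~out["gene_id"].isin(masked)].reset_index(drop=True)
        if out.empty:
            out["q"] = []
            out["significant"] = []
            return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] <= fdr
    return out


def ld_clump_and_novelty(gwas: GwasSummary, ld: LdReference, genes: list,
                         p_index: float = 5e-8, p_clump: float = 5e-8,
                         window: int = 250_000, r2: float = 0.1,
                         locus_pad: int = 1_000_000) -> pd.DataFrame:
    """Greedy LD clumping of GWAS SNPs and per-gene novelty flags.

    The best remaining SNP with p <= p_index becomes an index SNP and claims
    every unassigned SNP with p <= p_clump within ``window`` bp and LD
    r^2 >= ``r2``.  GWAS loci are index +- locus_pad; a gene is novel iff its
    body (start, end) overlaps no locus.  Genes need chrom/start/end
    attributes (Gene records with start/end set, falling back to the TSS).
    """
    recs = [r for r in gwas.records if r.p is not None]
    pos = {}
    for r in recs:
        j = ld.index(r.snp_id)
        if j is not None and ld.snps is not None:
            pos[r.snp_id] = (ld.snps[j].chrom, ld.snps[j].pos, j)
    cand = sorted((r for r in recs if r.snp_id in pos), key=lambda r: r.p)
    assigned: set[str] = set()
    loci = []  # (chrom, lo, hi, index_snp)
    for r in cand:
        if r.snp_id in assigned or r.p > p_index:
            continue
        chrom, ipos, ij = pos[r.snp_id]
        assigned.add(r.snp_id)
        for s in cand:
            if s.snp_id in assigned or s.p > p_clump:
                continue
            schrom, spos, sj = pos[s.snp_id]
            if schrom == chrom and abs(spos - ipos) <= window and \
                    ld.corr[ij, sj] ** 2 >= r2:
                assigned.add(s.snp_id)
        loci.append((chrom, max(1, ipos - locus_pad), ipos + locus_pad, r.snp_id))

    rows = []
    for g in genes:
        start = g.start if getattr(g, "start", None) is not None else g.tss
        end = g.end if getattr(g, "end", None) is not None else g.tss
        novel = not any(
            c == g.chrom and start <= hi and end >= lo for c, lo, hi, _ in loci
        )
        rows.append({"gene_id": g.id, "novel": novel})
    return pd.DataFrame(rows)


def direction_across_tissues(assocs: pd.DataFrame) -> str:
    """Majority z-score sign across tissues for one gene-trait pair.

    Returns 'up', 'down' or 'ambiguous' (exact tie of tissue counts).
    """
    z = np.asarray(assocs["z"] if isinstance(assocs, pd.DataFrame) else assocs,
                   dtype=float)
    if len(z) == 0:
        raise ValueError("need at least one tissue record")
    n_up = int((z > 0).sum())
    n_down = int((z < 0).sum())
    if n_up > n_down:
        return "up"
    if n_down > n_up:
        return "down"
    return "ambiguous"
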