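"""Synthetic-data generators for the full imputation/TWAS pipeline.

The generators emulate the ingredients the training and evaluation design
assumes: LD-structured genotype dosages, an annotation-enriched causal
architecture, expression built as ``y = X beta + level * eps`` with Gaussian
noise of fixed SD, LD-consistent GWAS z-scores, and randomized compound
signature libraries.  All generators are seed-deterministic and export the
generated truth so downstream modules can be scored for recovery.

LD model: first-order haplotype copying.  Each haplotype carries a latent
uniform that is either copied from the previous SNP (probability ``ld_decay``)
or redrawn; thresholding at each SNP's MAF yields alleles with exact marginal
frequency and adjacent-SNP allele correlation equal to ``ld_decay`` when MAFs
match (approximately otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, GwasRecord, GwasSummary, Snp


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults follow the reference design where one is stated (500 training
    samples; noise SD 0.3; noise levels span 0.1..1.0; 50 replicates per
    gene); the MAF spectrum, cis-SNP count, LD strength and causal
    architecture are this package's own documented choices.
    """

    n_samples: int = 500
    n_snps_per_gene: int = 30
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.7
    n_causal_per_gene: int = 3
    effect_sd: float = 0.05
    noise_level: float = 1.0
    noise_sd: float = 0.3
    annotation_enrichment: float = 5.0
    annotation_base_rate: float = 0.2
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        if self.n_snps_per_gene < 1:
            raise ValueError("need at least one SNP per gene")
        if self.n_causal_per_gene > self.n_snps_per_gene:
            raise ValueError("more causal SNPs than SNPs")
        if self.annotation_enrichment <= 0:
            raise ValueError("annotation_enrichment must be positive")


@dataclass
class AnnotationSet:
    """Binary SNP x feature annotation flags."""

    matrix: np.ndarray  # (n_snps, n_features) of 0/1
    features: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("annotation matrix must be binary")


def _haplotypes(rng: np.random.Generator, mafs: np.ndarray, ld: float,
                n: int) -> np.ndarray:
    """n haplotypes over len(mafs) SNPs via uniform copying (vectorized)."""
    p = len(mafs)
    u = np.empty((n, p))
    u[:, 0] = rng.random(n)
    fresh = rng.random((n, p))
    copy = rng.random((n, p)) < ld
    for s in range(1, p):
        u[:, s] = np.where(copy[:, s], u[:, s - 1], fresh[:, s])
    return (u < mafs).astype(float)


def simulate_genotypes(cfg: SimulationConfig, chrom: str = "1", start_pos: int = 1_000_000,
                       spacing: int = 5_000, rng: Optional[np.random.Generator] = None,
                       snp_prefix: str = "rs") -> GenotypeMatrix:
    """Simulate dosages as the sum of two independent copied haplotypes."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.n_snps_per_gene
    mafs = rng.uniform(*cfg.maf_range, size=p)
    dosages = (_haplotypes(rng, mafs, cfg.ld_decay, cfg.n_samples)
               + _haplotypes(rng, mafs, cfg.ld_decay, cfg.n_samples))
    snps = [
        Snp(f"{snp_prefix}{start_pos + s * spacing}", chrom, start_pos + s * spacing, "A", "G")
        for s in range(p)
    ]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(dosages, snps, samples)


def simulate_gene_architecture(cfg: SimulationConfig, snps: list,
                               rng: Optional[np.random.Generator] = None
                               ) -> tuple[np.ndarray, AnnotationSet]:
    """Draw causal effects and a linked binary annotation.

    Exactly ``n_causal_per_gene`` SNPs get effects ~ N(0, effect_sd^2).  The
    annotation is assigned so that the odds of carrying it are multiplied by
    ``annotation_enrichment`` for causal SNPs relative to the base rate.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = len(snps)
    if p == 0:
        raise ValueError("snps must be nonempty")
    beta = np.zeros(p)
    causal = rng.choice(p, size=cfg.n_causal_per_gene, replace=False)
    beta[causal] = rng.normal(0.0, cfg.effect_sd, size=cfg.n_causal_per_gene)
    a0 = cfg.annotation_base_rate
    odds1 = cfg.annotation_enrichment * a0 / (1 - a0)
    p1 = odds1 / (1 + odds1)
    rates = np.full(p, a0)
    rates[causal] = p1
    ann = (rng.random(p) < rates).astype(int).reshape(-1, 1)
    return beta, AnnotationSet(ann, ["regulatory"])


def simulate_expression(G: GenotypeMatrix, beta: np.ndarray, level: float,
                        noise_sd: float = 0.3, seed: int = 0,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Expression as genetic value plus level-scaled Gaussian noise."""
    if level < 0:
        raise ValueError("level must be non-negative")
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != G.n_snps:
        raise ValueError("beta length does not match SNP count")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=G.n_samples)
    return G.dosages @ beta + level * eps


def nearest_psd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    fixed = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def simulate_gwas_z(ld: np.ndarray, snps: Optional[list] = None,
                    causal_w: Optional[np.ndarray] = None, lam: float = 0.0,
                    n_reps: int = 1, seed: int = 0) -> list[GwasSummary]:
    """Draw GWAS z-score vectors consistent with an LD matrix.

    Under the null z ~ MVN(0, ld); under a gene-mediated alternative the mean
    is ``lam * ld @ causal_w``.  Non-PSD inputs are repaired to the nearest
    correlation matrix with a warning.
    """
    import warnings

    from scipy import stats

    ld = np.asarray(ld, dtype=float)
    eigmin = np.linalg.eigvalsh((ld + ld.T) / 2).min()
    if eigmin < -1e-8:
        warnings.warn(f"LD matrix not PSD (min eigenvalue {eigmin:.3g}); repairing")
        ld = nearest_psd(ld)
    p = ld.shape[0]
    mean = np.zeros(p)
    if causal_w is not None and lam != 0.0:
        mean = lam * ld @ np.asarray(causal_w, dtype=float)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(ld + 1e-10 * np.eye(p))
    out = []
    for _ in range(n_reps):
        z = mean + chol @ rng.standard_normal(p)
        if snps is None:
            recs = [GwasRecord(f"snp{j}", "A", "G", float(z[j]),
                               p=float(2 * stats.norm.sf(abs(z[j])))) for j in range(p)]
        else:
            recs = [GwasRecord(s.id, s.effect_allele, s.other_allele, float(z[j]),
                               p=float(2 * stats.norm.sf(abs(z[j])))) for j, s in enumerate(snps)]
        out.append(GwasSummary(recs))
    return out


def simulate_drug_library(n_genes: int, n_compounds: int,
                          planted_query: Optional[dict] = None,
                          seed: int = 0):
    """Random compound signatures: each compound a permutation of gene ranks.

    ``planted_query`` may carry keys ``up``/``down`` (gene lists), ``compound``
    (which compound to plant into), ``strength`` in [0, 1] and ``mode``
    ('mimic' pushes up-genes toward rank 1, 'reverse' the opposite).  Returns
    a DataFrame gene_id x compound of ranks (1 = most up-regulated).
    """
    import pandas as pd

    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    ranks = {}
    for c in range(n_compounds):
        name = f"cmpd{c:04d}"
        score = rng.standard_normal(n_genes)
        if planted_query is not None and planted_query.get("compound") == name:
            up = planted_query.get("up", [])
            down = planted_query.get("down", [])
            if len(up) + len(down) > n_genes:
                raise ValueError("planted set larger than the gene universe")
            s = float(planted_query.get("strength", 1.0))
            sign = 1.0 if planted_query.get("mode", "mimic") == "mimic" else -1.0
            gi = {g: i for i, g in enumerate(genes)}
            for g in up:
                score[gi[g]] += sign * s * 10.0
            for g in down:
                score[gi[g]] -= sign * s * 10.0
        # rank 1 = largest score (most up-regulated)
        order = np.argsort(-score, kind="stable")
        r = np.empty(n_genes, dtype=int)
        r[order] = np.arange(1, n_genes + 1)
        ranks[name] = r
    return pd.DataFrame(ranks, index=pd.Index(genes, name="gene_id"))


def simulate_trait_pair(seed: int, n_genes: int = 120, slope: float = 0.3,
                        coupled: bool = True, n_tissues: int = 2,
                        n_signal: int = 40) -> dict:
    """Two traits' per-gene association tables with a planted A -> B direction.

    Trait A has ``n_signal`` strong-signal genes; when ``coupled``, A's gene
    effects propagate into B with the given slope, while B additionally
    carries its own strong-signal genes unrelated to A.  The propagated
    effects sit mostly below B's own significance threshold, so B's
    significant set is dominated by B-own genes and the reverse (B -> A)
    regression is diluted toward the null — the regime in which
    bi-directional regression can call the direction.  When ``coupled`` is
    False the traits are independent (calibration null).

    Returns {"A": DataFrame, "B": DataFrame} with columns gene_id, tissue,
    z, p, q (q = unadjusted p here; the tables are already per-trait).
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    own_start = 2 * n_signal  # B's own signal block
    out = {"A": [], "B": []}
    for t in range(n_tissues):
        zA = np.where(np.arange(n_genes) < n_signal,
                      rng.normal(0, 4, n_genes), rng.normal(0, 1, n_genes))
        if coupled:
            zB = slope * zA + rng.normal(0, 1, n_genes)
            zB[own_start:] = rng.normal(0, 4, n_genes - own_start)
        else:
            zB = np.where(np.arange(n_genes) >= own_start,
                          rng.normal(0, 4, n_genes), rng.normal(0, 1, n_genes))
        for name, z in (("A", zA), ("B", zB)):
            p = 2 * _stats.norm.sf(np.abs(z))
            out[name].append(pd.DataFrame(
                {"gene_id": genes, "tissue": f"t{t}", "z": z, "p": p, "q": p}))
    return {k: pd.concat(v, ignore_index=True) for k, v in out.items()}


def simulate_gene_panel(cfg: SimulationConfig, n_genes: int, seed: Optional[int] = None,
                        level: Optional[float] = None):
    """Simulate a panel of independent genes with exported truth.

    Returns a list of dicts with keys ``gene_id``, ``G``, ``beta``, ``ann``,
    ``y``.  Each gene gets its own genotype block, architecture and
    expression at the requested noise level (``cfg.noise_level`` if None).
    """
    if seed is None:
        seed = cfg.seed
    if level is None:
        level = cfg.noise_level
    rng = np.random.default_rng(seed)
    panel = []
    for g in range(n_genes):
        grng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        G = simulate_genotypes(cfg, chrom=str(g % 22 + 1),
                               start_pos=1_000_000 + 10_000_000 * (g // 22),
                               rng=grng, snp_prefix=f"g{g}_rs")
        beta, ann = simulate_gene_architecture(cfg, G.snps, rng=grng)
        y = simulate_expression(G, beta, level, cfg.noise_sd, rng=grng)
        panel.append({"gene_id": f"GENE{g:04d}", "G": G, "beta": beta, "ann": ann, "y": y})
    return panel
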