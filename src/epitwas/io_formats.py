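"""Readers/writers for genotype, expression, GWAS, and model-weight tables.

All coordinates are 1-based inclusive (VCF convention); region filters are
inclusive on both ends.  Tabular formats are TSV; a trained model database is a
directory of two TSVs (weights, performance) plus a small JSON manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MODELDB_SCHEMA_VERSION = 1

# Strand-ambiguous allele pairs (indistinguishable from their reverse complement).
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class Snp:
    id: str
    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str


@dataclass
class GenotypeMatrix:
    """Samples x cis-SNP dosage matrix with SNP metadata.

    ``dosages`` holds values in [0, 2]; missing entries are mean-imputed at
    load time and counted in ``n_imputed``.
    """

    dosages: np.ndarray  # (n_samples, n_snps)
    snps: list[Snp]
    samples: list[str]
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x snps)")
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError("dosage shape does not match sample/snp metadata")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP ids must be unique")
        if any(s.pos <= 0 for s in self.snps):
            raise ValueError("SNP positions must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def subset_snps(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], [self.snps[i] for i in idx], list(self.samples)
        )

    def canonical_sort(self) -> "GenotypeMatrix":
        """Sort SNP columns by (chrom, pos, id) so load order never matters."""
        order = sorted(
            range(self.n_snps),
            key=lambda i: (self.snps[i].chrom, self.snps[i].pos, self.snps[i].id),
        )
        return self.subset_snps(order)


@dataclass
class Gene:
    id: str
    chrom: str
    tss: int  # 1-based
    strand: str = "+"
    start: Optional[int] = None
    end: Optional[int] = None


@dataclass
class ExpressionMatrix:
    values: np.ndarray  # (n_samples, n_genes)
    genes: list[Gene]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        if any(g.tss <= 0 for g in self.genes):
            raise ValueError("TSS must be positive")
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("expression shape does not match metadata")

    def gene_vector(self, gene_id: str) -> np.ndarray:
        j = [g.id for g in self.genes].index(gene_id)
        return self.values[:, j]


@dataclass
class GwasRecord:
    snp_id: str
    effect_allele: str
    other_allele: str
    z: float
    p: Optional[float] = None
    n: Optional[float] = None


@dataclass
class GwasSummary:
    records: list[GwasRecord]
    n_dropped: int = 0  # rows excluded at load (se <= 0 etc.)

    def __post_init__(self) -> None:
        for r in self.records:
            if not np.isfinite(r.z):
                raise ValueError(f"non-finite z for {r.snp_id}")

    def as_dict(self) -> dict[str, GwasRecord]:
        return {r.snp_id: r for r in self.records}


@dataclass
class ModelDb:
    """Per-gene sparse SNP weights plus a performance record per gene."""

    weights: pd.DataFrame  # gene_id, snp_id, chrom, pos, effect_allele, other_allele, weight
    performance: pd.DataFrame  # gene_id, r2_cv, perf_p, perf_q, n_snps_selected
    tissue: str = "synthetic"
    seed: Optional[int] = None

    WEIGHT_COLS = ["gene_id", "snp_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]
    PERF_COLS = ["gene_id", "r2_cv", "perf_p", "perf_q", "n_snps_selected"]

    def validate(self) -> None:
        missing = set(self.weights["gene_id"]) - set(self.performance["gene_id"])
        if missing:
            raise ValueError(f"weight rows for genes absent from performance: {sorted(missing)}")
        if (self.weights["weight"] == 0).any():
            raise ValueError("model weights must be nonzero")

    def genes(self) -> list[str]:
        return list(self.performance["gene_id"])


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype loading


def _in_region(chrom: str, pos: int, region: Optional[tuple]) -> bool:
    if region is None:
        return True
    rc, start, end = region
    return chrom == str(rc) and int(start) <= pos <= int(end)


def load_genotypes(path, region: Optional[tuple] = None) -> GenotypeMatrix:
    """Load a dosage matrix from VCF (GT or DS) or a tabular dosage TSV.

    Missing entries are imputed to the SNP mean; SNPs that are missing in every
    sample are dropped with a warning.  ``region`` is (chrom, start, end),
    1-based inclusive.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        return _load_vcf(path, region)
    return _load_dosage_tsv(path, region)


def _load_vcf(path: Path, region: Optional[tuple]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, cols = [], []
    n_imputed = 0
    for var in vcf:
        pos = var.POS
        chrom = var.CHROM
        if not _in_region(chrom, pos, region):
            continue
        alt = var.ALT[0] if var.ALT else "."
        fmts = var.FORMAT
        if "DS" in fmts:
            dose = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gts = var.genotype.array()
            dose = np.where((gts[:, :2] < 0).any(axis=1), np.nan,
                            np.clip(gts[:, :2], 0, None).sum(axis=1).astype(float))
        miss = ~np.isfinite(dose)
        if miss.all():
            warnings.warn(f"SNP {var.ID or pos} has no called genotypes; dropped")
            continue
        if miss.any():
            dose = np.where(miss, np.nanmean(dose), dose)
            n_imputed += int(miss.sum())
        snps.append(Snp(var.ID or f"{chrom}:{pos}", chrom, pos, alt, var.REF))
        cols.append(np.clip(dose, 0.0, 2.0))
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, snps, samples, n_imputed=n_imputed)


def _load_dosage_tsv(path: Path, region: Optional[tuple]) -> GenotypeMatrix:
    """Tabular dosages: columns snp_id, chrom, pos, effect_allele, other_allele,
    then one column per sample.  'NA' or empty cells are missing."""
    meta_cols = 5
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[meta_cols:]
        snps, cols = [], []
        n_imputed = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != meta_cols + len(samples):
                raise ParseError(f"{path}:{lineno}: expected {meta_cols + len(samples)} fields, got {len(parts)}")
            try:
                pos = int(parts[2])
                vals = np.array(
                    [float(v) if v not in ("", "NA", "nan") else np.nan for v in parts[meta_cols:]]
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not _in_region(parts[1], pos, region):
                continue
            miss = ~np.isfinite(vals)
            if miss.all():
                warnings.warn(f"SNP {parts[0]} all-missing; dropped")
                continue
            if miss.any():
                vals = np.where(miss, np.nanmean(vals), vals)
                n_imputed += int(miss.sum())
            snps.append(Snp(parts[0], parts[1], pos, parts[3].upper(), parts[4].upper()))
            cols.append(np.clip(vals, 0.0, 2.0))
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, snps, samples, n_imputed=n_imputed)


def save_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["snp_id", "chrom", "pos", "effect_allele", "other_allele"] + list(gm.samples)) + "\n")
        for j, s in enumerate(gm.snps):
            row = [s.id, s.chrom, str(s.pos), s.effect_allele, s.other_allele]
            row += [f"{v:.17g}" for v in gm.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# expression


def load_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["gene_id", "chrom", "tss", "strand"]
    samples = [c for c in df.columns if c not in meta]
    genes = [Gene(r.gene_id, str(r.chrom), int(r.tss), r.strand) for r in df.itertuples()]
    return ExpressionMatrix(df[samples].to_numpy().T, genes, samples)


def save_expression(em: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.id for g in em.genes],
            "chrom": [g.chrom for g in em.genes],
            "tss": [g.tss for g in em.genes],
            "strand": [g.strand for g in em.genes],
        }
    )
    for i, s in enumerate(em.samples):
        df[s] = em.values[i, :]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def load_gwas(path, allele_policy: str = "keep_ambiguous") -> GwasSummary:
    """Load GWAS summary statistics from TSV.

    Requires columns ``snp_id``, ``effect_allele``, ``other_allele`` and either
    ``z`` or (``beta``, ``se``); z is computed as beta/se when absent.  Rows
    with se <= 0 are dropped and counted.
    """
    if allele_policy not in ("keep_ambiguous", "drop_ambiguous"):
        raise ValueError(f"unknown allele_policy {allele_policy!r}")
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if "z" not in cols and not {"beta", "se"} <= cols:
        raise ValueError("GWAS file needs a 'z' column or both 'beta' and 'se'")
    n_dropped = 0
    records = []
    for r in df.itertuples():
        ea, oa = str(r.effect_allele).upper(), str(r.other_allele).upper()
        if allele_policy == "drop_ambiguous" and (ea, oa) in _AMBIGUOUS:
            n_dropped += 1
            continue
        if "z" in cols and np.isfinite(getattr(r, "z", np.nan)):
            z = float(r.z)
        else:
            se = float(r.se)
            if se <= 0:
                n_dropped += 1
                continue
            z = float(r.beta) / se
        records.append(
            GwasRecord(
                str(r.snp_id), ea, oa, z,
                p=float(r.p) if "p" in cols else None,
                n=float(r.n) if "n" in cols else None,
            )
        )
    return GwasSummary(records, n_dropped=n_dropped)


def save_gwas(gs: GwasSummary, path) -> None:
    pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in gs.records],
            "effect_allele": [r.effect_allele for r in gs.records],
            "other_allele": [r.other_allele for r in gs.records],
            "z": [r.z for r in gs.records],
            "p": [r.p if r.p is not None else np.nan for r in gs.records],
        }
    ).to_csv(path, sep="\t", index=False)


def harmonize_alleles(effect_a: str, other_a: str, ref_effect: str, ref_other: str) -> Optional[int]:
    """Return +1 (match), -1 (swapped alleles: flip sign), or None (mismatch)."""
    if (effect_a, other_a) == (ref_effect, ref_other):
        return 1
    if (effect_a, other_a) == (ref_other, ref_effect):
        return -1
    return None


# ---------------------------------------------------------------------------
# model database


def save_model_db(db: ModelDb, path) -> None:
    db.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    db.weights[ModelDb.WEIGHT_COLS].to_csv(
        path / "weights.tsv", sep="\t", index=False, float_format="%.17g"
    )
    db.performance[ModelDb.PERF_COLS].to_csv(
        path / "performance.tsv", sep="\t", index=False, float_format="%.17g"
    )
    manifest = {
        "schema_version": MODELDB_SCHEMA_VERSION,
        "tissue": db.tissue,
        "seed": db.seed,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model_db(path) -> ModelDb:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("schema_version") != MODELDB_SCHEMA_VERSION:
        raise ValueError(f"unsupported model DB schema version {manifest.get('schema_version')}")
    weights = pd.read_csv(path / "weights.tsv", sep="\t", dtype={"chrom": str, "gene_id": str, "snp_id": str})
    performance = pd.read_csv(path / "performance.tsv", sep="\t", dtype={"gene_id": str})
    if weights.empty:
        weights = pd.DataFrame(columns=ModelDb.WEIGHT_COLS)
    if performance.empty:
        performance = pd.DataFrame(columns=ModelDb.PERF_COLS)
    return ModelDb(weights, performance, tissue=manifest.get("tissue", ""), seed=manifest.get("seed"))
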