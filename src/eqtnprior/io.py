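"""Readers, writers and in-memory containers for the standard formats.

Containers
----------
:class:`GenotypeMatrix`   individuals x SNPs dosage matrix (values in [0, 2],
                          fractional allowed for imputed dosages).
:class:`ExpressionMatrix` genes x individuals phenotype matrix with
                          per-individual population / sex covariates.

Formats: VCF 4.x (GT or DS) via cyvcf2, plain dosage tables, BED3/6/12,
GFF3 via gffutils, TSV matrices. Coordinates are converted to the 0-based,
half-open convention of :mod:`eqtnprior.regions` on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GeneModel, GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "maf_filter",
    "read_annotation_track",
    "write_annotation_track",
    "read_gene_models",
    "write_gene_models_bed12",
    "read_expression_matrix",
    "write_expression_matrix",
]


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: identifier, position (0-based), alleles, MAF."""

    snp_id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"
    maf: float = float("nan")


@dataclass
class GenotypeMatrix:
    """Dosage matrix over ``individuals`` (rows) and ``snps`` (columns).

    Dosages count copies of the ALT allele, in [0, 2]; fractional values
    are allowed (imputed dosages). SNPs are sorted by (chrom, pos) and no
    entry is missing after loading.
    """

    individuals: list
    snps: list
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individuals) or m != len(self.snps):
            raise ValueError("dosage shape does not match individuals x snps")
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages after loading")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency recomputed from the dosages."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=int)

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def restrict(self, window: GenomicInterval) -> "GenotypeMatrix":
        """SNPs falling in ``window`` (half-open membership)."""
        keep = [
            i
            for i, s in enumerate(self.snps)
            if s.chrom == window.chrom and window.contains(s.pos)
        ]
        return self.subset_snps(np.array(keep, dtype=int))

    def with_recomputed_maf(self) -> "GenotypeMatrix":
        mafs = self.maf()
        snps = [
            SnpRecord(s.snp_id, s.chrom, s.pos, s.ref, s.alt, float(f))
            for s, f in zip(self.snps, mafs)
        ]
        return GenotypeMatrix(list(self.individuals), snps, self.dosages)


@dataclass
class ExpressionMatrix:
    """Genes x individuals expression values plus individual covariates.

    ``covariates`` is a DataFrame indexed by individual id; when paired
    with a GenotypeMatrix the individual ordering must be identical.
    """

    genes: list
    individuals: list
    values: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.individuals)):
            raise ValueError("values shape does not match genes x individuals")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.individuals)

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.genes.index(gene_id)]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _finalize_genotypes(individuals, records, columns, mean_impute: bool) -> GenotypeMatrix:
    if not records:
        return GenotypeMatrix(list(individuals), [], np.empty((len(individuals), 0)))
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    records = [records[i] for i in order]
    columns = [columns[i] for i in order]
    seen = set()
    for r in records:
        key = (r.chrom, r.pos)
        if key in seen:
            raise ValueError(f"duplicate SNP position {r.chrom}:{r.pos}")
        seen.add(key)
    dos = np.column_stack(columns).astype(float)
    if np.isnan(dos).any():
        if not mean_impute:
            raise ValueError(
                "missing genotypes present; pass mean_impute=True to fill "
                "them with the per-SNP mean dosage"
            )
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    return GenotypeMatrix(list(individuals), records, dos).with_recomputed_maf()


def _read_vcf(path, mean_impute: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    records, columns = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(var.gt_types)
            col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        records.append(
            SnpRecord(var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS - 1, var.REF, var.ALT[0])
        )
        columns.append(col)
    if n_skipped:
        logger.info("skipped %d multi-allelic VCF records", n_skipped)
    return _finalize_genotypes(individuals, records, columns, mean_impute)


def _read_dosage_table(path, mean_impute: bool) -> GenotypeMatrix:
    """Plain dosage table: columns snp_id, chrom, pos, ref, alt, then one
    column per individual (header row of ids); pos is 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"dosage table missing required column {c!r}")
    individuals = [c for c in df.columns if c not in meta_cols]
    records = [
        SnpRecord(str(r.snp_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    columns = [df[individuals].iloc[i].to_numpy(dtype=float) for i in range(len(df))]
    return _finalize_genotypes(individuals, records, columns, mean_impute)


def read_genotype_matrix(path, fmt: str | None = None, mean_impute: bool = True) -> GenotypeMatrix:
    """Load a genotype dosage matrix from VCF or a plain dosage table.

    Multi-allelic VCF records are skipped (count logged); missing genotypes
    are mean-imputed per SNP by default, or raise when ``mean_impute`` is
    False. SNPs are sorted by (chrom, pos); duplicated positions raise.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz") else "dosage_table"
    if fmt == "vcf":
        return _read_vcf(path, mean_impute)
    if fmt == "dosage_table":
        return _read_dosage_table(path, mean_impute)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotype_matrix(g: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    """Write dosages as an uncompressed VCF 4.2 (DS field) or dosage table."""
    path = Path(path)
    if fmt == "dosage_table":
        df = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in g.snps],
                "chrom": [s.chrom for s in g.snps],
                "pos": [s.pos for s in g.snps],
                "ref": [s.ref for s in g.snps],
                "alt": [s.alt for s in g.snps],
            }
        )
        for i, ind in enumerate(g.individuals):
            df[ind] = g.dosages[i]
        df.to_csv(path, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format {fmt!r}")
    chroms = sorted({s.chrom for s in g.snps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in g.individuals) + "\n")
        for j, s in enumerate(g.snps):
            cells = []
            for d in g.dosages[:, j]:
                if d == round(d):
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(round(d))]
                else:
                    gt = "./."
                cells.append(f"{gt}:{d:.6g}")
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref}\t{s.alt}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.01) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency strictly below ``min_maf``.

    The boundary is kept (MAF exactly ``min_maf`` passes); SNP order is
    preserved and MAF is recomputed from dosages before comparison.
    """
    mafs = g.maf()
    return g.subset_snps(mafs >= min_maf).with_recomputed_maf()


# ---------------------------------------------------------------------------
# intervals / gene models
# ---------------------------------------------------------------------------


def read_annotation_track(path, merge: bool = False) -> list:
    """Read a BED3+ file into a sorted list of :class:`GenomicInterval`.

    BED is native 0-based half-open. Malformed lines raise with the
    offending line number; with ``merge=True`` overlapping intervals are
    unioned per chromosome.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: expected >= 3 fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from None
            strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: invalid interval at line {lineno}: {exc}") from None
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    if merge and intervals:
        intervals = merge_intervals(intervals)
    return intervals


def write_annotation_track(intervals, path, name: str | None = None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                label = f"{name or 'iv'}_{k}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")


def _gene_from_bed12(parts, lineno, path) -> GeneModel:
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    gene_id, strand = parts[3], parts[5]
    n_blocks = int(parts[9])
    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
    offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError(f"{path}: BED12 block count mismatch at line {lineno}")
    exons = tuple(
        GenomicInterval(chrom, start + off, start + off + sz, strand)
        for off, sz in zip(offsets, sizes)
    )
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), exons)


def read_gene_models(path, fmt: str | None = None) -> list:
    """Read gene models from BED12 or GFF3 into :class:`GeneModel` objects."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed12"
    if fmt == "bed12":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 12:
                    raise ValueError(f"{path}: BED12 requires 12 fields (line {lineno})")
                genes.append(_gene_from_bed12(parts, lineno, path))
        return genes
    if fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for feat in db.features_of_type("gene"):
            exons = tuple(
                GenomicInterval(ex.seqid, ex.start - 1, ex.end, feat.strand)
                for ex in db.children(feat, featuretype="exon", order_by="start")
            )
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            genes.append(
                GeneModel(gene_id, GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand), exons)
            )
        return genes
    raise ValueError(f"unknown gene-model format {fmt!r}")


def write_gene_models_bed12(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = g.exons or (iv,)
            sizes = ",".join(str(ex.length) for ex in exons) + ","
            offsets = ",".join(str(ex.start - iv.start) for ex in exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression_matrix(path, covariates_path=None) -> ExpressionMatrix:
    """Read a genes x individuals TSV (first column gene ids, header row of
    individual ids); optionally attach a covariate TSV indexed by individual."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cov = pd.DataFrame(index=df.columns)
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t", index_col=0)
        cov = cov.loc[df.columns]
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        individuals=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        covariates=cov,
    )


def write_expression_matrix(e: ExpressionMatrix, path, covariates_path=None) -> None:
    e.to_frame().to_csv(path, sep="\t")
    if covariates_path is not None and len(e.covariates.columns):
        e.covariates.to_csv(covariates_path, sep="\t")
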