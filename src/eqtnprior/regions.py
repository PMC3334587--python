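"""Genomic coordinate primitives: intervals, gene models, cis-windows.

Every internal surface of the package uses 0-based, half-open coordinates
(``[start, end)``, BED-style). 1-based formats (VCF, GFF3) are converted on
read and on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "cis_window",
    "merge_intervals",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True iff ``start <= pos < end`` (half-open membership)."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A strand-aware gene: outer span, exon structure, TSS and TES.

    The TSS is the 5' end of the gene on its own strand (``interval.start``
    on '+', ``interval.end - 1`` on '-'); the TES is the 3' end. Exons must
    be sorted, non-overlapping and contained in the outer interval.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError("gene interval must be stranded ('+' or '-')")
        self.exons = tuple(self.exons)
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError("exon on a different chromosome than the gene")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError("exon outside the gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based bp)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tes(self) -> int:
        """Strand-aware transcription end site (0-based bp)."""
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start

    def in_exon(self, pos: int) -> bool:
        return any(ex.contains(pos) for ex in self.exons)

    def in_intron(self, pos: int) -> bool:
        return self.interval.contains(pos) and not self.in_exon(pos)


def cis_window(gene: GeneModel, up: int = 100_000, down: int = 100_000) -> GenomicInterval:
    """Candidate region for a gene: ``up`` bp 5' of the TSS through ``down``
    bp 3' of the TES, strand-aware and clipped at position 0.

    On the '+' strand the upstream flank extends left of the gene; on the
    '-' strand it extends right. With symmetric flanks the window is the
    same interval either way.
    """
    if gene.strand == "+":
        start = gene.interval.start - up
        end = gene.interval.end + down
    else:
        start = gene.interval.start - down
        end = gene.interval.end + up
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def merge_intervals(intervals) -> list:
    """Merge overlapping or touching intervals, per chromosome.

    Returns a new sorted list; strand information is dropped (merged
    intervals get strand '.').
    """
    out = []
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out
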