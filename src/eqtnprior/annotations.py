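"""Annotation design construction and sequence-level annotation calling.

The hierarchical model's prior covariates are binary indicators
delta[j, l] = 1 iff SNP j lies inside annotation l. This module builds
those indicators from interval tracks, derives the background features
(strand-aware distance-to-TSS bins plus exon/intron/downstream structure),
scans promoter sequence for known core-promoter motifs and overrepresented
hexamers, and includes a simple read-pileup peak caller with a Monte-Carlo
null threshold for turning raw cut-site positions into interval tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .regions import GeneModel, GenomicInterval, merge_intervals

__all__ = [
    "MotifSpec",
    "DEFAULT_CORE_PROMOTER_MOTIFS",
    "build_indicator_matrix",
    "background_features",
    "DEFAULT_DISTANCE_EDGES",
    "scan_core_promoter_motifs",
    "overrepresented_hexamers",
    "shift_reads",
    "call_peaks",
    "track_with_min_marks",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC pattern searched in a window around the TSS."""

    name: str
    pattern: str
    window: int = 50  # +/- bp around the TSS

    def __post_init__(self):
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC symbols in pattern: {sorted(bad)}")


# Literature consensus sequences for the core promoter. The initiator (Inr)
# consensus is not uniquely standardized; YYANWYY is the common vertebrate
# form and is an assumption here.
DEFAULT_CORE_PROMOTER_MOTIFS = (
    MotifSpec("TATA", "TATAAA"),
    MotifSpec("GC_box", "CCCCGCCCCG"),
    MotifSpec("BRE", "SSRCGCC"),
    MotifSpec("DPE", "RGWYV"),
    MotifSpec("Inr", "YYANWYY"),
)


# ---------------------------------------------------------------------------
# indicator / background design
# ---------------------------------------------------------------------------


def _membership(positions: np.ndarray, intervals, chrom: str) -> np.ndarray:
    """Binary membership of positions in a track, half-open intervals."""
    ivs = [iv for iv in intervals if iv.chrom == chrom]
    if not ivs:
        return np.zeros(len(positions), dtype=int)
    merged = merge_intervals(ivs)
    starts = np.array([iv.start for iv in merged])
    ends = np.array([iv.end for iv in merged])
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = positions[ok] < ends[idx[ok]]
    return inside.astype(int)


def build_indicator_matrix(tracks: dict, gene: GeneModel, snps) -> pd.DataFrame:
    """SNP x annotation indicator matrix for one gene's cis SNPs.

    ``tracks`` maps annotation name -> iterable of GenomicInterval (any
    chromosome; only the gene's chromosome is consulted). Membership is
    half-open: delta = 1 iff start <= pos < end for some interval.
    """
    positions = np.array([s.pos for s in snps], dtype=int)
    data = {
        name: _membership(positions, ivs, gene.chrom) for name, ivs in tracks.items()
    }
    return pd.DataFrame(data, index=[s.snp_id for s in snps])


DEFAULT_DISTANCE_EDGES = (1_000, 5_000, 20_000, 100_000)


def _distance_bin_labels(edges) -> list:
    labels = []
    rev = list(edges)[::-1]
    for hi, lo in zip(rev, rev[1:]):
        labels.append(f"up_{lo}_{hi}")
    labels.append(f"up_0_{edges[0]}")
    labels.append(f"down_0_{edges[0]}")
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"down_{lo}_{hi}")
    return labels


def background_features(snps, gene: GeneModel, distance_edges=DEFAULT_DISTANCE_EDGES) -> pd.DataFrame:
    """Background design: one-hot signed distance-to-TSS bin per SNP plus
    gene-structure indicators (in_exon, in_intron, downstream_of_tes).

    Distance is strand-aware: negative = 5' of the TSS on the gene's
    strand. With edges (1k, 5k, 20k, 100k) there are 8 bins; distances
    beyond the outermost edge are clamped into the outermost bin, so the
    bins partition the cis-window (exactly one bin active per SNP).
    """
    positions = np.array([s.pos for s in snps], dtype=int)
    if gene.strand == "+":
        d = positions - gene.tss
    else:
        d = gene.tss - positions
    edges = list(distance_edges)
    bounds = [-e for e in edges[::-1]] + [0] + edges
    # clamp into the outer bins
    d = np.clip(d, bounds[0], bounds[-1] - 1)
    bin_idx = np.searchsorted(bounds, d, side="right") - 1
    bin_idx = np.clip(bin_idx, 0, len(bounds) - 2)
    labels = _distance_bin_labels(edges)
    data = {lab: (bin_idx == i).astype(int) for i, lab in enumerate(labels)}
    in_exon = np.array([int(gene.in_exon(p)) for p in positions])
    in_intron = np.array([int(gene.in_intron(p)) for p in positions])
    if gene.strand == "+":
        downstream = positions > gene.tes
    else:
        downstream = positions < gene.tes
    data["in_exon"] = in_exon
    data["in_intron"] = in_intron
    data["downstream_of_tes"] = downstream.astype(int)
    return pd.DataFrame(data, index=[s.snp_id for s in snps])


# ---------------------------------------------------------------------------
# core promoter sequence
# ---------------------------------------------------------------------------


def _iupac_match(seq: str, pattern: str) -> bool:
    return all(base in IUPAC[sym] for base, sym in zip(seq, pattern.upper()))


def scan_core_promoter_motifs(seq: str, tss_index: int, motifs=DEFAULT_CORE_PROMOTER_MOTIFS, window: int = 50) -> pd.DataFrame:
    """All sense-strand IUPAC motif matches fully inside TSS +/- ``window``.

    ``seq`` is the (uppercase) genomic sequence containing the promoter;
    ``tss_index`` is the TSS position within ``seq``. Matches are returned
    with start/end relative to the TSS (0 = the TSS base); overlapping
    occurrences are all reported.
    """
    seq = seq.upper()
    lo, hi = tss_index - window, tss_index + window  # inclusive window
    if lo < 0 or hi >= len(seq):
        raise ValueError("sequence does not cover the promoter window")
    rows = []
    for spec in motifs:
        m = len(spec.pattern)
        for start in range(lo, hi - m + 2):
            if start + m - 1 > hi:
                break
            if _iupac_match(seq[start : start + m], spec.pattern):
                rows.append((spec.name, start - tss_index, start - tss_index + m))
    return pd.DataFrame(rows, columns=["motif", "rel_start", "rel_end"])


def _hexamer_counts(seqs) -> dict:
    counts: dict = {}
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - 5):
            word = s[i : i + 6]
            if set(word) <= {"A", "C", "G", "T"}:
                counts[word] = counts.get(word, 0) + 1
    return counts


def overrepresented_hexamers(core_seqs, control_seqs, top_n: int = 1000, p_max: float = 1e-10) -> pd.DataFrame:
    """Hexamers overrepresented in core-promoter sequence versus a control.

    Overlapping occurrences are counted, pooled over genes. For each
    hexamer a one-sided binomial test asks whether its count among all
    core-region hexamers exceeds the control-derived expected proportion.
    Up to ``top_n`` hexamers with P < ``p_max`` are returned, ranked by P.
    """
    core = _hexamer_counts(core_seqs)
    ctrl = _hexamer_counts(control_seqs)
    n_core = sum(core.values())
    n_ctrl = sum(ctrl.values())
    if n_ctrl == 0:
        raise ValueError("control sequences contain no hexamers")
    rows = []
    for word, k in core.items():
        p0 = ctrl.get(word, 0) / n_ctrl
        if p0 >= 1.0:
            pval = 1.0
        else:
            pval = float(stats.binom.sf(k - 1, n_core, p0))
        if pval < p_max:
            rows.append((word, k, ctrl.get(word, 0), p0, pval))
    df = pd.DataFrame(rows, columns=["hexamer", "core_count", "control_count", "p0", "p"])
    df = df.sort_values(["p", "core_count"], ascending=[True, False], kind="mergesort")
    return df.head(top_n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# read-pileup peak calling
# ---------------------------------------------------------------------------


def shift_reads(positions, strands, shift: int = 73, on_unstranded: str = "error") -> np.ndarray:
    """Shift read positions toward the fragment center: '+' reads ``shift``
    bp 3' (rightward), '-' reads ``shift`` bp 5' (leftward).

    Shifted positions below 0 are clamped to 0 with a warning. Unstranded
    reads raise by default; ``on_unstranded='keep'`` passes them through.
    """
    positions = np.asarray(positions, dtype=int)
    strands = np.asarray(strands)
    out = positions.copy()
    plus = strands == "+"
    minus = strands == "-"
    other = ~(plus | minus)
    if other.any():
        if on_unstranded == "error":
            raise ValueError("unstranded reads present")
        if on_unstranded != "keep":
            raise ValueError("on_unstranded must be 'error' or 'keep'")
    out[plus] += shift
    out[minus] -= shift
    if (out < 0).any():
        warnings.warn("shifted read positions clamped at 0")
        out = np.maximum(out, 0)
    return out


def _window_scores(positions, genome_length: int, window: int, bandwidth: float) -> np.ndarray:
    """Smoothed read count per 1-bp-stepped window of length ``window``."""
    counts = np.bincount(np.asarray(positions, dtype=int), minlength=genome_length).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    win = csum[window:] - csum[:-window]  # reads in [i, i+window)
    return gaussian_filter1d(win, sigma=bandwidth, mode="constant")


def call_peaks(
    positions,
    genome_length: int,
    window: int = 150,
    bandwidth: float = 50.0,
    fdr_target: float = 1e-6,
    n_mc: int | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> list:
    """Sliding-window peak caller with a Monte-Carlo null threshold.

    Reads are treated as point positions. The score at window start i is
    the read count in [i, i+window) smoothed by a Gaussian kernel
    (sd = ``bandwidth`` bp); windows advance 1 bp. The threshold is set by
    placing the same number of reads uniformly on the genome ``n_mc``
    times and taking the smallest score exceeded by fewer than
    ``fdr_target`` of all null window scores. Windows above threshold are
    merged by contiguity into maximal peak intervals.
    """
    positions = np.asarray(positions, dtype=int)
    if genome_length <= window:
        raise ValueError("genome_length must exceed the window size")
    if len(positions) == 0:
        return []
    if (positions < 0).any() or (positions >= genome_length).any():
        raise ValueError("read positions outside [0, genome_length)")
    n_windows = genome_length - window + 1
    if n_mc is None:
        # enough pooled null windows that the tail quantile is resolvable
        n_mc = max(3, int(np.ceil(10.0 / (fdr_target * n_windows))))
    rng = np.random.default_rng(seed)
    null_tail = []
    k_keep = max(int(np.ceil(2 * fdr_target * n_windows)) + 10, 10)
    for _ in range(n_mc):
        null_pos = rng.integers(0, genome_length, size=len(positions))
        scores = _window_scores(null_pos, genome_length, window, bandwidth).astype(np.float32)
        # keep only the extreme tail of each replicate to bound memory
        null_tail.append(np.partition(scores, len(scores) - k_keep)[-k_keep:])
    null_tail = np.concatenate(null_tail)
    n_null = n_mc * n_windows
    n_allow = int(np.floor(fdr_target * n_null))
    # threshold = smallest value with < fdr_target exceedance frequency
    tail_sorted = np.sort(null_tail)[::-1]
    if n_allow >= len(tail_sorted):
        raise RuntimeError("Monte-Carlo tail too short; increase n_mc")
    threshold = float(tail_sorted[n_allow]) + 1e-9
    obs = _window_scores(positions, genome_length, window, bandwidth)
    above = obs > threshold
    peaks = []
    if above.any():
        d = np.diff(above.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [len(above)]
        for s, e in zip(starts, ends):
            peaks.append(GenomicInterval(chrom, int(s), int(e - 1 + window)))
    return peaks


def track_with_min_marks(base_track, mark_tracks, min_marks: int = 2) -> list:
    """Portions of ``base_track`` covered by at least ``min_marks`` of the
    given mark tracks (a derived composite annotation, e.g. open-chromatin
    sites supported by two or more histone marks)."""
    chroms = sorted({iv.chrom for iv in base_track})
    out = []
    for chrom in chroms:
        events = []  # (pos, delta)
        base = [iv for iv in base_track if iv.chrom == chrom]
        for track in mark_tracks:
            for iv in merge_intervals([v for v in track if v.chrom == chrom]):
                events.append((iv.start, 1))
                events.append((iv.end, -1))
        if not events:
            continue
        events.sort()
        covered = []  # maximal intervals with coverage >= min_marks
        depth, open_start = 0, None
        for pos, delta in events:
            new_depth = depth + delta
            if depth < min_marks <= new_depth:
                open_start = pos
            elif new_depth < min_marks <= depth:
                covered.append((open_start, pos))
                open_start = None
            depth = new_depth
        cstarts = np.array([c[0] for c in covered], dtype=int)
        cends = np.array([c[1] for c in covered], dtype=int)
        for iv in base:
            lo = np.searchsorted(cends, iv.start, side="right")
            hi = np.searchsorted(cstarts, iv.end, side="left")
            for i in range(lo, hi):
                s = max(iv.start, cstarts[i])
                e = min(iv.end, cends[i])
                if e > s:
                    out.append(GenomicInterval(chrom, int(s), int(e)))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))
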