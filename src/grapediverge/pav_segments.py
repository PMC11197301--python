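"""Windowed genome-specific segments and species-specific PAV genes.

The query genome is tiled into overlapping windows (500 bp, step 100 bp
by default); a window whose aligned coverage against the reference is
below 25% — or that does not align at all — is *genome-specific*.
Overlapping specific windows are merged into segments, and query genes
lying in those segments are the species-specific presence/absence
variation (PAV) genes.

A built-in exact k-mer chained matcher can derive window coverage from
raw sequences when no external aligner output is available; PAF / TSV
alignment tables are the production input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_io import GenomeAnnotation, Interval, merge_intervals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    size: int = 500
    step: int = 100

    def __post_init__(self):
        if not (0 < self.step <= self.size):
            raise ValueError(f"invalid window spec size={self.size} step={self.step}")


@dataclass
class CoverageRecord:
    window: Interval
    covered_fraction: float
    aligned: bool


@dataclass
class SpecificSegmentSet:
    segments: list[Interval]
    total_length: int
    n_windows_specific: int


@dataclass
class PAVGeneSet:
    """Species-specific genes with their overlap fraction against segments."""

    genes: dict[str, float]


def make_windows(chrom_lengths: dict[str, int], spec: WindowSpec = WindowSpec()) -> list[Interval]:
    """Full-length sliding windows starting at 1, 1+step, ...

    Chromosomes shorter than one window yield none (logged).
    """
    out: list[Interval] = []
    for chrom, length in sorted(chrom_lengths.items()):
        if length < spec.size:
            logger.info("chromosome %s (%d bp) shorter than window size", chrom, length)
            continue
        start = 1
        while start + spec.size - 1 <= length:
            out.append(Interval(chrom, start, start + spec.size - 1))
            start += spec.step
    return out


def _union_length(window: Interval, pieces: list[tuple[int, int]]) -> int:
    """Length of the union of [start, end] pieces clipped to the window."""
    clipped = sorted(
        (max(s, window.start), min(e, window.end)) for s, e in pieces
    )
    total = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if e < s:
            continue
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def window_coverage(
    windows: list[Interval], alignments: list[Interval]
) -> list[CoverageRecord]:
    """Per-window aligned coverage fraction from query-side alignment intervals.

    ``covered_fraction`` is the union of overlapping alignment intervals
    intersected with the window, divided by the window length.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in alignments:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for pieces in by_chrom.values():
        pieces.sort()
    out: list[CoverageRecord] = []
    for w in windows:
        pieces = [
            (s, e)
            for s, e in by_chrom.get(w.chrom, [])
            if s <= w.end and e >= w.start
        ]
        cov = _union_length(w, pieces) if pieces else 0
        out.append(
            CoverageRecord(w, covered_fraction=cov / len(w), aligned=bool(pieces))
        )
    return out


def call_specific_segments(
    records: list[CoverageRecord], threshold: float = 0.25
) -> SpecificSegmentSet:
    """Merge windows with no alignment or coverage strictly below threshold.

    A window with coverage exactly at the threshold is NOT specific.
    """
    specific = [
        r.window for r in records if (not r.aligned) or r.covered_fraction < threshold
    ]
    merged = merge_intervals(specific)
    return SpecificSegmentSet(
        segments=merged,
        total_length=sum(len(s) for s in merged),
        n_windows_specific=len(specific),
    )


def assign_pav_genes(
    segments: SpecificSegmentSet | list[Interval],
    annotation: GenomeAnnotation,
    min_gene_overlap: float = 0.5,
    strict_containment: bool = False,
) -> PAVGeneSet:
    """Genes lying within specific segments.

    A gene is listed when the fraction of its span covered by segments is
    >= ``min_gene_overlap`` (or, with ``strict_containment``, when it is
    fully inside one segment).
    """
    segs = segments.segments if isinstance(segments, SpecificSegmentSet) else segments
    by_chrom: dict[str, list[Interval]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: dict[str, float] = {}
    for gene in annotation.genes:
        span = Interval(gene.chrom, gene.start, gene.end)
        pieces = [
            (s.start, s.end)
            for s in by_chrom.get(gene.chrom, [])
            if s.start <= span.end and s.end >= span.start
        ]
        if not pieces:
            continue
        frac = _union_length(span, pieces) / len(span)
        if strict_containment:
            if any(
                s.contains(span) for s in by_chrom.get(gene.chrom, [])
            ):
                out[gene.gene_id] = frac
        elif frac >= min_gene_overlap:
            out[gene.gene_id] = frac
    return PAVGeneSet(genes=out)


# ---------------------------------------------------------------------------
# Exact k-mer window matcher (aligner-free coverage path)


def kmer_window_coverage(
    windows: list[Interval],
    query_seqs: dict[str, str],
    reference_seqs: dict[str, str],
    k: int = 21,
) -> list[CoverageRecord]:
    """Window coverage by chained exact k-mer matches against the reference.

    For each window, positions covered by any query k-mer occurring
    anywhere in the reference are unioned; the covered fraction plays the
    role of aligner coverage.  Exact matching makes this a conservative
    stand-in suitable for synthetic and closely related sequences.
    """
    ref_kmers: set[str] = set()
    for seq in reference_seqs.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            ref_kmers.add(seq[i : i + k])
    out: list[CoverageRecord] = []
    for w in windows:
        seq = query_seqs[w.chrom][w.start - 1 : w.end].upper()
        covered = [False] * len(seq)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in ref_kmers:
                for j in range(i, i + k):
                    covered[j] = True
        frac = sum(covered) / len(seq)
        out.append(CoverageRecord(w, covered_fraction=frac, aligned=frac > 0))
    return out
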