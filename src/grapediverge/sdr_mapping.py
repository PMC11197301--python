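"""Ortholog-anchored interval lift-over and SDR haplotype gene-content
comparison.

The sex-determination region (SDR) of one grape genome can be located in
another by mapping its interval through one-to-one ortholog anchors:
anchors overlapping (or immediately flanking) the source interval define
the target as the span of their partner coordinates.  Gene content of
the resulting haplotype intervals is compared at the level of normalized
functional labels (multiset difference + relative-order check).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core_io import GenomeAnnotation, Interval


@dataclass(frozen=True)
class OrthologAnchor:
    gene_a: str
    loc_a: Interval
    gene_b: str
    loc_b: Interval


@dataclass
class MappedInterval:
    source: Interval
    target: Interval
    anchors: list[str]
    orientation: str  # "same" | "inverted"


@dataclass
class HaplotypeGeneContent:
    """Coordinate-ordered (gene id, functional label) list for one haplotype."""

    entries: list[tuple[str, str]]

    @property
    def labels(self) -> list[str]:
        return [normalize_label(lab) for _id, lab in self.entries]


@dataclass
class ContentDiff:
    shared: list[str]
    gained: list[str]  # labels only in A
    lost: list[str]  # labels only in B
    order_conserved: bool


def normalize_label(label: str) -> str:
    return " ".join(label.lower().split())


def sort_anchors(anchors: list[OrthologAnchor]) -> list[OrthologAnchor]:
    ids_a = [a.gene_a for a in anchors]
    ids_b = [a.gene_b for a in anchors]
    if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
        raise ValueError("anchor map must be one-to-one (injective both ways)")
    return sorted(anchors, key=lambda a: (a.loc_a.chrom, a.loc_a.start))


def liftover_interval(
    anchors: list[OrthologAnchor], source: Interval, flank_anchors: int = 1
) -> MappedInterval:
    """Map ``source`` from genome A to genome B through ortholog anchors.

    Anchors whose A-gene overlaps the source, plus ``flank_anchors`` on
    each side, span the target; orientation comes from the sign of the
    correlation between A and B coordinates of the supporting anchors.
    """
    srt = [a for a in sort_anchors(anchors) if a.loc_a.chrom == source.chrom]
    inside = [
        i for i, a in enumerate(srt) if a.loc_a.overlap_bp(source) > 0
    ]
    if inside:
        lo = max(0, inside[0] - flank_anchors)
        hi = min(len(srt), inside[-1] + 1 + flank_anchors)
        support = srt[lo:hi]
    else:
        before = [i for i, a in enumerate(srt) if a.loc_a.end < source.start]
        after = [i for i, a in enumerate(srt) if a.loc_a.start > source.end]
        support = [srt[i] for i in before[-flank_anchors:]] + [
            srt[i] for i in after[:flank_anchors]
        ]
    if not support:
        raise ValueError(f"unmappable interval {source}")
    chroms_b = {a.loc_b.chrom for a in support}
    if len(chroms_b) > 1:
        # keep the majority target chromosome
        counts = {c: sum(a.loc_b.chrom == c for a in support) for c in chroms_b}
        top = max(sorted(counts), key=lambda c: counts[c])
        support = [a for a in support if a.loc_b.chrom == top]
    target = Interval(
        support[0].loc_b.chrom,
        min(a.loc_b.start for a in support),
        max(a.loc_b.end for a in support),
    )
    if len(support) >= 2:
        xs = [a.loc_a.start for a in support]
        ys = [a.loc_b.start for a in support]
        rho = np.corrcoef(xs, ys)[0, 1]
        orientation = "inverted" if rho < 0 else "same"
    else:
        orientation = "same"
    return MappedInterval(source, target, [a.gene_a for a in support], orientation)


def compare_gene_content(
    a: HaplotypeGeneContent, b: HaplotypeGeneContent
) -> ContentDiff:
    """Multiset-align two haplotype gene lists by normalized label.

    ``gained`` are label instances present only in A, ``lost`` only in B;
    ``order_conserved`` is true when the shared label instances occur in
    the same relative order in both haplotypes.
    """
    la, lb = a.labels, b.labels
    from collections import Counter

    ca, cb = Counter(la), Counter(lb)
    shared_counts = {lab: min(ca[lab], cb[lab]) for lab in ca if lab in cb}
    gained = sorted((ca - cb).elements())
    lost = sorted((cb - ca).elements())

    def shared_seq(labels):
        remaining = dict(shared_counts)
        seq = []
        for lab in labels:
            if remaining.get(lab, 0) > 0:
                seq.append(lab)
                remaining[lab] -= 1
        return seq

    sa, sb = shared_seq(la), shared_seq(lb)
    return ContentDiff(
        shared=sa, gained=gained, lost=lost, order_conserved=(sa == sb)
    )


def count_genes_in_interval(annotation: GenomeAnnotation, interval: Interval) -> int:
    """Genes overlapping the interval by >= 1 bp (inclusive coordinates)."""
    if annotation.genes and interval.chrom not in annotation.chrom_lengths:
        raise ValueError(f"unknown chromosome {interval.chrom}")
    return sum(
        1
        for g in annotation.genes
        if g.chrom == interval.chrom
        and g.start <= interval.end
        and g.end >= interval.start
    )


# ---------------------------------------------------------------------------
# Packaged haplotype fixtures

VA_SDR = Interval("chr2", 5_055_465, 5_198_824)


def _load_tsv(name: str) -> list[dict[str, str]]:
    path = resources.files("grapediverge.data").joinpath(name)
    with path.open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_sdr_annotation() -> GenomeAnnotation:
    """Packaged annotation of the 16 genes of the Amur grape putative SDR
    (chr2:5,055,465-5,198,824).

    Gene coordinates inside the interval are synthetic placements; the
    gene ids and functional labels follow the published haplotype.
    """
    from .core_io import GeneModel

    rows = _load_tsv("sdr_va_genes.tsv")
    genes = [
        GeneModel(
            r["gene_id"], r["chrom"], int(r["start"]), int(r["end"]), r["strand"], i
        )
        for i, r in enumerate(rows)
    ]
    return GenomeAnnotation([("chr2", 6_000_000)], genes)


def load_haplotype_content(which: str) -> HaplotypeGeneContent:
    """Packaged female-haplotype SDR gene-content lists.

    ``which`` is ``va_female`` or ``vv_female``.  The Vv-side gene ids
    are synthetic placeholders (only the labels are published); labels
    are transcribed functional names.
    """
    name = {
        "va_female": "sdr_va_female_content.tsv",
        "vv_female": "sdr_vv_female_content.tsv",
    }[which]
    rows = _load_tsv(name)
    return HaplotypeGeneContent([(r["gene_id"], r["label"]) for r in rows])
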