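"""Best-hit tables, collinear block chaining, and paralog classification.

Collinearity is detected in gene-rank space: anchors (homologous gene
pairs) are chained into maximal monotone runs — ascending on both
chromosomes (``same`` orientation) or ascending on one and descending on
the other (``inverted``) — with bounded rank gaps, reproducing the
diagonal structure of a homolog dotplot.  Paralog pairs are classified
as hexaploidy-derived (ECH: in a collinear block with Ks inside the
fitted ECH peak window), tandem (same chromosome, small rank gap), or
other; the two labels are not mutually exclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .core_io import GenomeAnnotation
from .ks_evolution import KsPeak

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hit:
    subject: str
    bitscore: float
    evalue: float
    identity: float


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    score: float = 0.0


@dataclass
class CollinearBlock:
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class ParalogClass:
    pair: AnchorPair
    label: str  # "ech" | "tandem" | "other"


def build_hit_table(
    rows, e_ceiling: float = 1e-5, max_hits: int = 5
) -> dict[str, list[Hit]]:
    """Filter outfmt6-like rows into a per-query best-hit table.

    Self-hits are removed, hits with E-value >= ``e_ceiling`` dropped
    (strict), and at most ``max_hits`` kept per query by descending
    bitscore.  Rows are sequences/tuples in BLAST outfmt6 column order
    (qseqid sseqid pident ... evalue bitscore).
    """
    table: dict[str, list[Hit]] = {}
    for i, row in enumerate(rows, 1):
        row = list(row)
        query, subject = str(row[0]), str(row[1])
        try:
            identity = float(row[2])
            evalue = float(row[10])
            bitscore = float(row[11])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"row {i}: non-numeric or missing score field") from exc
        if query == subject:
            continue
        if evalue >= e_ceiling:
            continue
        table.setdefault(query, []).append(Hit(subject, bitscore, evalue, identity))
    for query, hits in table.items():
        hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject))
        del hits[max_hits:]
    return {q: h for q, h in table.items() if h}


def _rank_maps(ann_a: GenomeAnnotation, ann_b: GenomeAnnotation):
    ga = {g.gene_id: g for g in ann_a.genes}
    gb = {g.gene_id: g for g in ann_b.genes}
    return ga, gb


def chain_collinear_blocks(
    anchors: list[AnchorPair],
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    min_block_size: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors into maximal monotone collinear blocks.

    Within each chromosome pair, the longest chain (strictly monotone in
    rank on both genomes, consecutive rank gaps <= ``max_rank_gap`` on
    both axes, either orientation) is extracted greedily and its anchors
    removed, until no chain of ``min_block_size`` anchors remains.
    Blocks therefore never share anchors.
    """
    ga, gb = _rank_maps(ann_a, ann_b)
    for a in anchors:
        if a.gene_a not in ga:
            raise KeyError(f"anchor references unknown gene {a.gene_a}")
        if a.gene_b not in gb:
            raise KeyError(f"anchor references unknown gene {a.gene_b}")

    by_chrom_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        key = (ga[a.gene_a].chrom, gb[a.gene_b].chrom)
        by_chrom_pair.setdefault(key, []).append(a)

    blocks: list[CollinearBlock] = []
    for (ca, cb), group in sorted(by_chrom_pair.items()):
        pool = sorted(group, key=lambda a: (ga[a.gene_a].rank, gb[a.gene_b].rank))
        while True:
            chain, orient = _best_chain(pool, ga, gb, max_rank_gap)
            if len(chain) < min_block_size:
                break
            blocks.append(CollinearBlock(chain, ca, cb, orient))
            used = set(id(a) for a in chain)
            pool = [a for a in pool if id(a) not in used]
    return blocks


def _best_chain(pool, ga, gb, max_gap):
    """Longest gap-bounded monotone chain over ``pool`` (already sorted by
    A-rank), tried in both orientations; ties favour ``same``."""
    best: list[AnchorPair] = []
    best_orient = "same"
    for orient in ("same", "inverted"):
        chain = _longest_chain(pool, ga, gb, max_gap, orient)
        if len(chain) > len(best):
            best, best_orient = chain, orient
    return best, best_orient


def _longest_chain(pool, ga, gb, max_gap, orient):
    """O(n^2) DP; among equally long chains the lexicographically smallest
    (by index in the rank-sorted pool) is returned, making the greedy
    block extraction canonical."""
    n = len(pool)
    if n == 0:
        return []
    ra = [ga[a.gene_a].rank for a in pool]
    rb = [gb[a.gene_b].rank for a in pool]

    def step_ok(i, j):
        da = ra[j] - ra[i]
        db = rb[j] - rb[i]
        if not (0 < da <= max_gap):
            return False
        return (0 < db <= max_gap) if orient == "same" else (0 < -db <= max_gap)

    # longest chain starting at each index, computed right to left
    length = [1] * n
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            if step_ok(i, j) and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
    best = max(length)
    cur = min(i for i in range(n) if length[i] == best)
    chain = [cur]
    need = best - 1
    while need:
        cur = min(
            j for j in range(cur + 1, n) if step_ok(chain[-1], j) and length[j] == need
        )
        chain.append(cur)
        need -= 1
    return [pool[i] for i in chain]


def classify_paralogs(
    pairs: list[AnchorPair],
    blocks: list[CollinearBlock],
    ks_map: dict[tuple[str, str], float],
    ech_peak: KsPeak,
    annotation: GenomeAnnotation,
    tandem_max_rank_gap: int = 5,
) -> list[ParalogClass]:
    """Label paralog pairs as ech / tandem / other.

    ``ech``: the pair sits in a collinear block and its Ks lies within
    mu ± 2 sigma of the fitted hexaploidy peak.  ``tandem``: both genes
    on one chromosome within ``tandem_max_rank_gap`` ranks.  A pair can
    carry both labels (the classes genuinely overlap in genome surveys);
    a warning is emitted when it does.  Pairs matching neither, or with
    missing Ks, are ``other``.
    """
    in_block = set()
    for b in blocks:
        for a in b.anchors:
            in_block.add(frozenset((a.gene_a, a.gene_b)))
    genes = annotation.genes_by_id()
    lo, hi = ech_peak.mu - 2 * ech_peak.sigma, ech_peak.mu + 2 * ech_peak.sigma
    out: list[ParalogClass] = []
    for p in pairs:
        labels = []
        ks = ks_map.get((p.gene_a, p.gene_b), ks_map.get((p.gene_b, p.gene_a)))
        if ks is None:
            logger.info("pair (%s, %s): no Ks value, classed other", p.gene_a, p.gene_b)
        elif frozenset((p.gene_a, p.gene_b)) in in_block and lo <= ks <= hi:
            labels.append("ech")
        a, b = genes.get(p.gene_a), genes.get(p.gene_b)
        if (
            a is not None
            and b is not None
            and a.chrom == b.chrom
            and abs(a.rank - b.rank) <= tandem_max_rank_gap
        ):
            labels.append("tandem")
        if len(labels) == 2:
            warnings.warn(
                f"pair ({p.gene_a}, {p.gene_b}) is both ech and tandem", stacklevel=2
            )
        if not labels:
            labels = ["other"]
        out.extend(ParalogClass(p, lab) for lab in labels)
    return out


def count_retained_duplicates(
    blocks: list[CollinearBlock], annotation: GenomeAnnotation
) -> tuple[int, float]:
    """Distinct genes in intra-genome collinear blocks, and their fraction.

    The fraction is over all annotated genes, the convention used for
    "duplicated genes" percentages in genome reports.
    """
    total = len(annotation.genes)
    if total == 0:
        raise ValueError("annotation has no genes")
    genes: set[str] = set()
    for b in blocks:
        for a in b.anchors:
            genes.add(a.gene_a)
            genes.add(a.gene_b)
    return len(genes), len(genes) / total
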