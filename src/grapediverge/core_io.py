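"""Shared coordinate model and readers/writers for on-disk formats.

All internal coordinates are 1-based inclusive (the GFF3 convention);
0-based half-open inputs (PAF) are converted at the boundary.  The domain
containers here — :class:`GeneModel`, :class:`GenomeAnnotation`,
:class:`Interval`, :class:`GenotypeTable` — are the substrate for every
downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel dosage for missing genotypes


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its along-chromosome rank.

    ``rank`` is the 0-based index of the gene among all genes of its
    chromosome sorted by start; collinearity chaining works in this rank
    space.
    """

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"
    rank: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus ranked gene models."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond {g.chrom} "
                    f"length {lengths[g.chrom]}"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval {self}: start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GenotypeTable:
    """Biallelic diploid genotypes as per-sample ALT dosages.

    ``sites`` holds ``(chrom, pos, ref, alt, dosages)`` with dosage in
    {0, 1, 2, MISSING}.  Positions are strictly increasing within a
    chromosome.
    """

    samples: list[str]
    sites: list[tuple[str, int, str, str, list[int]]]
    n_skipped: int = 0  # multiallelic / non-SNP records dropped on read

    def __post_init__(self):
        n = len(self.samples)
        last: dict[str, int] = {}
        for chrom, pos, _ref, _alt, dos in self.sites:
            if len(dos) != n:
                raise ValueError(f"site {chrom}:{pos}: {len(dos)} dosages, {n} samples")
            if chrom in last and pos <= last[chrom]:
                raise ValueError(f"positions not increasing on {chrom} at {pos}")
            last[chrom] = pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def restrict(self, region: Interval) -> "GenotypeTable":
        """Subset sites to those inside ``region`` (inclusive)."""
        kept = [
            s
            for s in self.sites
            if s[0] == region.chrom and region.start <= s[1] <= region.end
        ]
        return GenotypeTable(list(self.samples), kept)

    def subset_samples(self, names: list[str]) -> "GenotypeTable":
        idx = [self.samples.index(n) for n in names]
        sites = [
            (c, p, r, a, [dos[i] for i in idx]) for c, p, r, a, dos in self.sites
        ]
        return GenotypeTable(list(names), sites)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA records in file order; uppercase, U mapped to T.

    Raises ``ValueError`` naming the id on duplicates.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rec.id, seq, rec.description))
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read gene features from GFF3 into a ranked :class:`GenomeAnnotation`.

    Chromosome lengths come from ``##sequence-region`` pragmas unless a
    ``chrom_lengths`` table is supplied.  Genes are sorted by
    (chrom, start) and ranks assigned per chromosome.
    """
    lengths: dict[str, int] = dict(chrom_lengths or {})
    raw: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths.setdefault(parts[1], int(parts[3]))
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = cols[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr:
                raise ValueError(f"gene at {chrom}:{start} lacks an ID attribute")
            s, e = int(start), int(end)
            if e < s:
                raise ValueError(f"gene {attr['ID']}: end {e} < start {s}")
            raw.append(GeneModel(attr["ID"], chrom, s, e, strand, rank=0))
    for g in raw:
        lengths.setdefault(g.chrom, max(x.end for x in raw if x.chrom == g.chrom))
    raw.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    ranked: list[GeneModel] = []
    counter: dict[str, int] = {}
    for g in raw:
        r = counter.get(g.chrom, 0)
        counter[g.chrom] = r + 1
        ranked.append(GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, r))
    chroms = sorted(lengths.items())
    return GenomeAnnotation(chroms, ranked)


def write_gff3(ann: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in ann.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\tgrapediverge\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path, tetraploid_mode: str = "collapse"
) -> GenotypeTable:
    """Read a VCF v4.x into a :class:`GenotypeTable`.

    Multiallelic and non-SNP records are skipped (count kept on the
    table).  ``./.`` becomes missing.  Genotypes with ploidy > 2 (the
    tetraploid accessions of a mixed panel) are handled per
    ``tetraploid_mode``:

    ``collapse``
        any ALT allele present -> 1, all-ALT -> 2, all-REF -> 0.
    ``exclude``
        such calls become missing.
    """
    if tetraploid_mode not in ("collapse", "exclude"):
        raise ValueError(f"unknown tetraploid_mode {tetraploid_mode!r}")
    samples: list[str] = []
    sites: list[tuple[str, int, str, str, list[int]]] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            cols = line.split("\t")
            chrom, pos, _id, ref, alt = cols[0], int(cols[1]), cols[2], cols[3], cols[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                n_skipped += 1
                continue
            fmt = cols[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise ValueError(f"line {lineno}: no GT field")
            dosages: list[int] = []
            for cell in cols[9:]:
                gt = cell.split(":")[gt_idx]
                alleles = gt.replace("|", "/").split("/")
                if any(a == "." for a in alleles):
                    dosages.append(MISSING)
                    continue
                try:
                    calls = [int(a) for a in alleles]
                except ValueError:
                    raise ValueError(f"line {lineno}: malformed GT {gt!r}")
                if any(c not in (0, 1) for c in calls):
                    raise ValueError(f"line {lineno}: allele index out of range in {gt!r}")
                if len(calls) == 2:
                    dosages.append(sum(calls))
                elif tetraploid_mode == "exclude":
                    dosages.append(MISSING)
                else:
                    n_alt = sum(calls)
                    if n_alt == 0:
                        dosages.append(0)
                    elif n_alt == len(calls):
                        dosages.append(2)
                    else:
                        dosages.append(1)
            sites.append((chrom, pos, ref, alt, dosages))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    table = GenotypeTable(samples, sites)
    table.n_skipped = n_skipped
    return table


# ---------------------------------------------------------------------------
# Alignment interval tables


def read_alignment_intervals(
    path, dialect: str = "paf"
) -> list[tuple[Interval, Interval, float]]:
    """Read pairwise alignments as (query, target, identity) interval pairs.

    ``paf`` input is 0-based half-open and converted to the internal
    1-based inclusive convention; ``bed_tsv`` is a 6/7-column 1-based TSV
    ``qchrom qstart qend tchrom tstart tend [identity]``.
    """
    if dialect not in ("paf", "bed_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[tuple[Interval, Interval, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "paf":
                qname, _qlen, qs, qe = cols[0], cols[1], int(cols[2]), int(cols[3])
                tname, _tlen, ts, te = cols[5], cols[6], int(cols[7]), int(cols[8])
                nmatch, alen = int(cols[9]), int(cols[10])
                if min(qs, qe, ts, te) < 0:
                    raise ValueError(f"negative coordinate in PAF: {line[:60]}")
                ident = nmatch / alen if alen else 0.0
                out.append(
                    (
                        Interval(qname, qs + 1, qe),
                        Interval(tname, ts + 1, te),
                        ident,
                    )
                )
            else:
                qname, qs, qe, tname, ts, te = cols[:6]
                qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
                if min(qs, qe, ts, te) < 0:
                    raise ValueError(f"negative coordinate: {line[:60]}")
                ident = float(cols[6]) if len(cols) > 6 else 1.0
                out.append((Interval(qname, qs, qe), Interval(tname, ts, te), ident))
    return out


def write_alignment_paf(
    pairs: list[tuple[Interval, Interval, float]], path,
    q_lengths: dict[str, int] | None = None, t_lengths: dict[str, int] | None = None,
) -> None:
    """Write (query, target, identity) pairs as minimal PAF (involution of read)."""
    q_lengths = q_lengths or {}
    t_lengths = t_lengths or {}
    with open(path, "w") as fh:
        for q, t, ident in pairs:
            alen = max(len(q), len(t))
            nmatch = int(round(ident * alen))
            fh.write(
                f"{q.chrom}\t{q_lengths.get(q.chrom, q.end)}\t{q.start - 1}\t{q.end}\t+\t"
                f"{t.chrom}\t{t_lengths.get(t.chrom, t.end)}\t{t.start - 1}\t{t.end}\t"
                f"{nmatch}\t{alen}\t60\n"
            )


def write_bed(intervals: list[Interval], path) -> None:
    """Write intervals as 3-column BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.append(Interval(chrom, int(s) + 1, int(e)))
    return out


def merge_intervals(intervals: list[Interval], join_adjacent: bool = True) -> list[Interval]:
    """Merge overlapping (and, by default, book-ended) intervals per chromosome."""
    out: list[Interval] = []
    slack = 1 if join_adjacent else 0
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + slack:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out
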