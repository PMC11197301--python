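"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study conditions of a three-grape
comparative/population analysis:

* codon-aligned gene pairs diverged to target NG86 Ks/Ka levels
  (ortholog-like Ks ~ 0.026, hexaploidy-paralog-like Ks ~ 1.25);
* genome pairs sharing collinear gene order with implanted inversions,
  retained whole-genome-duplication (WGD) paralogs, and query-specific
  segments invisible to the reference (the PAV substrate);
* three-group diploid populations (female/male/hermaphrodite) with a
  localized sex-linked sweep — reduced diversity in one group and
  elevated between-group differentiation inside one interval;
* random gene-interaction networks (Erdos-Renyi or scale-free).

Codon evolution uses per-position category substitution over codon
families whose third position is fully synonymous and first/second
positions fully nonsynonymous, so the generative site definitions match
the NG86 estimator under test.  Substitution events per site are
Poisson; each event replaces the base uniformly among alternatives that
do not create a stop codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .core_io import GeneModel, GenomeAnnotation, GenotypeTable, Interval
from .ks_evolution import CODON_TABLE, STOP_CODONS

# codon families with a 4-fold synonymous third position and strictly
# nonsynonymous first/second positions (no first-position degeneracy)
_CLEAN_FAMILIES = ("GC", "GG", "GT", "CC", "AC", "TC")
_BASES = "ACGT"


@dataclass
class TruthTable:
    """Ground-truth records of every implanted feature."""

    codon_pairs: list[dict] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    inversions: list[dict] = field(default_factory=list)
    specific_segments: list[Interval] = field(default_factory=list)
    sweep_interval: Interval | None = None
    sex_labels: dict[str, str] = field(default_factory=dict)
    cluster_labels: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Codon pair sets


def _random_clean_sequence(rng: np.random.Generator, n_codons: int) -> str:
    fams = rng.integers(0, len(_CLEAN_FAMILIES), size=n_codons)
    thirds = rng.integers(0, 4, size=n_codons)
    return "".join(
        _CLEAN_FAMILIES[f] + _BASES[t] for f, t in zip(fams, thirds)
    )


def _mutate_position(rng: np.random.Generator, codon: str, pos: int) -> str:
    """One substitution at ``pos``, avoiding stop codons."""
    choices = [
        b
        for b in _BASES
        if b != codon[pos]
        and (codon[:pos] + b + codon[pos + 1 :]) not in STOP_CODONS
    ]
    b = choices[rng.integers(0, len(choices))]
    return codon[:pos] + b + codon[pos + 1 :]


def _diverge(
    rng: np.random.Generator, seq: str, d_syn: float, d_nonsyn: float
) -> tuple[str, int, int]:
    """Evolve one sequence copy: Poisson(d) substitution events per site,
    synonymous (third) and nonsynonymous (first+second) categories
    treated separately.  Returns (sequence, n_syn_events, n_nonsyn_events).
    """
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    n = len(codons)
    events = np.zeros((n, 3), dtype=np.int64)
    if d_nonsyn > 0:
        events[:, 0] = rng.poisson(d_nonsyn, size=n)
        events[:, 1] = rng.poisson(d_nonsyn, size=n)
    if d_syn > 0:
        events[:, 2] = rng.poisson(d_syn, size=n)
    n_s = n_n = 0
    for ci in np.nonzero(events.any(axis=1))[0]:
        codon = codons[ci]
        for pos in range(3):
            for _ in range(events[ci, pos]):
                codon = _mutate_position(rng, codon, pos)
                if pos == 2:
                    n_s += 1
                else:
                    n_n += 1
        codons[ci] = codon
    return "".join(codons), n_s, n_n


def simulate_codon_pair_set(
    n_pairs: int,
    n_codons: int,
    target_ks: float,
    target_ka: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Codon-aligned pairs whose expected NG86 Ks/Ka match the targets.

    Each pair derives from a common ancestor; total divergence
    ``target_ks`` (``target_ka``) is split evenly between the two
    branches.  Within the clean codon families used here each codon has
    exactly one synonymous site (the third position), so the
    Jukes-Cantor-corrected difference proportion is an unbiased match to
    the Poisson event rate.
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("divergence targets must be >= 0")
    if n_codons < 50:
        raise ValueError("need >= 50 codons per pair")
    for t in (target_ks, target_ka):
        if 0.75 * (1 - math.exp(-4 * t / 3)) >= 0.75:
            raise ValueError(f"target {t} implies a saturated difference proportion")
    rng = np.random.default_rng(seed)
    # per-position nonsynonymous rate: Ka counts 2 sites per codon
    pairs: list[tuple[str, str]] = []
    truth = TruthTable()
    for i in range(n_pairs):
        anc = _random_clean_sequence(rng, n_codons)
        a, sa, na = _diverge(rng, anc, target_ks / 2, target_ka / 2)
        b, sb, nb = _diverge(rng, anc, target_ks / 2, target_ka / 2)
        pairs.append((a, b))
        truth.codon_pairs.append(
            {"pair": i, "syn_events": sa + sb, "nonsyn_events": na + nb}
        )
    return pairs, truth


# ---------------------------------------------------------------------------
# Genome pairs


@dataclass
class GenomePairSimSpec:
    n_genes_per_chromosome: int = 300
    n_chromosomes: int = 2
    gene_length: int = 450  # bp, multiple of 3
    intergenic_gap: int = 500
    ortholog_target_ks: float = 0.026
    wgd_target_ks: float = 1.25
    wgd_retention: float = 0.2  # fraction of final genes in a retained pair
    n_inversions: int = 1
    specific_segments: list[tuple[int, int]] = field(
        default_factory=lambda: [(5000, 3)]
    )  # (length bp, count), implanted only in the query
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.wgd_retention < 1:
            raise ValueError("wgd_retention must be in [0, 1)")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")
        if min(self.ortholog_target_ks, self.wgd_target_ks) < 0:
            raise ValueError("Ks targets must be >= 0")


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation
    chromosome_seqs: dict[str, str]
    gene_seqs: dict[str, str]


def _assemble_chromosome(gene_seqs: list[str], gap: int, rng) -> tuple[str, list[int]]:
    """Concatenate genes with random intergenic spacers; returns sequence
    and 1-based gene start positions."""
    parts, starts = [], []
    pos = 0
    for gs in gene_seqs:
        spacer = "".join(_BASES[i] for i in rng.integers(0, 4, size=gap))
        parts.append(spacer)
        pos += gap
        starts.append(pos + 1)
        parts.append(gs)
        pos += len(gs)
    parts.append("".join(_BASES[i] for i in rng.integers(0, 4, size=gap)))
    return "".join(parts), starts


def simulate_genome_pair(
    spec: GenomePairSimSpec,
) -> tuple[SimulatedGenome, SimulatedGenome, list[tuple[Interval, Interval, float]], TruthTable]:
    """Reference and query genomes with known collinearity, WGD paralogs,
    inversions and query-specific segments.

    The emitted alignment table covers all shared query sequence and has
    no matches inside implanted segments.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthTable()
    n = spec.n_genes_per_chromosome
    n_codons = spec.gene_length // 3
    rho = spec.wgd_retention
    k_retained = int(round(rho * n / (2 - rho))) if rho > 0 else 0

    ref_genes: dict[str, str] = {}
    qry_genes: dict[str, str] = {}
    ref_chroms: dict[str, list[tuple[str, str]]] = {}  # chrom -> [(gene_id, seq)]
    qry_chroms: dict[str, list[tuple[str, str, str]]] = {}  # + strand

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        ids = [f"G{ci + 1:02d}_{j:04d}" for j in range(n)]
        anc = {g: _random_clean_sequence(rng, n_codons) for g in ids}
        ref_seq_of = {}
        qry_seq_of = {}
        for g in ids:
            ref_seq_of[g], _, _ = _diverge(rng, anc[g], spec.ortholog_target_ks / 2, 0.0)
            qry_seq_of[g], _, _ = _diverge(rng, anc[g], spec.ortholog_target_ks / 2, 0.0)
            truth.ortholog_pairs.append((f"R_{g}", f"Q_{g}"))
        ref_chroms[chrom] = [(f"R_{g}", ref_seq_of[g]) for g in ids]
        order = list(ids)
        strands = {g: "+" for g in ids}
        # implanted inversions: reverse a run of genes on the query
        if spec.n_inversions > 0 and ci < spec.n_inversions:
            run = max(8, n // 10)
            start_idx = int(rng.integers(n // 4, n // 2))
            seg = order[start_idx : start_idx + run]
            order[start_idx : start_idx + run] = seg[::-1]
            for g in seg:
                strands[g] = "-"
            truth.inversions.append(
                {"chrom": chrom, "genes": [f"Q_{g}" for g in seg]}
            )
        qry_chroms[chrom] = [(f"Q_{g}", qry_seq_of[g], strands[g]) for g in order]

        # retained WGD paralogs on a homeolog chromosome in both genomes
        if k_retained > 0:
            hchrom = f"chr{ci + 1}h"
            stride = max(1, n // k_retained)
            picked = ids[::stride][:k_retained]
            ref_h, qry_h = [], []
            for g in picked:
                para, _, _ = _diverge(rng, ref_seq_of[g], spec.wgd_target_ks, 0.0)
                ref_h.append((f"R_{g}p", para))
                para_q, _, _ = _diverge(rng, qry_seq_of[g], spec.wgd_target_ks, 0.0)
                qry_h.append((f"Q_{g}p", para_q, "+"))
                truth.paralog_pairs.append((f"R_{g}", f"R_{g}p"))
            ref_chroms[hchrom] = ref_h
            qry_chroms[hchrom] = qry_h

    ref = _build_genome(ref_chroms, spec, rng, with_strand=False)
    qry = _build_genome(qry_chroms, spec, rng, with_strand=True)
    ref_genes.update(ref.gene_seqs)
    qry_genes.update(qry.gene_seqs)

    # implant query-specific segments and derive the alignment table
    qry, segments = _implant_segments(qry, spec, rng)
    truth.specific_segments = segments
    alignment = _shared_alignment_table(qry, segments, spec)
    return ref, qry, alignment, truth


def _build_genome(chrom_tuples, spec, rng, with_strand: bool) -> SimulatedGenome:
    chroms, genes, seqs, gene_seqs = [], [], {}, {}
    for chrom in sorted(chrom_tuples):
        entries = chrom_tuples[chrom]
        ordered = [e[1] for e in entries]
        seq, starts = _assemble_chromosome(ordered, spec.intergenic_gap, rng)
        seqs[chrom] = seq
        chroms.append((chrom, len(seq)))
        for rank, (entry, start) in enumerate(zip(entries, starts)):
            gid, gseq = entry[0], entry[1]
            strand = entry[2] if with_strand else "+"
            genes.append(
                GeneModel(gid, chrom, start, start + len(gseq) - 1, strand, rank)
            )
            gene_seqs[gid] = gseq
    return SimulatedGenome(GenomeAnnotation(chroms, genes), seqs, gene_seqs)


def _implant_segments(genome: SimulatedGenome, spec, rng):
    """Insert random-DNA segments into intergenic space of the query's
    main chromosomes; gene coordinates shift accordingly."""
    segments: list[Interval] = []
    want = [(length, count) for length, count in spec.specific_segments]
    if not want:
        return genome, segments
    main_chroms = [c for c, _l in genome.annotation.chromosomes if not c.endswith("h")]
    new_seqs = dict(genome.chromosome_seqs)
    genes_by_chrom = {
        c: sorted(genome.annotation.genes_on(c), key=lambda g: g.start)
        for c, _ in genome.annotation.chromosomes
    }
    inserts: dict[str, list[tuple[int, int]]] = {c: [] for c in main_chroms}
    i = 0
    for length, count in want:
        for _ in range(count):
            chrom = main_chroms[i % len(main_chroms)]
            i += 1
            if length >= len(new_seqs[chrom]):
                raise ValueError(
                    f"segment of {length} bp exceeds chromosome {chrom}"
                )
            # insertion point: an intergenic boundary between two genes
            gs = genes_by_chrom[chrom]
            gi = int(rng.integers(1, len(gs)))
            point = gs[gi].start - spec.intergenic_gap // 2  # 1-based, insert before
            inserts[chrom].append((point, length))
    new_genes = []
    for chrom, _l in genome.annotation.chromosomes:
        ins = sorted(inserts.get(chrom, []))
        seq = new_seqs[chrom]
        out_parts, cursor, offset = [], 0, 0
        offsets = []  # (original point, cumulative shift)
        for point, length in ins:
            out_parts.append(seq[cursor : point - 1])
            filler = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
            out_parts.append(filler)
            seg_start = point + offset
            segments.append(Interval(chrom, seg_start, seg_start + length - 1))
            offset += length
            offsets.append((point, offset))
            cursor = point - 1
        out_parts.append(seq[cursor:])
        new_seqs[chrom] = "".join(out_parts)
        for g in genes_by_chrom[chrom]:
            shift = 0
            for point, cum in offsets:
                if g.start >= point:
                    shift = cum
            new_genes.append(
                GeneModel(g.gene_id, chrom, g.start + shift, g.end + shift, g.strand, g.rank)
            )
    chroms = [(c, len(new_seqs[c])) for c, _ in genome.annotation.chromosomes]
    ann = GenomeAnnotation(chroms, sorted(new_genes, key=lambda g: (g.chrom, g.start)))
    return SimulatedGenome(ann, new_seqs, genome.gene_seqs), sorted(
        segments, key=lambda s: (s.chrom, s.start)
    )


def _shared_alignment_table(qry: SimulatedGenome, segments, spec):
    """Alignments covering all query sequence except implanted segments."""
    by_chrom: dict[str, list[Interval]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    ident = max(0.0, 1.0 - spec.ortholog_target_ks / 3)
    table = []
    for chrom, length in qry.annotation.chromosomes:
        gaps = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        cursor = 1
        removed = 0
        tchrom = chrom  # reference naming mirrors the query here
        for g in gaps:
            if g.start > cursor:
                q = Interval(chrom, cursor, g.start - 1)
                t = Interval(tchrom, cursor - removed, g.start - 1 - removed)
                table.append((q, t, ident))
            removed += len(g)
            cursor = g.end + 1
        if cursor <= length:
            q = Interval(chrom, cursor, length)
            t = Interval(tchrom, cursor - removed, length - removed)
            table.append((q, t, ident))
    return table


# ---------------------------------------------------------------------------
# Populations


@dataclass
class PopulationSimSpec:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"female": 10, "male": 5, "hermaphrodite": 9}
    )
    n_sites: int = 40_000
    chrom_length: int = 2_000_000
    chrom: str = "chr2"
    background_pi: float = 0.005  # expected per-bp diversity
    sweep_interval: Interval | None = None  # default: central 100 kb
    sweep_group: str = "male"
    sweep_pi_reduction: float = 0.1  # multiplicative, <= 1
    sweep_fst_boost: float = 0.6  # allele-frequency displacement
    background_fst: float = 0.3  # differentiation of two sex-independent clusters
    seed: int = 0

    def __post_init__(self):
        if self.sweep_interval is None:
            mid = self.chrom_length // 2
            self.sweep_interval = Interval(self.chrom, mid - 50_000 + 1, mid + 50_000)
        if not (0 < self.sweep_pi_reduction <= 1):
            raise ValueError("sweep_pi_reduction must be in (0, 1]")
        if self.sweep_interval.chrom != self.chrom or self.sweep_interval.end > self.chrom_length:
            raise ValueError("sweep interval outside the chromosome")
        if self.sweep_group not in self.n_per_group:
            raise ValueError(f"unknown sweep group {self.sweep_group!r}")


def simulate_population(
    spec: PopulationSimSpec,
) -> tuple[GenotypeTable, dict[str, str], TruthTable]:
    """Three-group diploid panel with a localized sweep in one group.

    Outside the sweep interval all sex groups share site frequencies
    drawn from a symmetric Beta(a, a); ``a`` is solved so that the
    expected per-bp diversity of the pooled panel equals
    ``background_pi`` given the SNP density and the heterozygosity lost
    to background-cluster drift (a factor 1 - F/2).  Inside the sweep
    group's frequency is displaced by ``sweep_fst_boost`` toward the far
    allele-frequency boundary and then pulled toward that boundary by
    ``sweep_pi_reduction``, reducing its diversity and opening a
    between-group frequency gap.

    Independently of sex, samples alternate between two background
    clusters whose frequencies drift apart genome-wide under a
    Balding-Nichols model with F = ``background_fst``.  This mimics
    panels whose genome-wide phylogeny groups samples by ancestry rather
    than sex, while a tree restricted to the swept interval groups the
    sweep-group samples together.
    """
    rng = np.random.default_rng(spec.seed)
    pos = np.sort(
        rng.choice(np.arange(1, spec.chrom_length + 1), size=spec.n_sites, replace=False)
    )
    in_sweep = (pos >= spec.sweep_interval.start) & (pos <= spec.sweep_interval.end)
    if in_sweep.sum() < 50:
        raise ValueError(
            f"only {int(in_sweep.sum())} sites fall in the sweep interval; need >= 50"
        )
    # Beta(a,a) has E[2p(1-p)] = a/(2a+1); cluster drift multiplies the
    # pooled heterozygosity by (1 - F/2), so solve a for the target pi
    density = spec.n_sites / spec.chrom_length
    h_base = spec.background_pi / density / (1 - spec.background_fst / 2)
    if h_base >= 0.5:
        raise ValueError(
            f"background_pi {spec.background_pi} unreachable at "
            f"{spec.n_sites} sites on {spec.chrom_length} bp"
        )
    a_shape = h_base / (1 - 2 * h_base)
    p_base = rng.beta(a_shape, a_shape, size=spec.n_sites)
    # sweep-group frequency inside the interval
    direction = np.where(p_base < 0.5, 1.0, -1.0)
    far = np.where(p_base < 0.5, 1.0, 0.0)
    p_mid = np.clip(p_base + spec.sweep_fst_boost * direction, 0.0, 1.0)
    p_swept = far + (p_mid - far) * spec.sweep_pi_reduction

    samples, labels, clusters = [], {}, {}
    for group in sorted(spec.n_per_group):
        for i in range(spec.n_per_group[group]):
            name = f"{group[0].upper()}{i + 1:02d}"
            samples.append(name)
            labels[name] = group
            clusters[name] = "cluster1" if i % 2 == 0 else "cluster2"

    # Balding-Nichols drift of the two background clusters around p_base
    f = spec.background_fst
    if f > 0:
        scale = (1 - f) / f
        a = np.maximum(p_base * scale, 1e-3)
        b = np.maximum((1 - p_base) * scale, 1e-3)
        p_cluster = {
            "cluster1": rng.beta(a, b),
            "cluster2": rng.beta(a, b),
        }
    else:
        p_cluster = {"cluster1": p_base, "cluster2": p_base}

    sites = []
    dosage_cols = {}
    for s in samples:
        p = p_cluster[clusters[s]].copy()
        if labels[s] == spec.sweep_group:
            p[in_sweep] = p_swept[in_sweep]
        dosage_cols[s] = rng.binomial(2, p)
    for j in range(spec.n_sites):
        dosages = [int(dosage_cols[s][j]) for s in samples]
        sites.append((spec.chrom, int(pos[j]), "A", "G", dosages))
    truth = TruthTable(
        sweep_interval=spec.sweep_interval, sex_labels=labels, cluster_labels=clusters
    )
    return GenotypeTable(samples, sites), labels, truth


def write_vcf(gt: GenotypeTable, path, labels: dict[str, str] | None = None) -> None:
    """Write a GenotypeTable as a minimal diploid VCF v4.2 fixture."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({s[0] for s in gt.sites})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        for chrom, p, ref, alt, dos in gt.sites:
            cells = [gt_of.get(d, "./.") for d in dos]
            fh.write(
                f"{chrom}\t{p}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Networks


def simulate_network(
    n_nodes: int, mean_degree: float, model: str = "erdos_renyi", seed: int = 0
) -> nx.Graph:
    """Simple undirected random graph with the requested mean degree."""
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be < n_nodes")
    if model == "erdos_renyi":
        p = mean_degree / (n_nodes - 1)
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    elif model == "scale_free":
        m = max(1, int(round(mean_degree / 2)))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    return nx.relabel_nodes(g, {i: f"gene{i:04d}" for i in g.nodes})
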