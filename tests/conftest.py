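import pytest

from grapediverge.core_io import GeneModel, GenomeAnnotation, GenotypeTable, Interval
from grapediverge.synthetic_data import (
    GenomePairSimSpec,
    PopulationSimSpec,
    simulate_genome_pair,
    simulate_population,
)


@pytest.fixture(scope="session")
def genome_pair():
    """One simulated genome pair shared by homology/PAV tests."""
    return simulate_genome_pair(GenomePairSimSpec(seed=3))


@pytest.fixture(scope="session")
def population():
    """One simulated three-group panel with a sweep."""
    spec = PopulationSimSpec(seed=1)
    gt, labels, truth = simulate_population(spec)
    return spec, gt, labels, truth


def annotation_from_ranks(ranks_by_chrom):
    """Helper: build an annotation from {chrom: [gene ids in rank order]}."""
    genes, chroms = [], []
    for chrom, ids in ranks_by_chrom.items():
        for r, gid in enumerate(ids):
            start = 1000 * (r + 1)
            genes.append(GeneModel(gid, chrom, start, start + 500, "+", r))
        chroms.append((chrom, 1000 * (len(ids) + 1)))
    return GenomeAnnotation(chroms, genes)


def table(samples, rows, chrom="chr1"):
    """Helper: GenotypeTable from a list of (pos, dosages)."""
    sites = [(chrom, pos, "A", "G", list(d)) for pos, d in rows]
    return GenotypeTable(list(samples), sites)
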