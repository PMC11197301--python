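"""Hit filtering, collinear chaining vs a brute-force oracle, paralog classes."""

import numpy as np
import pytest

from grapediverge.homology import (
    AnchorPair,
    build_hit_table,
    chain_collinear_blocks,
    classify_paralogs,
    count_retained_duplicates,
)
from grapediverge.ks_evolution import KsPeak
from grapediverge.report import fraction_percent

from conftest import annotation_from_ranks


def row(q, s, evalue, bits, ident=90.0):
    return [q, s, ident, 100, 0, 0, 1, 100, 1, 100, evalue, bits]


class TestHitTable:
    def test_self_hits_removed(self):
        assert build_hit_table([row("qA", "qA", 1e-30, 200)]) == {}

    def test_e_ceiling_is_strict(self):
        assert build_hit_table([row("q", "s", 1e-5, 200)]) == {}
        kept = build_hit_table([row("q", "s", 0.9e-5, 200)])
        assert kept["q"][0].subject == "s"

    def test_truncation_keeps_best_bitscores(self):
        rows = [row("q", f"s{i}", 1e-30, 100 + i) for i in range(7)]
        hits = build_hit_table(rows)["q"]
        assert len(hits) == 5
        assert [h.subject for h in hits] == ["s6", "s5", "s4", "s3", "s2"]

    def test_non_numeric_score_raises_with_row_number(self):
        bad = row("q", "s", 1e-30, 200)
        bad[11] = "oops"
        with pytest.raises(ValueError, match="row 1"):
            build_hit_table([bad])


def brute_force_blocks(anchors, ann_a, ann_b, min_block_size, max_gap):
    """Independent oracle: exhaustive DFS over all monotone gap-bounded
    chains, greedily extracting the longest until none qualifies."""
    ga = ann_a.genes_by_id()
    gb = ann_b.genes_by_id()

    def all_chains(pool, orient):
        """Lexicographically smallest of the longest chains, found by
        exhaustive DFS over index sequences."""
        pool = sorted(pool, key=lambda a: (ga[a.gene_a].rank, gb[a.gene_b].rank))
        best = []

        def extend(chain):
            nonlocal best
            if len(chain) > len(best) or (
                len(chain) == len(best) and chain < best
            ):
                best = list(chain)
            start = chain[-1] + 1 if chain else 0
            for idx in range(start, len(pool)):
                if chain:
                    prev, cand = pool[chain[-1]], pool[idx]
                    da = ga[cand.gene_a].rank - ga[prev.gene_a].rank
                    db = gb[cand.gene_b].rank - gb[prev.gene_b].rank
                    if not (0 < da <= max_gap):
                        continue
                    if orient == "same" and not (0 < db <= max_gap):
                        continue
                    if orient == "inverted" and not (0 < -db <= max_gap):
                        continue
                chain.append(idx)
                extend(chain)
                chain.pop()

        extend([])
        return [pool[i] for i in best]

    by_pair = {}
    for a in anchors:
        by_pair.setdefault((ga[a.gene_a].chrom, gb[a.gene_b].chrom), []).append(a)
    blocks = []
    for _key, pool in sorted(by_pair.items()):
        while True:
            cands = [(all_chains(pool, o), o) for o in ("same", "inverted")]
            chain, orient = max(cands, key=lambda c: len(c[0]))
            if len(chain) < min_block_size:
                break
            blocks.append((chain, orient))
            used = {id(a) for a in chain}
            pool = [a for a in pool if id(a) not in used]
    return blocks


class TestChaining:
    def setup_method(self):
        ids_a = [f"a{i}" for i in range(30)]
        ids_b = [f"b{i}" for i in range(30)]
        self.ann_a = annotation_from_ranks({"cA": ids_a})
        self.ann_b = annotation_from_ranks({"cB": ids_b})

    def test_perfect_diagonal_single_block(self):
        anchors = [AnchorPair(f"a{i}", f"b{i}") for i in range(10)]
        (block,) = chain_collinear_blocks(anchors, self.ann_a, self.ann_b)
        assert block.orientation == "same"
        assert block.n_anchors == 10

    def test_reversed_diagonal_is_inverted(self):
        anchors = [AnchorPair(f"a{i}", f"b{9 - i}") for i in range(10)]
        (block,) = chain_collinear_blocks(anchors, self.ann_a, self.ann_b)
        assert block.orientation == "inverted"
        assert block.n_anchors == 10

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError, match="unknown gene"):
            chain_collinear_blocks(
                [AnchorPair("nope", "b1")], self.ann_a, self.ann_b
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        ann_a = annotation_from_ranks({"cA": ids_a})
        ann_b = annotation_from_ranks({"cB": ids_b})
        pts = rng.choice(n * n, size=20, replace=False)
        anchors = [AnchorPair(f"a{p // n}", f"b{p % n}") for p in sorted(pts)]
        got = chain_collinear_blocks(anchors, ann_a, ann_b, min_block_size=4, max_rank_gap=10)
        exp = brute_force_blocks(anchors, ann_a, ann_b, min_block_size=4, max_gap=10)
        assert len(got) == len(exp)
        assert sorted(b.n_anchors for b in got) == sorted(len(c) for c, _o in exp)

    def test_blocks_are_monotone_and_gap_bounded(self, genome_pair):
        ref, qry, _aln, truth = genome_pair
        anchors = [AnchorPair(a, b) for a, b in truth.ortholog_pairs]
        blocks = chain_collinear_blocks(anchors, ref.annotation, qry.annotation)
        ga = ref.annotation.genes_by_id()
        gb = qry.annotation.genes_by_id()
        assert blocks
        for block in blocks:
            ra = [ga[a.gene_a].rank for a in block.anchors]
            rb = [gb[a.gene_b].rank for a in block.anchors]
            assert ra == sorted(ra)
            assert all(0 < d <= 25 for d in np.diff(ra))
            db = np.diff(rb)
            if block.orientation == "same":
                assert all(0 < d <= 25 for d in db)
            else:
                assert all(0 < -d <= 25 for d in db)

    def test_implanted_inversions_recovered(self, genome_pair):
        ref, qry, _aln, truth = genome_pair
        anchors = [AnchorPair(a, b) for a, b in truth.ortholog_pairs]
        blocks = chain_collinear_blocks(anchors, ref.annotation, qry.annotation)
        inverted_genes = {
            g for b in blocks if b.orientation == "inverted" for a in b.anchors
            for g in (a.gene_b,)
        }
        for inv in truth.inversions:
            genes = set(inv["genes"])
            assert len(genes & inverted_genes) >= 0.8 * len(genes)


class TestParalogClassification:
    def make(self):
        ann = annotation_from_ranks({"c1": [f"g{i}" for i in range(20)]})
        peak = KsPeak(mu=1.25, sigma=0.135, weight=1.0)
        return ann, peak

    def test_blocked_pair_at_peak_is_ech(self):
        ann, peak = self.make()
        from grapediverge.homology import CollinearBlock

        pair = AnchorPair("g0", "g15")
        block = CollinearBlock([pair], "c1", "c1", "same")
        (cls,) = classify_paralogs([pair], [block], {("g0", "g15"): 1.25}, peak, ann)
        assert cls.label == "ech"

    def test_adjacent_genes_are_tandem(self):
        ann, peak = self.make()
        (cls,) = classify_paralogs(
            [AnchorPair("g10", "g11")], [], {("g10", "g11"): 0.02}, peak, ann
        )
        assert cls.label == "tandem"

    def test_unblocked_low_ks_pair_is_other(self):
        ann, peak = self.make()
        (cls,) = classify_paralogs(
            [AnchorPair("g0", "g15")], [], {("g0", "g15"): 0.025}, peak, ann
        )
        assert cls.label == "other"

    def test_overlapping_classes_reported_under_both_labels(self):
        ann, peak = self.make()
        from grapediverge.homology import CollinearBlock

        pair = AnchorPair("g10", "g11")
        block = CollinearBlock([pair], "c1", "c1", "same")
        with pytest.warns(UserWarning, match="both"):
            classes = classify_paralogs(
                [pair], [block], {("g10", "g11"): 1.25}, peak, ann
            )
        assert {c.label for c in classes} == {"ech", "tandem"}


class TestRetainedDuplicates:
    def test_no_blocks_is_zero(self):
        ann = annotation_from_ranks({"c1": ["g0", "g1"]})
        assert count_retained_duplicates([], ann) == (0, 0.0)

    def test_percent_formatting_matches_genome_survey_convention(self):
        assert fraction_percent(4494, 27635) == 16.26

    def test_recovery_of_simulated_retention(self, genome_pair):
        ref, _qry, _aln, truth = genome_pair
        anchors = [AnchorPair(a, b) for a, b in truth.paralog_pairs]
        blocks = chain_collinear_blocks(anchors, ref.annotation, ref.annotation)
        _n, frac = count_retained_duplicates(blocks, ref.annotation)
        assert frac * 100 == pytest.approx(20.0, abs=1.0)

    def test_empty_annotation_raises(self):
        from grapediverge.core_io import GenomeAnnotation

        with pytest.raises(ValueError):
            count_retained_duplicates([], GenomeAnnotation([], []))
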