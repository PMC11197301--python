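"""Diversity/FST against per-site oracles, LD pruning, sweep scan, NJ trees."""

import math

import numpy as np
import pytest

from grapediverge.core_io import Interval
from grapediverge.popgen import (
    WindowStats,
    compute_window_stats,
    is_monophyletic,
    ld_prune,
    nj_tree,
    overlap_regions,
    scan_sweeps,
    snp_distance_matrix,
    window_fst,
    window_pi,
)

from conftest import table


class TestLdPrune:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 30).tolist()
        gt = table([f"s{i}" for i in range(30)], [(100, col), (200, col), (300, rng.integers(0, 3, 30).tolist())])
        pruned = ld_prune(gt)
        assert [s[1] for s in pruned.sites][0] == 100
        assert 200 not in [s[1] for s in pruned.sites]

    def test_independent_sites_mostly_retained(self):
        rng = np.random.default_rng(1)
        n, m = 200, 100
        gt = table(
            [f"s{i}" for i in range(n)],
            [(100 * (j + 1), rng.binomial(2, 0.5, n).tolist()) for j in range(m)],
        )
        pruned = ld_prune(gt)
        assert pruned.n_sites >= 0.95 * m

    def test_monomorphic_site_always_retained(self):
        gt = table(["a", "b", "c"], [(1, [1, 1, 1]), (2, [0, 1, 2]), (3, [0, 1, 2])])
        pruned = ld_prune(gt)
        assert 1 in [s[1] for s in pruned.sites]


class TestPi:
    def test_monomorphic_window_is_zero(self):
        gt = table(["a", "b"], [(10, [0, 0]), (20, [2, 2])])
        assert window_pi(gt, [0, 1], [Interval("chr1", 1, 1000)]) == [0.0]

    def test_hand_formula_single_site(self):
        gt = table(["a", "b"], [(10, [0, 2])])
        (pi,) = window_pi(gt, [0, 1], [Interval("chr1", 1, 1000)])
        # 2*0.5*0.5 * 4/3 = 0.6667 per site, over 1 kb
        assert pi == pytest.approx(2 * 0.25 * 4 / 3 / 1000)

    def test_simulated_background_recovered(self, population):
        spec, gt, labels, _truth = population
        cols = [i for i, s in enumerate(gt.samples) if labels[s] == "female"]
        win = [
            Interval(spec.chrom, s, s + 4999)
            for s in range(1, spec.chrom_length - 4999 + 1, 5000)
        ]
        pis = [p for p in window_pi(gt, cols, win) if math.isfinite(p)]
        assert np.median(pis) == pytest.approx(spec.background_pi, rel=0.10)

    def test_empty_group_raises(self):
        gt = table(["a"], [(1, [0])])
        with pytest.raises(ValueError):
            window_pi(gt, [], [Interval("chr1", 1, 10)])


def brute_pi(dosages, length):
    """Oracle: per-site unbiased heterozygosity summed over sites / bp."""
    tot = 0.0
    for dos in dosages:
        obs = [d for d in dos if d >= 0]
        n = 2 * len(obs)
        if n < 2:
            continue
        p = sum(obs) / n
        tot += 2 * p * (1 - p) * n / (n - 1)
    return tot / length


def brute_fst(dosA, dosB):
    """Oracle: Hudson ratio-of-sums evaluated site by site from scratch."""
    num = den = 0.0
    for da, db in zip(dosA, dosB):
        oa = [d for d in da if d >= 0]
        ob = [d for d in db if d >= 0]
        na, nb = 2 * len(oa), 2 * len(ob)
        if na < 2 or nb < 2:
            continue
        p1, p2 = sum(oa) / na, sum(ob) / nb
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (na - 1) - p2 * (1 - p2) / (nb - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den else float("nan")


class TestFst:
    def test_fixed_difference_is_one(self):
        gt = table(["a1", "a2", "b1", "b2"], [(10, [2, 2, 0, 0])] )
        (f,) = window_fst(gt, [0, 1], [2, 3], [Interval("chr1", 1, 100)])
        assert f == pytest.approx(1.0)

    def test_hand_evaluated_hudson_value(self):
        # p1 = 0.8 of 10 alleles, p2 = 0.2 of 10 alleles
        gt = table(
            [f"x{i}" for i in range(10)],
            [(10, [2, 2, 2, 1, 1, 1, 1, 0, 0, 0])],
        )
        (f,) = window_fst(gt, [0, 1, 2, 3, 4], [5, 6, 7, 8, 9], [Interval("chr1", 1, 100)])
        assert f == pytest.approx((0.36 - 2 * 0.16 / 9) / 0.68, abs=1e-6)
        assert f == pytest.approx(0.47712, abs=1e-5)

    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.4, size=(50, 20))
        gt = table(
            [f"s{i}" for i in range(20)],
            [(10 * (j + 1), dos[j].tolist()) for j in range(50)],
        )
        (f,) = window_fst(gt, list(range(10)), list(range(10, 20)), [Interval("chr1", 1, 600)])
        assert abs(f) < 0.05

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 30)[:, None], size=(30, 12))
        gt = table(
            [f"s{i}" for i in range(12)],
            [(10 * (j + 1), dos[j].tolist()) for j in range(30)],
        )
        w = [Interval("chr1", 1, 400)]
        a = window_fst(gt, list(range(6)), list(range(6, 12)), w)
        b = window_fst(gt, list(range(6, 12)), list(range(6)), w)
        assert a[0] == pytest.approx(b[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_pi_and_fst_match_brute_force_on_random_toy_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(4, 6))
        n_sites = int(rng.integers(1, 11))
        dos = rng.integers(-1, 3, size=(n_sites, n_samples))
        # ensure at least some data
        dos[:, 0] = np.abs(dos[:, 0])
        gt = table(
            [f"s{i}" for i in range(n_samples)],
            [(10 * (j + 1), dos[j].tolist()) for j in range(n_sites)],
        )
        w = [Interval("chr1", 1, 200)]
        half = n_samples // 2
        ca, cb = list(range(half)), list(range(half, n_samples))
        (pi,) = window_pi(gt, ca, w)
        exp_pi = brute_pi([dos[j, ca].tolist() for j in range(n_sites)], 200)
        if math.isfinite(pi):
            assert pi == pytest.approx(exp_pi)
        (fst,) = window_fst(gt, ca, cb, w)
        exp_fst = brute_fst(
            [dos[j, ca].tolist() for j in range(n_sites)],
            [dos[j, cb].tolist() for j in range(n_sites)],
        )
        if math.isfinite(fst) and math.isfinite(exp_fst):
            assert fst == pytest.approx(exp_fst)
        else:
            assert math.isnan(fst) == math.isnan(exp_fst)


class TestSweepScan:
    def stats(self, values):
        return [
            WindowStats(Interval("c", 1 + 5000 * i, 5000 * (i + 1)), {}, f, r, 10)
            for i, (f, r) in enumerate(values)
        ]

    def test_degenerate_identical_windows_select_nothing(self):
        scan = scan_sweeps(self.stats([(0.1, 1.0)] * 30))
        assert scan.selected == []
        assert scan.regions == []

    def test_joint_outlier_required(self):
        rng = np.random.default_rng(0)
        vals = [(float(f), float(r)) for f, r in rng.uniform(0, 0.1, size=(100, 2))]
        vals[10] = (0.9, 0.05)  # FST outlier only
        vals[20] = (0.05, 0.9)  # ratio outlier only
        vals[30] = (0.9, 0.9)  # joint outlier
        scan = scan_sweeps(self.stats(vals))
        sel = {s.window.start for s in scan.selected}
        assert 1 + 5000 * 30 in sel
        assert 1 + 5000 * 10 not in sel
        assert 1 + 5000 * 20 not in sel

    def test_selected_fraction_bounded_without_ties(self):
        rng = np.random.default_rng(1)
        vals = [(float(f), float(r)) for f, r in rng.normal(size=(200, 2))]
        scan = scan_sweeps(self.stats(vals))
        assert len(scan.selected) <= math.ceil(0.05 * 200)

    def test_too_few_windows_raise(self):
        with pytest.raises(ValueError):
            scan_sweeps(self.stats([(0.1, 1.0)] * 10))

    def test_simulated_sweep_recovered_and_degraded_by_permutation(self, population):
        spec, gt, labels, truth = population
        win = [
            Interval(spec.chrom, s, s + 4999)
            for s in range(1, spec.chrom_length - 4999 + 1, 5000)
        ]
        stats = compute_window_stats(gt, labels, "female", "male", win)
        scan = scan_sweeps(stats)
        bp, _full = overlap_regions(scan.regions, truth.sweep_interval)
        assert bp > 0
        # Permuting labels strongly degrades the signal.  It is not fully
        # destroyed: permutations that concentrate the causal samples in
        # one analysis group keep genuine localized differentiation, just
        # as they would in a real panel of this size.
        rng = np.random.default_rng(0)
        names = list(labels)
        hits = 0
        for _ in range(20):
            perm = rng.permutation([labels[s] for s in names])
            plabels = dict(zip(names, perm))
            pstats = compute_window_stats(gt, plabels, "female", "male", win)
            pscan = scan_sweeps(pstats)
            pbp, _f = overlap_regions(pscan.regions, truth.sweep_interval)
            hits += pbp > 0
        assert hits <= 8


class TestOverlapRegions:
    def test_disjoint(self):
        assert overlap_regions([Interval("c", 1, 10)], Interval("c", 20, 30)) == (0, False)

    def test_sdr_containment_arithmetic(self):
        region = Interval("chr2", 5_000_001, 5_300_000)
        sdr = Interval("chr2", 5_055_465, 5_198_824)
        assert overlap_regions([region], sdr) == (143_360, True)

    def test_partial_overlap_exact_bp(self):
        assert overlap_regions([Interval("c", 1, 100)], Interval("c", 51, 150)) == (50, False)


class TestDistanceAndNj:
    def test_identical_and_opposite_samples(self):
        gt = table(["a", "b", "c"], [(10 * j, [0, 0, 2]) for j in range(1, 11)])
        dm, names = snp_distance_matrix(gt)
        assert dm[0, 1] == 0.0
        assert dm[0, 2] == 1.0

    def test_hand_grid(self):
        gt = table(["a", "b", "c"], [(10, [0, 1, 2]), (20, [2, 1, 0]), (30, [0, 0, 1])])
        dm, _names = snp_distance_matrix(gt)
        assert dm[0, 1] == pytest.approx((1 + 1 + 0) / 3 / 2)
        assert dm[0, 2] == pytest.approx((2 + 2 + 1) / 3 / 2)

    def test_pair_with_no_shared_sites_raises(self):
        gt = table(["a", "b", "c"], [(10, [0, -1, 0]), (20, [-1, 1, 1])])
        with pytest.raises(ValueError, match="a and b"):
            snp_distance_matrix(gt)

    def test_nj_recovers_additive_four_leaf_tree(self):
        # ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        names = ["A", "B", "C", "D"]
        dm = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = names.index(x), names.index(y)
            dm[i, j] = dm[j, i] = v
        tree = nj_tree(dm, names)
        assert is_monophyletic(tree, {"A", "B"})
        assert is_monophyletic(tree, {"C", "D"})
        # recover the cherry branch lengths
        newick = tree.to_newick()
        assert "A:1.000000" in newick and "B:2.000000" in newick

    def test_asymmetric_matrix_raises(self):
        dm = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(dm, ["a", "b", "c"])

    def test_sdr_restricted_tree_groups_by_sex_but_genome_wide_does_not(self, population):
        _spec, gt, labels, truth = population
        male = {s for s, g in labels.items() if g == "male"}
        dm, names = snp_distance_matrix(gt, restrict=truth.sweep_interval)
        assert is_monophyletic(nj_tree(dm, names), male)
        dmw, namesw = snp_distance_matrix(gt)
        assert not is_monophyletic(nj_tree(dmw, namesw), male)
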