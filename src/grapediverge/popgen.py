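"""Windowed diversity/differentiation scans, LD pruning, sweep calling,
and SNP-distance phylogenies.

The sweep scan follows the joint-outlier rule used in resequencing
panels: per 5-kb window, nucleotide diversity theta-pi per group, the
between-group pi ratio, and Hudson's FST are computed; windows in the
top 5% of BOTH the pi ratio and FST are selection candidates and are
merged into regions.  Sex-determination-region (SDR) candidacy is then a
question of overlap between merged regions and an a-priori interval.

Trees are neighbor-joining on allele-sharing distances; restricting the
sites to a candidate region before building the tree reproduces the
"region-restricted phylogeny" contrast (genome-wide trees need not group
samples by phenotype even when a region-restricted tree does).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, GenotypeTable, Interval, merge_intervals

GROUPS = ("female", "male", "hermaphrodite")


@dataclass
class WindowStats:
    window: Interval
    pi: dict[str, float]
    fst: float
    pi_ratio: float  # pi(reference group) / pi(candidate group); NaN if undefined
    n_snps: int


@dataclass
class SweepScanResult:
    comparison: str
    fst_threshold: float
    ratio_threshold: float
    selected: list[WindowStats]
    regions: list[Interval]


def _dosage_matrix(gt: GenotypeTable) -> np.ndarray:
    """(n_sites, n_samples) int matrix with MISSING = -1."""
    return np.array([s[4] for s in gt.sites], dtype=np.int16).reshape(
        gt.n_sites, len(gt.samples)
    )


def _group_freqs(mat: np.ndarray, cols: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """ALT allele frequency and non-missing allele count per site."""
    sub = mat[:, cols]
    miss = sub == MISSING
    alt = np.where(miss, 0, sub).sum(axis=1)
    n = 2 * (~miss).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


# ---------------------------------------------------------------------------
# LD pruning


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    Undefined (NaN) when either vector is constant over shared samples.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    gt: GenotypeTable, window_snps: int = 50, step_snps: int = 5, r2_max: float = 0.5
) -> GenotypeTable:
    """Sliding-window LD pruning (PLINK ``--indep-pairwise`` semantics).

    Within each window of ``window_snps`` consecutive SNPs (per
    chromosome), while any retained pair has r^2 > ``r2_max``, the later
    member of the highest-r^2 pair is removed; the window then advances
    ``step_snps``.  Monomorphic sites (undefined r^2) are always
    retained.  Deterministic.
    """
    if len(gt.samples) < 2:
        raise ValueError("need >= 2 samples")
    mat = _dosage_matrix(gt)
    keep = np.ones(gt.n_sites, dtype=bool)
    chrom_of = [s[0] for s in gt.sites]
    # per-chromosome site index lists
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(chrom_of):
        by_chrom.setdefault(c, []).append(i)
    for idxs in by_chrom.values():
        start = 0
        while start < len(idxs):
            window = [i for i in idxs[start : start + window_snps] if keep[i]]
            while True:
                worst, worst_pair = r2_max, None
                for a in range(len(window)):
                    for b in range(a + 1, len(window)):
                        r2 = _r2(mat[window[a]], mat[window[b]])
                        if not math.isnan(r2) and r2 > worst:
                            worst, worst_pair = r2, (a, b)
                if worst_pair is None:
                    break
                keep[window[worst_pair[1]]] = False
                window.pop(worst_pair[1])
            if start + window_snps >= len(idxs):
                break
            start += step_snps
    sites = [s for i, s in enumerate(gt.sites) if keep[i]]
    return GenotypeTable(list(gt.samples), sites)


# ---------------------------------------------------------------------------
# Diversity and differentiation


def window_pi(
    gt: GenotypeTable, group_cols: list[int], windows: list[Interval]
) -> list[float]:
    """Per-window nucleotide diversity (per bp) for one sample group.

    Per SNP site the unbiased heterozygosity 2*p*(1-p)*n/(n-1) is used
    (n = non-missing allele count in the group); window pi is the sum
    over its SNPs divided by the window length.  Windows whose group
    data are entirely missing yield NaN.
    """
    if not group_cols:
        raise ValueError("empty group")
    mat = _dosage_matrix(gt)
    p, n = _group_freqs(mat, group_cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n >= 2, 2 * p * (1 - p) * n / np.maximum(n - 1, 1), np.nan)
    pos = np.array([s[1] for s in gt.sites])
    chrom = np.array([s[0] for s in gt.sites])
    out = []
    for w in windows:
        mask = (chrom == w.chrom) & (pos >= w.start) & (pos <= w.end)
        vals = het[mask]
        if mask.sum() and np.all(np.isnan(vals)):
            out.append(float("nan"))
        else:
            out.append(float(np.nansum(vals)) / len(w))
    return out


def hudson_fst_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator and denominator of Hudson's FST estimator."""
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    usable = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    return np.where(usable, num, 0.0), np.where(usable, den, 0.0)


def _wc_fst_components(p1, n1, p2, n2):
    """Weir & Cockerham (1984) theta components for two populations,
    haploid-allele-count form without heterozygosity correction."""
    usable = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    n1 = np.maximum(n1, 2).astype(float)
    n2 = np.maximum(n2, 2).astype(float)
    r = 2.0
    n_bar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = n_bar / nc * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    num = a
    den = a + b
    return np.where(usable, num, 0.0), np.where(usable, den, 0.0)


def window_fst(
    gt: GenotypeTable,
    cols_a: list[int],
    cols_b: list[int],
    windows: list[Interval],
    estimator: str = "hudson",
) -> list[float]:
    """Per-window FST between two groups (ratio of sums across sites).

    ``hudson`` (default) or ``weir_cockerham``.  Windows with zero
    denominator yield NaN.
    """
    if not cols_a or not cols_b:
        raise ValueError("empty group")
    if estimator not in ("hudson", "weir_cockerham"):
        raise ValueError(f"unknown estimator {estimator!r}")
    mat = _dosage_matrix(gt)
    p1, n1 = _group_freqs(mat, cols_a)
    p2, n2 = _group_freqs(mat, cols_b)
    fn = hudson_fst_components if estimator == "hudson" else _wc_fst_components
    num, den = fn(p1, n1, p2, n2)
    pos = np.array([s[1] for s in gt.sites])
    chrom = np.array([s[0] for s in gt.sites])
    out = []
    for w in windows:
        mask = (chrom == w.chrom) & (pos >= w.start) & (pos <= w.end)
        d = den[mask].sum()
        out.append(float(num[mask].sum() / d) if d > 0 else float("nan"))
    return out


def compute_window_stats(
    gt: GenotypeTable,
    grouping: dict[str, str],
    reference_group: str,
    candidate_group: str,
    windows: list[Interval],
    estimator: str = "hudson",
) -> list[WindowStats]:
    """Per-window pi (both groups), pi ratio and FST for one comparison.

    ``pi_ratio = pi(reference_group) / pi(candidate_group)`` so that a
    diversity-reducing sweep in the candidate group raises the ratio.
    """
    cols = {
        g: [i for i, s in enumerate(gt.samples) if grouping.get(s) == g]
        for g in (reference_group, candidate_group)
    }
    pi_ref = window_pi(gt, cols[reference_group], windows)
    pi_cand = window_pi(gt, cols[candidate_group], windows)
    fst = window_fst(gt, cols[reference_group], cols[candidate_group], windows, estimator)
    pos = np.array([s[1] for s in gt.sites])
    chrom = np.array([s[0] for s in gt.sites])
    stats = []
    for i, w in enumerate(windows):
        n_snps = int(((chrom == w.chrom) & (pos >= w.start) & (pos <= w.end)).sum())
        ratio = (
            pi_ref[i] / pi_cand[i]
            if pi_cand[i] and not math.isnan(pi_cand[i]) and not math.isnan(pi_ref[i])
            else float("nan")
        )
        stats.append(
            WindowStats(
                window=w,
                pi={reference_group: pi_ref[i], candidate_group: pi_cand[i]},
                fst=fst[i],
                pi_ratio=ratio,
                n_snps=n_snps,
            )
        )
    return stats


def scan_sweeps(
    stats: list[WindowStats], quantile: float = 0.95, comparison: str = ""
) -> SweepScanResult:
    """Joint top-quantile outlier scan over window statistics.

    Thresholds are empirical quantiles (linear interpolation) of the
    finite FST and pi-ratio values; a window is selected when it exceeds
    BOTH thresholds strictly (ties at the threshold excluded).  Selected
    windows are merged into regions.
    """
    finite_fst = [s.fst for s in stats if math.isfinite(s.fst)]
    finite_ratio = [s.pi_ratio for s in stats if math.isfinite(s.pi_ratio)]
    if min(len(finite_fst), len(finite_ratio)) < 20:
        raise ValueError("need >= 20 finite windows for a quantile scan")
    fst_thr = float(np.quantile(finite_fst, quantile))
    ratio_thr = float(np.quantile(finite_ratio, quantile))
    selected = [
        s
        for s in stats
        if math.isfinite(s.fst)
        and math.isfinite(s.pi_ratio)
        and s.fst > fst_thr
        and s.pi_ratio > ratio_thr
    ]
    regions = merge_intervals([s.window for s in selected])
    return SweepScanResult(comparison, fst_thr, ratio_thr, selected, regions)


def overlap_regions(
    regions: list[Interval], candidate: Interval
) -> tuple[int, bool]:
    """Base-pair overlap of merged regions with a candidate interval.

    Returns total overlapping bp and whether the candidate is fully
    contained in a single region.
    """
    bp = sum(r.overlap_bp(candidate) for r in regions)
    fully = any(r.contains(candidate) for r in regions)
    return bp, fully


# ---------------------------------------------------------------------------
# SNP distances and neighbor-joining


def snp_distance_matrix(
    gt: GenotypeTable, restrict: Interval | None = None
) -> tuple[np.ndarray, list[str]]:
    """Pairwise allele-sharing distance: mean |dosage_i - dosage_j| / 2.

    Sites missing in either sample of a pair are excluded pairwise; a
    pair with no shared sites raises an error naming the pair.
    """
    if len(gt.samples) < 3:
        raise ValueError("need >= 3 samples")
    table = gt.restrict(restrict) if restrict is not None else gt
    mat = _dosage_matrix(table).astype(float)
    mat[mat == MISSING] = np.nan
    n = len(table.samples)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
            if not ok.any():
                raise ValueError(
                    f"samples {table.samples[i]} and {table.samples[j]} share no sites"
                )
            d = np.abs(mat[ok, i] - mat[ok, j]).mean() / 2.0
            dm[i, j] = dm[j, i] = d
    return dm, list(table.samples)


@dataclass
class PhyloNode:
    name: str | None = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: np.ndarray, names: list[str]) -> PhyloNode:
    """Neighbor-joining on a symmetric distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    (name_i, name_j) pair; negative branch lengths are clamped to zero.
    The returned tree is unrooted, represented with a trifurcating root.
    """
    dm = np.asarray(dm, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(names) < 3:
        raise ValueError("need >= 3 leaves")
    nodes: list[PhyloNode] = [PhyloNode(name=n) for n in names]
    labels = list(names)
    D = dm.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = PhyloNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[-1, : m - 2] = D2[: m - 2, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
    # join the final three nodes at an unrooted trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, (d01 + d02 - d12) / 2)
    l1 = max(0.0, (d01 + d12 - d02) / 2)
    l2 = max(0.0, (d02 + d12 - d01) / 2)
    return PhyloNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


def tree_bipartitions(tree: PhyloNode) -> list[frozenset]:
    """Leaf sets of every internal edge (one side of each bipartition)."""
    out: list[frozenset] = []

    def walk(node: PhyloNode):
        for child, _ in node.children:
            if child.children:
                out.append(frozenset(child.leaves()))
            walk(child)

    walk(tree)
    return out


def is_monophyletic(tree: PhyloNode, group: set[str]) -> bool:
    """True if some edge of the unrooted tree splits ``group`` from the rest."""
    all_leaves = frozenset(tree.leaves())
    g = frozenset(group)
    if g == all_leaves or not g:
        return True
    for side in tree_bipartitions(tree):
        if side == g or all_leaves - side == g:
            return True
    # also check splits induced at the root's children
    for child, _ in tree.children:
        side = frozenset(child.leaves())
        if side == g or all_leaves - side == g:
            return True
    return False
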