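"""Nei-Gojobori Ka/Ks, Ks-peak fitting, and WGD-anchored divergence dating.

The estimator is the classical NG86 method: per-codon synonymous-site
fractions from the universal genetic code, observed differences resolved
by averaging over all minimal substitution pathways (pathways through
stop codons excluded), and Jukes-Cantor correction of the proportions.
Ks peaks of block-median distributions are fitted as Gaussian mixtures;
a linear molecular clock anchored on the core-eudicot hexaploidy (ECH,
~130 Mya, paralog Ks ~ 1.25 in grapes) converts ortholog Ks to
divergence time.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    CODON_TABLE[_a + _b + _c] = _AMINO[_i]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in CODON_TABLE if c not in STOP_CODONS)


@dataclass
class NGCounts:
    """NG86 site and difference counts for one codon alignment."""

    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences


@dataclass
class KaKsResult:
    Ka: float
    Ks: float
    omega: float | None  # Ka/Ks; None when Ks == 0
    saturated: bool = False  # either proportion beyond the JC ceiling


@dataclass
class KsPeak:
    """One fitted Ks mixture component, reported as mu (± sigma)."""

    mu: float
    sigma: float
    weight: float

    def __str__(self) -> str:
        return f"{self.mu:.2f} (± {self.sigma:.3f})"


@dataclass
class DivergenceEstimate:
    T: float  # Mya
    ks_ortho: float
    ks_ech: float
    t_ech: float


@functools.lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in one sense codon (0..3).

    Each position contributes f/3 sites, f being the fraction of the
    three single-nucleotide changes that preserve the amino acid.
    Changes creating a stop codon count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


@functools.lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal pathways.

    All orderings of the differing positions are enumerated; pathways
    visiting a stop codon at an intermediate step are discarded.  If every
    pathway is stop-routed, the average is over all pathways instead (the
    degenerate fallback of the classical method).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            cur = nxt
        fallback.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def ng86_counts(seq_a: str, seq_b: str) -> NGCounts:
    """NG86 site/difference counts for a gap-free codon alignment.

    Site totals are averaged over the two sequences, so S + N equals the
    aligned length in nucleotides.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("alignment length not divisible by 3")
    if len(seq_a) < 3:
        raise ValueError("alignment shorter than one codon")
    S = Sd = Nd = 0.0
    n_codons = len(seq_a) // 3
    for i in range(n_codons):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i + 1}")
        S += (synonymous_site_fraction(ca) + synonymous_site_fraction(cb)) / 2.0
        sd, nd = _codon_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    return NGCounts(S=S, N=len(seq_a) - S, Sd=Sd, Nd=Nd)


def jc_correct(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns ``None`` (saturated) for p >= 0.75.
    """
    if p < 0:
        raise ValueError(f"negative proportion {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


def estimate_ka_ks(seq_a: str, seq_b: str) -> KaKsResult:
    """Ka and Ks by NG86 counting with Jukes-Cantor correction."""
    c = ng86_counts(seq_a, seq_b)
    if c.S == 0 or c.N == 0:
        raise ValueError("degenerate alignment: zero synonymous or nonsynonymous sites")
    ks = jc_correct(c.Sd / c.S)
    ka = jc_correct(c.Nd / c.N)
    if ks is None or ka is None:
        return KaKsResult(Ka=float("nan"), Ks=float("nan"), omega=None, saturated=True)
    omega = None if ks == 0 else ka / ks
    return KaKsResult(Ka=ka, Ks=ks, omega=omega)


def ks_distribution(blocks, ks_by_pair: dict[tuple[str, str], float]) -> list[float]:
    """One Ks value per collinear block: the median over its anchors.

    Saturated anchors (missing / NaN Ks) are excluded; blocks with no
    usable anchor are omitted.
    """
    out: list[float] = []
    for block in blocks:
        vals = []
        for a in block.anchors:
            k = ks_by_pair.get((a.gene_a, a.gene_b), ks_by_pair.get((a.gene_b, a.gene_a)))
            if k is not None and math.isfinite(k):
                vals.append(k)
        if vals:
            out.append(float(np.median(vals)))
    return out


def fit_ks_peaks(
    values, n_components: int = 1, seed: int = 0,
    ks_range: tuple[float, float] | None = None,
) -> list[KsPeak]:
    """Fit a Gaussian mixture to Ks values and return components by mu.

    ``ks_range`` restricts the fit to values inside a window (useful to
    isolate e.g. the hexaploidy peak from recent tandem duplicates).
    """
    v = np.asarray([x for x in values if math.isfinite(x)], dtype=float)
    if ks_range is not None:
        v = v[(v >= ks_range[0]) & (v <= ks_range[1])]
    if len(v) < 50:
        raise ValueError(f"need >= 50 finite values, got {len(v)}")
    if len(v) < 10 * n_components:
        raise ValueError(
            f"{len(v)} values cannot support {n_components} components"
        )
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant) Ks values")
    gm = GaussianMixture(
        n_components=n_components, random_state=seed, n_init=3, covariance_type="full"
    ).fit(v.reshape(-1, 1))
    peaks = [
        KsPeak(mu=float(m[0]), sigma=float(np.sqrt(c[0, 0])), weight=float(w))
        for m, c, w in zip(gm.means_, gm.covariances_, gm.weights_)
    ]
    peaks.sort(key=lambda p: p.mu)
    return peaks


def calibrate_divergence(
    ks_ortho: float, ks_ech: float, t_ech_mya: float = 130.0
) -> DivergenceEstimate:
    """Linear molecular-clock dating: T = Ks_ortho * T_ECH / Ks_ECH (Mya)."""
    if ks_ech <= 0:
        raise ValueError("ECH anchor Ks must be positive")
    if t_ech_mya <= 0:
        raise ValueError("ECH age must be positive")
    if ks_ortho < 0:
        raise ValueError("ortholog Ks must be non-negative")
    return DivergenceEstimate(
        T=ks_ortho * t_ech_mya / ks_ech,
        ks_ortho=ks_ortho,
        ks_ech=ks_ech,
        t_ech=t_ech_mya,
    )


def calibrate_divergence_range(
    ks_ortho_range, ks_ech_range, t_ech_mya: float = 130.0
) -> tuple[float, float]:
    """(T_min, T_max) over a grid of ortholog and anchor Ks values."""
    ts = [
        calibrate_divergence(o, e, t_ech_mya).T
        for o in ks_ortho_range
        for e in ks_ech_range
    ]
    return min(ts), max(ts)
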