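# Methods

This note documents the models, defaults and numerical choices behind
`grapediverge`, and what the synthetic-data generators do and do not
emulate.

## Ka/Ks estimation (NG86 + Jukes–Cantor)

The estimator is the classical Nei–Gojobori counting method, not the
YN00 refinement: no transition/transversion bias and no codon-frequency
weighting.  Per codon, each position contributes `f/3` synonymous sites
with `f` the fraction of the three single-nucleotide changes preserving
the amino acid; totals are averaged over the two sequences so `S + N`
always equals the aligned nucleotide length.  Changes that would create
a stop codon count as nonsynonymous in site counting.  Codons differing
at 2–3 positions are resolved by averaging synonymous/nonsynonymous
step counts over all orderings of the substitutions, excluding orderings
that pass through a stop codon; if every ordering does, the average is
taken over all of them (degenerate fallback).  Proportions `Sd/S` and
`Nd/N` are corrected with `d = −(3/4)·ln(1 − 4p/3)`; `p ≥ 0.75` is
flagged saturated rather than returned as a number.  Codon alignments
are assumed gap-free and in frame; a pairing mode for equal-length
synthetic CDS is built in, while protein-guided alignment is expected
from upstream tools.

## Ks distributions, peak fitting, dating

Collinear blocks are summarized by the median Ks of their anchors
(saturated anchors dropped; anchor-level values can be fitted directly
when block counts are small).  Peaks are Gaussian mixtures fitted by EM
(scikit-learn, 3 initializations, fixed random state, components
reported sorted by mean in the conventional "μ (± σ)" form).  Fits
require ≥ 50 finite values and ≥ 10 per component; constant input is an
error rather than a zero-variance component.  Dating uses a linear
molecular clock anchored on the core-eudicot hexaploidy: `T = Ks_ortho ×
T_ECH / Ks_ECH` with `T_ECH = 130` Mya by default (the anchor age is an
argument everywhere, since estimates of the hexaploidy range up to
~150 Mya).  A grid variant maps ranges of both Ks values to a `[T_min,
T_max]` band.

## Collinear chaining and paralog classes

Chaining works in gene-rank space per chromosome pair.  A block is a
strictly monotone chain (ascending/ascending = `same`,
ascending/descending = `inverted`) with consecutive rank gaps ≤ 25 on
both axes and ≥ 5 anchors; both defaults are exposed because published
collinearity tools vary.  The longest chain is extracted greedily and
its anchors removed until none qualifies, so blocks never share anchors.
Among equally long chains the lexicographically smallest in rank-sorted
order is taken, which makes the decomposition canonical and
reproducible.  Paralog pairs are `ech` when they lie in a block and
their Ks falls within μ ± 2σ of the fitted hexaploidy peak, `tandem`
when both genes sit on one chromosome within 5 ranks (flag-exposed; the
threshold is a convention, not a published value); the labels are not
forced to be exclusive, because genome surveys genuinely report
overlapping counts, and a pair satisfying both is reported under both
with a warning.  Duplicated-gene retention is the number of distinct
genes in intra-genome blocks over all annotated genes, formatted with
half-up rounding (34/64 → 53.13%, not banker's 53.12%).

## PAV segments

Windows are 500 bp every 100 bp, starting at base 1; trailing sub-size
windows are dropped so coverage fractions always share the 500-bp
denominator.  A window is genome-specific when it has no overlapping
alignment or its union coverage is strictly below 25%; specific windows
are merged (book-ended intervals join) into segments.  "Genes within
segments" is operationalized as ≥ 50% of the gene span covered by
segments, with a strict-containment mode behind a flag, since the source
procedure does not define "within".  An exact 21-mer matcher can stand
in for an external aligner on synthetic or closely related sequences; it
is conservative (exact matches only) and PAF input is the production
path.

## Population statistics and sweep scan

π per group is the sum over SNPs of the unbiased per-site
heterozygosity `2p̂(1−p̂)·n/(n−1)` divided by window length (n =
non-missing allele count; missing genotypes are excluded site-wise,
never imputed).  F_ST is Hudson's estimator as a ratio of sums across
sites; Weir–Cockerham is available behind a flag for sensitivity checks.
The π ratio is π(reference)/π(candidate) so a sweep in the candidate
group raises it; the orientation is explicit per comparison.  Sweep
windows default to 5 kb non-overlapping (published selected-region
bounds are 5-kb multiples).  Thresholds are empirical 95th percentiles
with linear interpolation; selection requires strictly exceeding both,
so a degenerate all-equal scan selects nothing.  LD pruning follows the
PLINK sliding-window scheme (50 SNPs, step 5, r² > 0.5 removes the later
member of the worst pair; monomorphic sites, whose r² is undefined, are
kept).  Mixed-ploidy VCF genotypes are either collapsed to presence
dosage (any ALT → 1, all-ALT → 2) or excluded, both exposed, since the
handling in the source panel is unstated.

Trees are neighbor-joining on allele-sharing distance (mean
|dosage_i − dosage_j|/2 over pairwise-complete sites), with Q-criterion
ties broken by leaf-name order and negative branch lengths clamped to
zero.  Only topology-level claims (does some edge split a group from the
rest?) are asserted — NJ supports those; an ML tree would be needed for
branch-support claims, which are out of scope.

## Network robustness

Robustness is the mean fraction of original nodes in the largest
connected component after removal of k nodes (or a percentage, rounded
half-up to a count).  Random removal averages 1000 seeded trials by
default; degree-targeted removal is deterministic with name-order tie
breaks.  The metric convention is documented rather than taken from any
specific published table, whose underlying networks are not available.

## SDR lift-over and haplotype content

Lift-over maps an interval through one-to-one ortholog anchors: anchors
overlapping the source plus one flanking anchor per side span the
target; orientation is the sign of the coordinate correlation.  The
packaged SDR annotation places the 16 genes of the Amur grape candidate
region (chr2:5,055,465–5,198,824) at synthetic coordinates inside the
interval — the published ids and functional labels with invented
placements — and the *V. vinifera* female-haplotype list uses synthetic
placeholder ids because only its labels are published.  Content
comparison is a multiset diff of normalized labels plus a relative-order
check.

## Synthetic data: what it emulates, and what it does not

*Codon pairs.*  Ancestors are built from codon families whose third
position is fully synonymous and first/second fully nonsynonymous
(GCN/GGN/GTN/CCN/ACN/TCN), so the generative site categories coincide
exactly with the NG86 site definitions — the estimator under test is
then checked as a parameter-recovery problem with no model mismatch.
Substitutions are Poisson per site, split evenly over the two branches,
and never create stops.  This is deliberately not a full codon-model
simulator (no transition bias, no rate heterogeneity): recoveries here
validate the counting machinery, not robustness to model violation.

*Genome pairs.*  Defaults: 2 chromosomes × 300 genes of 450 bp with
500-bp spacers, ortholog Ks 0.026, hexaploidy-paralog Ks 1.25, retention
0.2 (as the fraction of final genes participating in a retained pair,
matching the duplicated-gene-percentage convention; the homeolog
chromosomes carry `ρn/(2−ρ)` retained copies each), one implanted
inversion and three 5-kb query-specific segments.  The alignment table
is constructed, not computed: it covers exactly the shared sequence, so
PAV recovery tests the windowing/merging logic against known gaps, not
an aligner.

*Populations.*  24 diploids (10 female / 5 male / 9 hermaphrodite),
2 Mb, 40,000 SNPs, target π = 0.005/bp.  Base frequencies are Beta(a,a)
with `a` solved from the target π, the SNP density, and the
heterozygosity lost to background structure (factor 1 − F/2), so the
realized genome-wide π matches the target.  Samples alternate between
two ancestry clusters, independent of sex, drifted apart by a
Balding–Nichols model with F = 0.3; this reproduces the
study-characteristic contrast in which the genome-wide tree groups
samples by ancestry while only the region-restricted tree groups them
by sex.  The sweep (central 100 kb) displaces the male-group frequency
by 0.6 toward the far allele boundary and shrinks its distance to that
boundary by the factor 0.1: diversity drops and a large frequency gap
opens, without any attempt at coalescent realism — the acceptance
surface is window statistics, not genealogies.  A label-permutation
control strongly degrades sweep detection but does not abolish it: with
only five causal samples, permutations that concentrate them in one
analysis group retain genuine localized differentiation, exactly as
they would in a real panel of this size; tests assert strong
degradation, not total destruction.

*Networks.*  Erdős–Rényi with p = mean_degree/(n−1), or Barabási–Albert
with m = mean_degree/2; simple graphs, seeded.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (numpy Generator);
identical spec + seed gives byte-identical outputs.  The test suite and
the acceptance script use reduced problem sizes chosen to exercise every
code path with comfortable statistical margins: 1,500–2,000 codon pairs
of 300 codons for Ks recovery, a ~600-gene genome pair for
collinearity/PAV, 100 population seeds at 2 Mb for the sweep-detection
rate, and NJ-tree contrasts on a 10-seed subset.

## Known limitations

- NG86 underestimates Ks relative to YN00 when transition bias is
  strong; fine for the synthetic data (generated without bias), a known
  caveat on real CDS.
- The exact k-mer matcher misses diverged homology; it is a testing
  convenience, not an aligner.
- Collinear chaining is rank-space only; base-level structural-variant
  calls (inversion breakpoints) are out of scope.
- The allele-frequency sweep model cannot generate linked-haplotype
  signatures (iHS/XP-EHH style statistics would see nothing).
- Lift-over assumes a locally one-to-one anchor map; paralogy-confused
  anchor sets should be filtered to syntenic orthologs first.
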