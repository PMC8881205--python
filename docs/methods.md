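# Methods

## The signal: multi-mapping pileup over repeat-derived gene fragments

A fragment of a multi-copy TE family embedded in (or annotated together
with) a single-copy gene attracts reads originating from every copy of
the family: with `n` near-identical copies and haploid depth `c`, the
fragment's mapped depth is ~`n·c` while the rest of the gene sits at
`c`. Detection therefore needs only a depth track and gene coordinates,
not an alignment of the repeat itself.

## Synthetic data generator

The generator emulates the statistical structure this signal lives in,
with full ground truth:

- **Background**: i.i.d. uniform A/C/G/T (GC = 0.5). GC bias and
  heterozygosity are deliberately not modeled.
- **Features**: genes and intergenic repeat copies are placed uniformly
  and non-overlapping per contig by stick breaking (free space split into
  random gaps); contig assignment is length-weighted with bounded
  retries, and an overfull contig raises a placement error.
- **Repeat copies**: each family has a random consensus; each copy is the
  consensus mutated by per-site substitutions at a rate drawn from the
  family's divergence distribution (truncated to [0, 0.5]). Substitutions
  always change the base and indels are off, so realized divergence is
  exactly the measured mismatch fraction — the `.out` divergence column
  is the realized value, not the nominal rate.
- **TE–gene inserts**: a configurable fraction of genes receives a random
  consensus fragment. Internal placement overwrites part of the gene
  body; adjacent placement abuts the gene end, and the emitted gene
  interval is extended over the insert, mimicking ortholog annotations
  that inadvertently include flanking repeat sequence. Insert lengths
  default to uniform 200–1,000 bp (they must fit inside ~1.5 kb genes
  for internal placement).
- **Coverage**: depth at position *p* is Poisson(`base_depth · m(p)`)
  where the multiplicity `m(p)` is the realized number of genomic copies
  of the family covering *p* (1 outside repeats), smoothed by a
  read-length moving mean (default 150 bp) to mimic read-edge effects.
  This multiplicity model reproduces the pileup mechanism without
  running an aligner; it does not model mapping-quality filtering,
  sequencing error, or paired-end effects, so passing tests demonstrate
  detector correctness under the pileup model, not robustness to every
  real-world mapping artifact.

The standard benchmark dataset is a 2 Mb, 4-contig assembly, 200
Complete genes (uniform 1.2–1.8 kb), one 50-copy LINE family (2 kb
consensus, per-copy divergence ~ N(0.05, 0.02) truncated at 0), 20% of
genes carrying an insert, 10× depth. Everything is a deterministic
function of (config, seed); datasets round-trip byte-identically.

## Detection

Per Complete (or Duplicated) gene span: smooth the raw depth with a
25 bp moving mean, call maximal runs where smoothed depth ≥ 2.0× the
baseline, merge runs closer than the smoothing window, keep runs ≥ 50 bp.
The baseline is the median per-base depth pooled over all Complete gene
spans (robust to genome-wide repeat content because inflated fragments
are a small minority of pooled gene bases); the genome-wide positive-depth
median is available as a fallback, and a baseline under 5× raises a
low-coverage warning. A gene is TE-associated iff it has ≥ 1 region; the
reported fraction uses distinct Complete ids as the denominator by
default (Duplicated ids can be included; copies are profiled separately
but counted once). Raising either threshold can only shrink the flagged
set (monotonicity is tested). The thresholds are declared package
defaults, exposed in `ProfileParams`, not values inherited from any
external tool.

## Quantification

The search backend is an exact-k-mer seeded, ungapped x-drop extension
scorer: seeds on both strands are grouped per diagonal, merged into
runs, extended until the running score drops more than `x_drop` (20)
below its maximum, and overlapping same-diagonal extensions are
collapsed. The default seed length is 15: the query fragment and the
genomic copies have each diverged independently from the consensus, so
pairwise divergences around 10% are the operating regime, and longer
(megablast-style) seeds frequently have no exact match over a short
fragment there, silently dropping whole copies. E-values use fixed
Karlin–Altschul-style constants (λ = 1.28, K = 0.46) and are comparative
rankings only — absolute agreement with external search tools is a
non-goal, and externally produced 12-column tabular hits are accepted as
a drop-in backend for that purpose.

Filtered hits (e ≤ 1e-5, length ≥ 50, identity ≥ 80%) are unioned per
base on the subject, all Complete BUSCO loci are subtracted (removing
the query's own locus and every other gene locus, so residual bases
measure repeat copies *outside* genes), and residual bases are
attributed to the category of the overlapping repeat annotation; where
annotations overlap, the higher score wins, ties broken by earlier
interval then family name. The conservation invariant
Σ categories + unannotated = total holds by construction and is tested
against per-base bitmask oracles. All interval arithmetic is sorted-
interval/event-sweep based, never per-base masks.

The reference contrast runs the identical chain twice against the same
assembly — once with the inflated gene, once with the insert-free
ortholog — and reports the residual-bases ratio (denominator clamped at
1). Pairwise validation aligns inflated vs reference globally with
affine gaps (match +1, mismatch −2, open 5, extend 1, via biopython) and
declares success when an unaligned query segment ≥ 30 bp overlaps a
flagged region by ≥ 50% of the region or ≥ 100 bp. Sequences beyond a
50 kb cap raise an error rather than silently burning quadratic time.

## Repeat landscapes

Two-pass annotation runs are merged with first-pass priority: second-run
hits are trimmed against first-run coverage (the second pass normally
sees a hardmasked assembly, so trimming only matters when inputs were
not truly disjoint). Summaries assign every annotated base to exactly
one hit (score, then earlier start, then family name), so category
proportions sum to the masked proportion. Landscapes add each hit's
disjointly-assigned bases to the bin `⌊divergence / bin_width⌋` of its
category (bin widths 1, 2 or 5; > 50% pooled into the last bin).
Divergence is used as annotated (raw %); a Kimura-style correction is
available but off by default since annotation pipelines differ in what
they report. These landscapes are assembly-based: abundance is annotated
assembly bases, not read-cluster abundance, so satellite fractions
under-represented in assemblies are under-represented here too.

## Genome size

The back-mapping estimator divides total mapped bases by the modal
per-base depth: the histogram is smoothed (window 3), the argmax over
depth ≥ 1 is the 1C peak, smoothed ties are broken by raw count then by
the lowest depth (haploid-peak convention, with a warning listing
candidates). Uniform coverage recovers the track length exactly. On
simulated tracks the relevant truth is the multiplicity-weighted base
total Σ m(p) — the collapsed-repeat analogue in which reads from all
copies exist but the assembly holds fewer; the estimator recovers it to
well under 1%. The k-mer-peak comparator (canonical k-mers, default
k = 21) is deliberately naive — total k-mers ÷ peak multiplicity in read
mode, total k-mer count in assembly mode — and is labeled as such in all
outputs; fitting the full genome-profiling mixture model is out of
scope. Method agreement uses the textbook Bland–Altman quantities: bias
= mean paired difference, limits of agreement = bias ± 1.96 × SD(diff).

## Association statistics

Correlations (Pearson or Spearman) carry a two-sided label-permutation
p-value, p = (1 + #{|r*| ≥ |r|}) / (n_perm + 1), seeded and vectorized;
permutation is used because species-level comparative designs have small
n and asymptotic p-values are fragile there. Empirical type-I error at
α = 0.05 over 1,000 null replicates sits within [0.03, 0.07]. Group
summaries report n, mean, sample SD, quartiles and pairwise fold
differences of means. No multiple-testing correction is applied by
default across the handful of category correlations (a Benjamini–
Hochberg helper can be layered on via statsmodels if needed);
phylogenetically independent contrasts are a non-goal.

## Problem sizes and numerical choices

Benchmarks run at 2 Mb assemblies / 200 genes (detector, quantifier),
1 Mb (genome size), 0.6 Mb (landscapes), 75 alignment pairs and 1,000
permutation replicates — sizes chosen so the full acceptance run
completes in well under a minute while keeping every per-gene statistic
in its asymptotic regime (50-copy pileups at 10× are a ~50σ signal; the
scores are not threshold-sensitive). Coordinates are 0-based half-open
internally with one conversion site per external format; all writers are
bit-stable; every stochastic routine takes an explicit seed and derived
child seeds stay below 2³¹.

## Known limitations

- The multiplicity coverage model treats all copies of a family as
  cross-mapping equally; real multi-mapping depends on aligner scoring,
  mapping-quality thresholds and copy-to-copy identity structure.
- The built-in search is ungapped; indel-rich repeat copies fragment
  into multiple hits (base accounting is unaffected by the per-base
  union, but per-hit statistics differ from gapped tools).
- Landscape divergences come from the annotation, so consensus quality
  bounds age resolution; two bursts closer than ~2 bins are not
  separable at the default bin width.
- The detector sees only the annotated gene span; inserts beyond the
  span (and not absorbed into the annotation) are invisible by design.
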