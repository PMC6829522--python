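# Methods

## Differential-coverage binning

Scaffolds assembled jointly from several colony metagenomes are represented
by their mean read depth in each of three colony samples, computed as the sum
of aligned bases over scaffold length (equal to the per-base pileup mean).
Depths are transformed to `log10(depth + c)` with pseudocount `c = 0.01`,
which keeps zero-coverage scaffolds finite at −2 — populations entirely
absent from a colony are common and informative, and the pseudocount places
them on a tight plane of the coverage space rather than at −∞.

The original selection of coverage clouds was interactive; `colonybin`
replaces it with deterministic density clustering with DBSCAN semantics: a
scaffold with at least `min_cluster_size` neighbors (default 10, itself
included) within Euclidean radius `r` (default 0.3 log10 units) is a core
point; bins are connected components of core points plus their reachable
neighbors; everything else is noise. The defaults were validated on
simulation, not fitted to any external dataset: at 50 000 pairs per sample a
scaffold of a few kbp has Poisson depth noise well below 0.1 log units, an
order of magnitude smaller than the abundance contrasts in the default
design, while `r = 0.3` still merges the per-genome clouds across their
within-genome GC-bias spread. Cluster labels are renumbered by first
appearance, so identical inputs give identical labels.

## Composition refinement of mixed bins

Two populations can share a coverage vector by chance. Single-copy essential
genes flag such mixtures: a bin whose duplicated-marker count exceeds
`max_duplicated` (default 5, the largest value seen among clean accepted
bins) is split. Member scaffolds are projected onto the first two principal
components of their TNF matrix with GC as a third axis — all three axes
standardized to unit variance, since raw PC coordinates are of order 10⁻³
while a standardized GC axis is of order 1 and would otherwise dominate —
and divided by 2-means seeded from the two most GC-distant members
(deterministic). The 2-means is length-weighted: scaffold TNF noise scales
as 1/√length, so long scaffolds anchor the centroids while short ones are
merely assigned. A split is accepted only if it strictly reduces the total
duplicated-marker count; accepted sub-bins are refined recursively. The
acceptance rule guarantees refinement never increases duplication and makes
degenerate splits a no-op.

Tetranucleotide frequencies use 136 canonical keys: each 4-mer is pooled
with its reverse complement (palindromes map to themselves) because
assembled scaffolds are strandless. Windows containing ambiguous bases are
skipped; counts are normalized to frequencies.

## MDA GC-bias standardization

Multiple displacement amplification over-amplifies low-GC DNA. The bias is
estimated by comparing GC histograms (1-percentage-point half-open bins) of
the amplified metagenome and an unamplified bulk sample:
`factor(bin) = bulk_fraction(bin) / amplified_fraction(bin)`. Bins occupied
only in the amplified sample borrow the nearest common bin's factor and are
flagged as smoothed. Histogram weighting is the caller's choice (scaffold
length, scaffold count, or mapped reads); the pipeline weights scaffold GC by
mapped reads, because read counts are the quantity the correction divides.
One-point bins are fine enough to resolve a 42–69% GC community while
keeping thousands of reads per occupied bin at the default depth.

Corrected counts are `mapped_reads × factor(gc bin)` at scaffold granularity
— the finest level the data supports — and a bin's standardized relative
abundance is its corrected share of the corrected total, in percent, so a
full partition sums to 100%. With an unbiased simulation the factors are
statistically indistinguishable from 1 and standardized equals raw abundance
up to Monte-Carlo error.

## Marker-gene quality accounting

A catalog of single-copy essential genes (size configurable, default 107)
gives per-bin completeness `found/total` and a duplicated count (markers
with total bin count ≥ 2). Quality flags follow the conventions
`completeness > 0.90` (near-complete) and `> 0.95` (high), both requiring
duplicated ≤ 5; heavier duplication marks a bin partial regardless of
completeness. On real data marker hits are imported from an external gene
prediction + profile-HMM pipeline as a tab-separated table (duplicate rows
summed, non-positive counts rejected). In synthetic mode markers are unique
random 60-bp tags planted in the genomes and detected by exact substring
search on both strands — at that length a spurious match against random
background is vanishingly improbable, so exact matching reproduces the
accounting (the part under test) without gene prediction.

## Read trimming

Reads are trimmed by four ordered rules: optional exact-match adapter
clipping; removal of leading/trailing bases with quality below 3; truncation
at the start of the first 4-base sliding window (advanced one base at a
time, trailing windows evaluated on their actual length) whose mean quality
drops below 20; and dropping reads shorter than 50 bp. Surviving pairs stay
paired; single survivors go to an orphan stream, which is kept out of
binning coverage by default. The implementation is oracle-tested against an
independent brute-force version of the same rules.

## The synthetic community generator

The generator produces the statistical structure the analysis assumes, with
planted ground truth:

* **Genomes** are i.i.d. sequences of *codons*: each genome draws a private
  64-codon distribution (log-normal perturbation, σ = 0.4, of the
  base-product distribution under per-genome G-vs-C and A-vs-T skews), then
  exponentially tilts it in codon GC count so the expected GC equals the
  target exactly. Codon-usage differences are what give real genomes of
  similar GC their distinct TNF signatures; plain i.i.d. bases cannot do
  this, because the canonical (strand-pooled) TNF of an i.i.d. sequence
  depends only on the unordered base-probability pairs {A,T} and {G,C} — two
  equal-GC genomes would be TNF-identical in expectation and composition
  refinement would be structurally impossible. Marker tags replace
  background bases (genome length stays exact) at uniform non-overlapping
  positions; the background GC target is adjusted for the ≈50%-GC tags so
  the whole genome realizes the target within ±0.01.
* **Abundance designs** are genome × sample weight matrices, column
  normalized; a warning fires if no genome varies at least 5-fold across
  samples, since the binning signal then vanishes. The default community has
  five 200-kbp genomes (GC 0.42/0.50/0.54/0.676/0.685, 105 planted markers
  each from a 107-catalog) and three samples in which each of the first
  three genomes dominates one sample (weight 0.60 vs 0.05), while the two
  high-GC genomes share one vector (0.15/0.15/0.175) — deliberately
  indistinguishable by coverage, so the refinement step is exercised.
* **MDA bias** acts at fragment acceptance: a fragment of GC `g` is accepted
  with probability proportional to `exp(−β(g − 0.5))` (implemented as
  `exp(−βg)`, the weight normalized by its maximum). This one-parameter
  model is monotone in GC and reproduces the qualitative low-GC preference;
  β = 2 gives the default community a ≈12-point raw-abundance distortion in
  a 42%-vs-68% two-genome mixture. The bulk sample is the same simulation
  with β forced to 0 and the design's mean composition.
* **Reads** are the two ends of normal-length fragments (default 2×150 bp,
  insert 300 ± 30) with i.i.d. substitution errors (default 0.5%) and a
  configurable per-position quality profile (default Q38 easing to Q32,
  Phred+33). **Scaffolds** come from geometric-spaced breakpoints (mean 5
  kbp, pieces < 1 kbp discarded), giving the long-tailed length distribution
  of real assemblies; breakpoints are pushed out of marker intervals so
  completeness truth stays exact (a stress mode allows splitting).
  **Alignments** are synthesized from the truth: each mate is assigned to
  the scaffold its interval overlaps most. Everything is seeded;
  regeneration is byte-identical.

What the generator does *not* emulate: chimera formation and
strand-displacement branching of real MDA, indels, inter-genome homology and
shared repeats, assembler behavior (mis-joins, fragmented repeats), and
alignment ambiguity between related genomes. Passing tests therefore show
the pipeline's statistical machinery is correct under its own model — clean
differential coverage, composition-distinct genomes, monotone GC bias — not
that it is robust to strain-level mosaicism or repeat-rich communities.

## Replicate clustering

Genus-level abundance profiles (sample × genus, row-normalized) are reduced
to genera whose cross-sample range is ≥ 0.001 (the threshold is a
convention; the filter is the point) and clustered by average linkage under
Euclidean (default) or Bray-Curtis distance. Samples are ordered
lexicographically before distance computation so ties break identically
regardless of input order; the dendrogram serializes to newick with
merge-height branch lengths. The synthetic bench draws one Dirichlet base
profile per species and log-normal within-species noise (σ = 0.10), under
which replicate colonies of the same species form sister clades.

## Problem sizes and numerical choices

The default validation community uses five 200-kbp genomes and 50 000 read
pairs per sample — deep enough that per-scaffold depth noise is far below
the design contrasts, small enough that the full pipeline runs in well under
a minute on one core; the bias bench uses two 200-kbp genomes at 50 000
pairs over five seeds. Table outputs are written with `%.6g` floats, so
reruns with the same config are byte-identical. Sub-seeds for the pipeline's
stages are fixed offsets of the master seed modulo 2³¹−1. Degenerate inputs
are defined errors, not silent results: empty sequences or histograms,
all-zero design columns, desynchronized mate files, unknown scaffolds in
alignment tables, and zero corrected-read denominators all raise with the
offending item named.

## Limitations

Real-data mode ingests externally produced scaffolds, alignments and marker
hits but does not run assemblers, aligners or gene predictors; re-assembly
of extracted bin reads is a documented hook, not an internal step.
Lineage-specific contamination estimation (CheckM-style) is out of scope —
duplicated universal markers are the only contamination signal. The
N-sample generalization of the 3-sample coverage space exists behind an
explicit flag but is unvalidated. The bias model corrects composition, not
within-genome coverage unevenness, and assumes the bulk sample shares the
amplified community's underlying composition.
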