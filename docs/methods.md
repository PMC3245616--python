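# Methods

## Setting and scope

The package implements the bespoke computational steps of a time-course
RNA-seq analysis on an organism with a highly fragmented, A/T-rich draft
genome: the transcriptome is assembled de novo (assembly itself is out of
scope — assemblies and alignments are consumed as inputs), and the analysis
must work without biological replicates per time window. Coordinates are
0-based half-open everywhere; strand "+" means transcript sense equals the
scaffold forward strand. BLAST tabular input (1-based, inclusive, reversed
subject spans for minus hits) is converted on read.

## Read quality filter

A read passes when at least `m` positions (default 20) have windowed mean
quality strictly greater than `q` (default 10); the window at position *i*
is [*i−w*, *i+w*] (default half-width 2, window length 5), truncated at the
read ends rather than padded — padding would fabricate qualities. The
strictness of both comparisons (`> q`, `≥ m`) follows the flag semantics the
filter reimplements. The window statistic is centered on each position;
evaluating windows at their start offsets would shift calls by `w` but is
otherwise equivalent. Internally the comparison `mean > q` is evaluated as
the integer comparison `window_sum > q × window_width`, so the vectorized
implementation is exactly equal to a naive per-position loop, not just close
to it (the test suite checks bit-level agreement on random reads).

Pair handling: `orphan` (default) drops only the failing mate and keeps the
survivor in a singletons file — the downstream three-step counter consumes
singletons anyway; `drop-pair` and `keep-pair-if-either` are available.

## Assembly QC

- **N50**: largest element L of the length multiset such that sequences of
  length ≥ L contain at least half of all bases. Always a member of the
  multiset; ≥ the lower median, with equality when all lengths are equal.
- **Median convention**: lower median for even counts, so every reported
  order statistic is an observed length.
- **Ortholog hit ratio**: (aligned query nucleotides / 3) / ortholog protein
  length, from the best (highest-scoring) hit passing the e-value cutoff
  (default 1e-3). Queries without a passing hit are omitted from the ratio
  distribution rather than zero-filled, so its shape reflects aligned genes
  only. The ratio is not capped: values above 1 flag queries longer than
  their ortholog.
- **Reciprocal best hits**: (a, b) is a pair iff b is a's unique top score
  ≥ cutoff (default 50) and vice versa; a score tie across distinct targets
  makes the best hit ambiguous and blocks pairing. Pair coverage is the
  union of the pair's aligned blocks on the reference cDNA (overlaps merged)
  divided by cDNA length.
- **Single-scaffold coverage**: a transcript counts at threshold f when some
  single scaffold's merged alignment blocks cover strictly more than f of
  its length; fractions are reported over all transcripts (longest isoform
  per gene), unaligned ones counting against every threshold.
- When PSL input is used, the score is matches + repMatches − misMatches −
  qNumInsert − tNumInsert (the classic web-BLAT score); BLAST tabular input
  uses the bit score. The cutoff applies to whichever score the input
  carries.

## Scaffold-join detection

Only longest isoforms ≥ 1 kb enter the procedure. Each is split into
non-overlapping 500-bp chunks; the sub-500-bp remainder is dropped rather
than scored pro-rata (the acceptance bar of 450 matched bases is defined for
full chunks only). Per chunk, the best placement is kept iff it has ≥
450/500 perfectly matched bases; a tie in matched bases across different
scaffolds is ambiguous and discards the chunk. Consecutive placed chunks on
one scaffold form runs; a transcript whose runs touch ≥ 2 scaffolds is a
candidate, with each junction placed midway between the end of one run's
chunk span and the start of the next (unplaced chunks in between do not
block the call, they only widen the uncertainty). A candidate is *supported*
when one continuous protein alignment block covers [junction − margin,
junction + margin]; margin defaults to 25 bp. The margin rule replaces a
manual inspection step with an explicit, reviewable criterion; unsupported
candidates are retained as low-confidence calls, never silently dropped.

A minimal seeded aligner (16-mer seeds, ungapped extension, perfect-match
counting) places chunks on synthetic scaffolds so the procedure can be
tested end to end; real datasets supply precomputed PSL or BLAST tabular
placements instead.

## Unique read counting and strand bias

Candidate placements per read pair are resolved in three steps: (1) accept
the pair iff exactly one concordant placement exists — mates on opposite
strands of the same transcript, facing inward, implied fragment ≤ 600 bp
(generous for a ~200-bp library); (2) otherwise accept the forward mate iff
it places uniquely; (3) otherwise the reverse mate, likewise. Each accepted
unit — pair or singleton — contributes **one** fragment count, avoiding the
double-counting ambiguity of per-read units. Placements carrying a mapping
quality are filtered at MAPQ > 20; placements without the field rely on
uniqueness alone. Assignment is per-pair and therefore independent of input
order, and accepted + unassigned units always equals the number of pairs.

Stranded libraries accumulate per-gene forward/reverse fragment counts; a
gene is strand-biased when one strand exceeds ten times the other strictly,
with (0, 0) unbiased.

## Differential expression

**Normalization.** RLE size factors: per library, the median over genes
positive in every library of count / across-library geometric mean, then
rescaled so the factors' geometric mean is 1. Genes with any zero are
excluded from the reference because their geometric mean is zero.

**Exact Poisson test.** For counts (c₁, c₂) with effective sizes (s₁, s₂),
conditional on n = c₁+c₂ the first count is binomial(n, s₁/(s₁+s₂)) under
the null; the two-sided p sums the probabilities of all outcomes with
probability ≤ that of the observed one (minimum-likelihood ordering, the
exact-test convention; doubled-tail is available as an option). p = 1 when
n = 0, and the test is invariant under rescaling both sizes.

**Common dispersion (qCML).** From the two control replicates: counts are
scaled to the geometric-mean library size (deterministic proportional
scaling with rounding — the stochastic-rounding-free stand-in for full
quantile adjustment, an acknowledged approximation), and the NB conditional
likelihood given per-gene totals is maximized over φ ∈ [0, 10] by bounded
1-D search, with the φ = 0 Poisson limit (binomial(z, 1/2)) checked
explicitly so the boundary is attainable. The conditional law for two
equal-size libraries, P(y₁ | z) ∝ C(y₁+r−1, y₁)·C(y₂+r−1, y₂) with r = 1/φ,
is free of the gene means, which is what makes a common dispersion estimable
without replicates per condition.

**Exact NB test.** Same conditional construction with the estimated φ; φ = 0
delegates to the Poisson test exactly (an NB with zero dispersion *is*
Poisson, and conditioning Poisson pairs on their total gives the
size-proportional binomial with no adjustment needed), which realizes the
reduction property bit-for-bit including unequal sizes.

**Calling.** Each time window is compared to the control of its own
processing batch (batch 1: windows 1–3 and control 1; batch 2: windows 4–5
and control 2); a window without a batch control is an error.
Benjamini–Hochberg adjustment is applied within each comparison — the
design compares each sample to its own control, so each comparison is its
own family. Significance requires padj < 0.001 (strict) **and** |log₂ FC| >
0.7 jointly; fold changes use pseudocount 0.5 on normalized counts so zero
counts stay finite. The significant set is the union over time points.

## Temporal classification

Significant genes' per-window log₂ fold changes are z-scored row-wise
(sample sd, ddof 1); constant rows are excluded with a logged list, never
NaN-filled. `kmeans_run` is Lloyd's algorithm with Euclidean distance,
centers initialized at k distinct data points from the given seed, tolerance
1e-6 on center movement, at most 300 iterations, emptied clusters re-seeded
at the farthest point. Consensus: 100 runs with seeds derived from the
master seed; the gene × gene co-clustering frequency matrix is thresholded
at 0.8 and the connected components of the resulting graph are the classes;
components below 2 genes are "unstable". Classes are numbered by the time of
their peak mean z-score (earliest first) — a reporting convention only.

Each consensus run takes the best of 20 random-point starts by inertia.
A single random-point start of Lloyd's algorithm places a center in every
well-separated cluster only a few percent of the time (it cannot move
centers across wide gaps), which floods the co-clustering matrix with
merge-the-nearest-pair solutions; best-of-n restarts restore the consensus
signal while keeping the initialization scheme.

## Synthetic data

The generator emulates the study design so that every stage has planted
truth: ~40 scaffolds with log-normal lengths (median ~11 kb) at 65% A/T;
genes placed as exact scaffold substrings on either strand with 1–3 nested
isoforms; a configurable fraction of *split genes* concatenating a 3'-end
region of one scaffold with a 5'-end region of another (always exactly two
scaffolds). Split genes get a 2-kb length floor with the junction ≥ 500 bp
from each end: a transcript bridging two scaffolds spans sequence on both
sides of a scaffold boundary and is by construction a long, multi-chunk
locus, and anything shorter is invisible to the 1-kb/500-bp-chunk procedure
by design. Reads are 2 × 36-bp inward-facing fragment ends (fragment length
~N(200, 20)); qualities follow a linear per-cycle decay with Gaussian noise
clamped to [2, 41]; base calls are exact — the aligner-facing tests need
placement truth, not error models. Read ids carry a parseable truth suffix
used only by oracles and tests.

Count matrices cover 5 time windows plus 2 controls in 2 batches (windows
1–3 with control 1, windows 4–5 with control 2). Per-gene baseline means are
log-normal with median 500 and log-sd 1 (mean ~820 counts/gene, matching
libraries of ~12–16 million unique counts over ~17,500 loci); library size
factors are log-normal (cv 0.2); counts are NB with mean baseline × size
factor × 2^profile and the configured dispersion (0 = Poisson). Five default
temporal prototypes encode the canonical regeneration classes — early
sustained induction, transient early induction, late induction, repression
peaking mid-course with partial recovery, monotone late repression. Because
classification operates on z-scored profiles, the prototypes are chosen to
be distinct as *shapes* (minimum pairwise z-space distance ~1.7); profiles
differing only in amplitude would collapse after z-scoring and the planted
"classes" would be meaningless. 6.5% of genes are assigned a class by
default; the rest are null.

The stand-in ortholog proteins are frame-0 translations of each gene's
longest isoform with point substitutions at a configurable per-residue rate;
for split genes the protein spans the junction by construction, mirroring
the role of cross-species homology in junction support. `naive_protein_hits`
produces full-length transcript-vs-protein alignment records by direct
translated comparison — a blastx stand-in for synthetic data only.

What the synthetic data does **not** emulate: sequencing errors in bases,
genomic repeats and paralogy (scaffolds are i.i.d. random sequence, so
multi-mapping is rare and join precision on synthetic data is an easier
problem than on a repeat-rich genome), pooling variance across animals
(absorbed into the NB dispersion knob rather than modelled), and spliced
alignment. Passing tests therefore demonstrate correctness of the
procedures, not their robustness to repeat-driven mismapping.

## Problem sizes and numerical choices

The test suite and acceptance script use the sizes at which each property is
sharp but cheap: 10,000 random reads for filter/oracle agreement, 1,000
random length sets for N50, 200 genes with 10% splits for join recovery,
10,000 null genes for p-value calibration, 5,000 genes for dispersion
recovery, 500 genes for class recovery, 1,000 random inputs for the NB→
Poisson reduction. Exact-test p-values compare outcome log-probabilities
with a relative tie tolerance of 1e-9 so float noise cannot split exact
ties. The qCML search uses `xatol` 1e-6 on φ. The consensus support
threshold is applied as ≥ (at least 80 of 100 runs).

## Known limitations

- The qCML quantile adjustment is deterministic proportional scaling, not
  the full quantile-matching construction; for library sizes within ~2× of
  each other the difference is negligible (the dispersion-recovery tests run
  with cv 0.2 size factors), but strongly unequal sizes would bias φ̂.
- Exact conditional tests are discrete and therefore mildly conservative at
  low counts; null calibration holds at the study's count depth (hundreds
  per gene) and degrades for shallow libraries.
- Join junctions are located only to within half a chunk (~250 bp); the
  protein-support margin is interpreted relative to that estimate, not the
  true junction.
- `reciprocal_best_hits` treats score ties as ambiguity rather than
  attempting tie-breaking by coverage or e-value.
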