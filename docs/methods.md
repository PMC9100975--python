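# Methods

This note documents the models and procedures `sylvamir` implements, the
defaults it ships, the design decisions that were genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Read QC

Reads are 1×50 bp single-end: insert (a small RNA of 18–30 nt) followed
by the 3′ sequencing adapter and, for short inserts, downstream bases.

**Adapter inference.** Every 10-mer occurring in a read votes once (at
its leftmost offset). Among 10-mers supported by ≥ 25 % of reads, the one
with the smallest median start offset is taken: because insert lengths
vary, all 10-mers of the adapter are near-universally supported, and the
adapter's own 5′ end is the leftmost of that chained family. A
user-supplied adapter bypasses inference. Trimming cuts at the leftmost
occurrence of the adapter's first 10 nt, allowing one mismatch in the
seed.

**Six-way filter.** Categories are tested in a fixed order — low quality
(> 30 % of bases below Q20), high N (> 10 % N), 5′ adapter (read starts
with the last 10 nt of the 3′ adapter's reverse complement, or a
configured 5′ string, ≤ 1 mismatch), no 3′ adapter, poly-nt (one base
≥ 80 % of the trimmed insert), trimmed length outside [18, 30] — so each
read is counted exactly once and the report satisfies the integer
identity `raw = clean + Σ categories` on every input. The fixed order
means only the *attribution* of multiply-defective reads depends on
order; the clean set does not. Thresholds are configurable
(`FilterParams`); the poly threshold of 80 % and the 5′-adapter test are
conventions chosen here because standard pipelines name these categories
without defining them.

## Contaminant removal

A read is removed iff it aligns end-to-end to any window of any
rRNA/tRNA/organelle reference, either strand, with ≤ 1 substitution.
Matching is ungapped Hamming — the convention for 18–30 nt reads against
contaminant databases — implemented exactly via pigeonhole
seed-and-verify (a read with ≤ m mismatches contains one of m+1
mismatch-free seed segments), so it can be property-tested against a
brute-force all-windows scan. An empty reference set is an error rather
than a silent pass-through.

## miRNA annotation

Mapping is exhaustive seed-and-verify on the genome (both strands,
default 0 mismatches, reads with > 20 placements discarded and counted);
multi-mapped reads contribute full counts to every stack they fall in,
because family members share sequences and only aggregate expression is
identifiable from short reads. Same-strand placements overlapping or
abutting within 2 nt merge into a stack whose representative is the most
abundant sequence (ties: lexicographically smallest). Each stack is
extended ±150 nt into a candidate precursor window (minus-strand windows
reverse-complemented so the mature reads in sense).

**Duplex evaluation.** Secondary structure is assessed by aligning the
mature against the reverse complement of the opposite arm — located by
local alignment on each side of the mature, best side kept — rather than
by thermodynamic folding; every acceptance criterion is a statement
about that duplex alignment. In reverse-complement space a G:U wobble
appears as (G, A) or (T, C) and counts as *paired*. Counted against the
criteria:

- substitutions (aligned, non-paired columns),
- gap positions (asymmetric bulges / internal loops) — these also count
  as "loop-region" mismatches,
- mature positions not covered by the arm alignment.

A locus passes iff total mismatches ≤ 5, loop-region mismatches ≤ 3,
mature length ∈ [20, 24], no internal loop exceeds 5 nt on one strand,
the arm pairs at all (otherwise "large loop"), and the star — the arm
interval shifted +2 nt, giving the canonical 2-nt 3′ overhangs — lies
inside the window. The trimmed precursor spans mature↔star plus ≤ 15 nt
flanks, capped at 300 nt. Two readings in the published criteria are
ambiguous and were fixed here as design choices: "loop region"
mismatches are read as bulge/internal-loop positions within the duplex
(the terminal loop is by definition outside the duplex), and "large
loop" is given the numeric bound of 5 nt (configurable constant).

Counting uncovered mature positions as mismatches makes rejection of
non-hairpin windows intrinsic: a random 321-nt window rarely pairs more
than ~10 of 21 mature positions, far beyond the 5-mismatch budget. Note
that alignment-based pairing with wobbles is more permissive than free-
energy folding; on a real genome (rich in inverted repeats and
siRNA-producing loci) these criteria alone would admit candidates a
folding-based pipeline would reject. That is the main caveat when
extrapolating the synthetic recovery results to real data.

**Low-expression filter and naming.** Loci below 10 reads in *every*
sample are removed. Overlapping same-strand loci deduplicate to the
higher-count one. A locus is *known* if some reference mature matches
with ≤ 2 substitutions at the best ungapped offset and length difference
≤ 2 (family parsed from the reference id); novel loci are named miRN1,
miRN2, … in genomic order.

## Expression and differential expression

RPTM (reads per ten million) is `count / total mapped reads × 10⁷`,
used for reporting expression levels. The test statistic instead uses
median-of-ratios size factors: for loci with nonzero counts in all
samples, factor_j = median_i(count_ij / geometric-mean_i); an explicit
`pseudo_reference=True` fallback (+0.5) exists for matrices with no
all-nonzero locus.

The DE test is a defined NB Wald test (deliberately *not* a bit-level
re-implementation of any published package; it is validated by
calibration properties instead):

- normalised counts `q_ij = count_ij / s_j`; per-group means
  `μ_X, μ_P`; `log₂FC = log₂(μ_X/μ_P)`;
- per-locus method-of-moments dispersion from within-group variances of
  normalised counts, floored at 1e-8, then shrunk 50 % toward a fitted
  `a₀ + a₁/μ` mean–dispersion trend — at n = 3 per group the raw MoM
  estimate is too noisy to use alone, and the fixed blend avoids
  importing empirical-Bayes machinery;
- delta-method standard error
  `Var(μ̂_g) = n_g⁻² Σ_j (μ_g/s_j + α μ_g²)`, two-sided normal p;
- loci with an all-zero group get a signed-infinity log₂FC sentinel and
  a p-value from a +0.5 pseudo-count path, flagged;
- all-zero loci are excluded before testing and from the BH family;
  BH adjustment across the tested loci; `up ⇔ log₂FC > 1.5 ∧ padj <
  0.05` with both inequalities strict (so a locus at exactly the
  threshold is not significant).

Calibration, measured by the acceptance script and seed-pinned tests: on
a 2000-locus global-null simulation (n = 3/group, dispersion 0.05) the
BH-rejection fraction is ≈ 0.001 ≤ 0.05; power for loci planted at
FC = 8 (mean 200) among nulls is 1.0. One caveat discovered while
validating: if *every* locus carries the same fold change, median-of-
ratios absorbs it and power collapses — the classic failure mode of
global-shift designs, which is why the calibration plants DE loci as a
minority.

## Degradome target calling

AGO slicing leaves the downstream fragment's 5′ end opposite miRNA
positions 10–11; degradome tags therefore pile up at the cleavage
position. Tags are placed by exact match of their first 20 nt on the
transcript sense strand (multi-placed tags count everywhere). Calling is
degradome-led: only tag-supported positions are tested, with the site
window on the transcript chosen so that miRNA position 10 lies opposite
the tag position.

Complementarity uses Allen-style penalties per miRNA position —
mismatch 1.0, G:U 0.5, gap 1.0, doubled at positions 2–13, best
ungapped-or-single-gap alignment, cutoff 7.0. Categories follow the
standard degradome tiers computed from the transcript's tag profile:
4 if the site has a single tag; 0 unique maximum; 1 tied maximum;
2 above the mean over tag-bearing positions; 3 otherwise. "Average" is
the mean over *nonzero* positions — including zeros would make
category 2 nearly universal on long transcripts. The default report
keeps categories 0–2 (3–4 are conventionally unreliable).

The p-value is a permutation null: the miRNA sequence is shuffled R
times (default 1000; the pipeline uses a configurable smaller R) and a
shuffle counts as a hit if it achieves any site on the same transcript
with category ≤ observed and score ≤ observed;
`p = (1 + hits)/(R + 1)`. This conditions on the observed tag profile
and tests only sequence complementarity; it is not comparable to
p-values produced by other degradome tools' internal models.

## Enrichment and family sets

Over-representation only (upper tail of Hypergeom(N, K, n)), BH across
terms; the universe is all genes with ≥ 1 annotation in the tested
ontology, matching the rich-factor denominator (`rich factor = k/K`,
target genes in the term over annotated genes in the term). Family
utilities return the exact Venn partition: a family belongs to the cell
of those groups in which it is present in *all* member species;
families not complete in any group land in the empty cell, so cell
sizes sum to the family union.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions the tests run under:
two tissue groups × 3 replicates, 1×50 bp reads, a 21-nt kit adapter,
20,000 reads/sample, 12 planted hairpins + 25 decoys on a 60 kb i.i.d.
uniform genome, NB counts (dispersion 0.05, lognormal base means around
200) with planted fold changes {1, 8, 0.125, 4, 0.25, 1}, discard-
category fractions of a few per mil to a few per cent (no-3′-adapter the
largest, mirroring real library breakdowns), 5 % contaminant reads, and
a pooled degradome (15,000 tags over 40 transcripts, signal fraction 0.8
at 8 planted cleavage sites).

Planted hairpins are mature + 8–40 nt loop + reverse-complement arm with
1–4 substitutions; validity is asserted *in situ* with the package's own
duplex evaluator. The 1-edit minimum ensures the star arm is never an
exact reverse complement — a perfectly palindromic hairpin is
legitimately annotatable from either arm/strand and would be reported
twice. Decoys are rejection-sampled to *fail* the evaluator, which is
what makes precision = 1.0 a meaningful oracle: on uniform background
roughly a quarter of random windows can satisfy the alignment-based
duplex criteria by wobble-rich chance pairing, so "decoy" is defined by
the criteria, not by randomness alone. Defect reads are mutually
exclusive per category and verified at generation time to land in their
intended bucket, making category counts exactly recoverable. Planted and
decoy read counts are emitted exactly (no multinomial resampling), so a
planted count of c yields exactly c clean mapped reads. Filler reads
with random inserts emulate the unmapped fraction of a real library.
Degradome tags are emitted already adapter-trimmed; adapter handling is
exercised on the small-RNA side.

Not emulated: base-call error models, isomiR heterogeneity, ligation
bias, genomic repeat structure, siRNA-producing loci, multi-chromosome
genomes. Passing recovery tests therefore demonstrates correctness of
the pipeline's logic under its stated model, not annotation specificity
on real genomes (see the folding caveat above).

Determinism: one integer seed drives everything; per-stage substreams
use fixed offsets (`default_rng([seed, stage, index])`), so identical
config + seed reproduces byte-identical FASTA/FASTQ/TSV artifacts and
manifest digests.

## Numerical and degenerate-input choices

- Duplex aligner scores: match +2, wobble +1, mismatch −1.5, gap open
  −4, extend −1.5; arm detection requires a local score ≥ 8 (below
  that, "no complementary arm"). These affect only *which* duplex
  alignment is evaluated; the accept/reject thresholds are the criteria
  themselves.
- Ties in stack representatives and known-miRNA matches break
  lexicographically; loci dedup keeps the higher total count.
- Empty inputs are first-class: 0 loci / 0 reads produce empty but
  well-formed tables end-to-end; an empty contaminant reference or
  transcriptome is an error (never a silent pass-through).
- RPTM requires positive per-sample totals; size factors require an
  all-nonzero locus unless the pseudo-reference flag is set.
- Permutation p-values are bounded below by 1/(R+1); R is the
  sensitivity/runtime dial.
- Problem sizes in tests and the acceptance script (60 kb genome, 120 k
  reads, 2000-locus null, R = 100) were chosen so the whole suite runs
  in well under a minute-scale budget while keeping every Monte-Carlo
  margin comfortable.

## Package shape

The package is organised as a staged pipeline (the analysis is a chain
of heterogeneous transformations, not a single model fit); the one
stage that is a statistical model — NB differential expression — is
additionally exposed statsmodels-style as
`NBDifferentialExpression(...).fit() → DEResults.summary()`.
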