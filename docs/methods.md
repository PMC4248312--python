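# Methods

## The analysis in brief

The unit of analysis is the *occupied segment* (OS): per-cell-type
ChIP-seq peak calls are blacklist-filtered (a peak is dropped whole if
it overlaps any blacklist interval by ≥ 1 bp), concatenated, and merged
wherever segments share at least one base. Coordinates are BED
conventions throughout: 0-based, half-open. Touching intervals
(`a.end == b.start`) are *not* merged — overlap means ≥ 1 shared base —
so adjacent but distinct binding events stay distinct. Membership of a
merged OS is defined from the original peak calls (a cell type is a
member iff one of its peaks overlaps the merged interval), never from
signal thresholds.

Signal per OS is the mean per-base coverage from each cell type's
bedGraph track, scaled per track to counts-per-million of that track's
total signal (value × length summed over records). This stands in for
"read counts normalized across experiments"; re-counting reads is out
of scope, and CPM scaling removes sequencing-depth differences while
preserving relative signal. Quantile normalization then forces every
column onto the across-column mean reference distribution (ties receive
the mean of their tied ranks' reference values, via interpolation at
the average rank).

## Clustering

Rows are clustered by Euclidean k-means (k = 16 by default, k-means++
initialization, 10 restarts, best inertia, fixed seed) on the
quantile-normalized matrix. Whether distance should instead be
correlation-based is genuinely open; Euclidean on quantile-normalized
values was chosen because quantile normalization already equalizes the
marginals, making Euclidean distances comparable across columns. A
Gaussian-mixture variant with the same interface is provided for
model-based clustering.

Cell-type relatedness uses the *raw* (CPM, not quantile-normalized)
columns: pairwise Pearson r, dissimilarity d = 1 − r ∈ [0, 2],
agglomerative clustering with average linkage (UPGMA). Average linkage
is the standard choice for correlation dissimilarities and is monotone,
so dendrogram heights never invert. Heatmap preparation winsorizes each
column at its 0.5 % / 99.5 % quantiles; quantiles are taken as order
statistics (`lower`/`higher` methods) so that clipping is idempotent.

## Motif scanning and central enrichment

PWMs are read from JASPAR count or MEME-minimal text; counts become
probabilities with a per-cell pseudocount (zero probabilities without a
pseudocount are rejected, since log-odds would be −∞). Scores are
log₂(p/background) in bits. Scanning follows the FIMO design: the
per-position scores are discretized onto a shared integer grid (grid
step = total score range / 1000), the null distribution of a random
background word's total score is computed exactly by convolving the
per-position score distributions, and the threshold is the smallest
*achievable* integer score whose tail probability is ≤ p (default
10⁻³). The scanner decides acceptance on the same integer grid, so
threshold decisions are exact with respect to the grid; the
reverse-complement matrix shares the grid, making both strands
consistent. Positions containing N (or soft-masked lowercase, when
honored) are skipped; windows truncated at chromosome edges are scanned
over the available span and flagged. Repeat masking by external tools
is replaced by honoring lowercase/N masking in the input FASTA.

A match's position is the midpoint of the matched word (symmetric under
strand; half-integral for even widths). Central enrichment counts
matches with |offset| ≤ 50 bp of the OS midpoint (a) versus the rest of
the 1-kb window (b), each normalized by the same counts on
equally-sized uniform-random non-blacklisted segments (c, d):
log₂[(a/c)/(b/d)]. When any of the four means is zero, a small epsilon
(1/(n_random × window)) is added to all four and the result is flagged
— never silently. Random segments are uniform over the non-blacklisted
genome, the same number as the OS set by default; GC-matching is not
attempted.

## Response partition and switch classes

The occupancy universe for the GATA1-response analysis is the merged
union of TAL1-G1E, TAL1-ER4 and GATA1-ER4 peaks (so GATA1-only segments
are representable). Each segment maps to three booleans (≥ 1 bp overlap
with each peak set) and then to a group by a fixed truth table:
dissociation (TAL1 in G1E only: a indirect, b direct), retention (both:
c indirect, d direct), recruitment (ER4 only: e indirect, f direct),
where "direct" means GATA1 co-occupies the segment in ER4 cells;
(F,F,T) is gata1_only. GATA switch sites are segments with GATA2 in
G1E and GATA1 in ER4; GATA2 without GATA1 replacement is a loss site.
The minimum-overlap criterion is configurable but defaults to 1 bp,
since "overlap" is otherwise unquantified.

## Target assignment

EPU assignment: an OS belongs to the EPU containing its midpoint (an OS
straddling an EPU boundary is otherwise ambiguous); its targets are all
genes with a TSS inside that EPU. OSs outside every EPU, or in
gene-free EPUs, keep empty target lists and are flagged rather than
dropped. Nearest-TSS assignment measures unsigned distance from the OS
midpoint, intra-chromosomal only; exact ties go to the
lexicographically smaller gene id and are flagged. Genes with multiple
annotated TSSs contribute one record per TSS; the nearest record wins.

## Expression response and the permutation null

A gene is differentially expressed iff log₂ FPKM > 3 in *both*
conditions (strictly) and q ≤ 0.05; induced/repressed by direction, and
a DE call with exactly equal FPKMs is demoted to not_DE and flagged.
Per-OS percentages use *all* assigned targets as denominator by default
(a `denominator="de"` mode restricts to DE targets); the all-targets
reading keeps OSs with no DE targets informative. OSs with zero
targets are excluded and counted. Group summaries are unweighted means
over OSs.

The null shuffles the *group designation* across OSs (target lists stay
attached to their OSs, group sizes are preserved exactly) and
recomputes the group means; 1000 permutations by default. Per group and
direction the pipeline reports the pseudo-mean distribution, its mean
(the background line), the distribution of log₂(true/pseudo), and an
empirical two-sided p-value with add-one smoothing, (r + 1)/(n + 1),
where r counts pseudo-means at least as far from the pseudo-mean center
as the true mean. Zero pseudo-means are guarded by an epsilon of 0.01
percentage points, flagged. P-values are reported raw; no
multiple-testing correction across groups is applied (documented
limitation).

## Chromatin states and fates

Nine-state segmentations are consumed as labeled BED tilings (validated
contiguous and non-overlapping per chromosome). An OS takes the state
containing its midpoint; a majority-overlap mode is not the default.
States collapse to active/inactive via a per-cell-type activity map
(configuration, since emission profiles differ per trained model);
the shipped default marks states 1–4 active. Progenitor-only OSs are
categorized over an ordered three-cell-type maturation series:
active-active-active → active_all; all inactive → inactive_all;
monotone inactivation (A,A,I or A,I,I) → progression; anything else →
mixed. Including A,I,I in "progression" is an interpretation — the
series is named but the exact triple set is not fixed — and is
documented as such.

## The synthetic-data generator

The generator emulates the data regime the pipeline is designed for:
peak sets whose cross-cell-type sharing is mostly single-cell-type, a
GATA1 co-occupancy structure over the G1E/ER4 universe, motifs
concentrated at segment centers, coverage enrichment over peaks, EPU /
gene geometry, complete nine-state tilings, and expression labels
coupled to occupancy-response groups.

Defaults (the demo fixture): 2 chromosomes × 500 kb of i.i.d. sequence
at GC 0.45; 590 planting events from a sharing table dominated by
single-cell-type patterns (plus HPC7+Epro, HPC7+Meg, the four-way
erythroid pattern and an all-six pattern), 20 extra GATA1-only events;
peak width 300 ± 60 bp with ± 20 bp per-cell-type coordinate jitter.
Each event occupies an exclusive 1.2-kb slot, so planted events never
merge with each other and 1-kb scan windows of adjacent events never
overlap (center jitter is capped at ± 80 bp to preserve this). GATA1
co-occupancy probabilities given (TAL1-G1E, TAL1-ER4) occupancy are
0.37 / 0.93 / 0.76 for dissociation / retention / recruitment — chosen
to give direct:indirect odds comparable to the published group sizes.
Coverage is Poisson background (rate 1 per 10-bp bin) plus a Gaussian
bump (amplitude 20, σ = width/4) per peak; read-level detail is
irrelevant to the downstream math, which only consumes mean coverage.
Motif words are sampled column-wise from the PWM (so the scanner's
threshold behavior is exercised on non-exact matches) and written into
the sequence at central offsets (± 50 bp) with the configured central
fraction, else uniformly in the window; collisions re-draw with capped
retries. The five shipped PWMs are consensus-derived synthetic
stand-ins (GATA WGATAA, E-box CAGVTG, ETS GGAWGT, RUNX TGYGGT, KLF
GC-box), not curated database matrices. Expression coupling: each
gene's governing OS is the response-labeled event nearest its TSS
within the same EPU; induced/repressed draws use that group's
probabilities (defaults couple d/f to induction, a/b to repression,
0.1/0.1 baseline), and the emitted (log₂ FPKM pair, q) rows reproduce
the label exactly under the DE rule, with margins around the 3.0 and
0.05 thresholds so rounding cannot flip a label.

All randomness flows from one seeded generator; per-stage child seeds
are drawn once from a master stream, so identical config + seed yields
a byte-identical bundle.

What the generator does **not** emulate: raw reads, duplicate and
mappability artifacts, replicate structure, GC- or repeat-driven
coverage bias, realistic gene/EPU size distributions (EPUs here are
uniform ~23-kb blocks), and correlated noise between cell types.
Passing tests therefore demonstrate correctness of the interval
algebra, statistics and plumbing on data with planted truth — not
robustness to the artifacts of real ChIP-seq.

## Problem sizes used by the test suite and acceptance script

The suite exercises the statistics at desk scale, chosen to keep the
default run fast while leaving comfortable statistical margins:
enrichment calibration uses 500 OSs × 20 seeds over a 5-point
central-fraction grid; permutation calibration uses 50 fixture
replicates at 200 permutations with ~600 OSs and 600 genes, and the
power check 20 seeds with ≥ 150 OSs per group; the demo fixture is the
default 590-event bundle with 1000 permutations. The acceptance script
reruns the demo end to end for the requested seed.

## Known limitations

- The sharing-group map covers the named categories and routes all
  other patterns to "other"; a full 11-group enumeration is
  configuration, not code.
- Overlap-based co-occupancy is binary; signal-strength-based soft
  membership is out of scope beyond raw export.
- The permutation p-values are raw, per group/direction.
- The exact-threshold guarantee is relative to the integer score grid
  (1/1000 of the score range); two words whose real scores differ by
  less than one grid step are not distinguished.
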