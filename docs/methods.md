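# Methods

## Read-pair filtering

A pair is kept iff all five predicates hold: concordant (the aligner's
proper-pair call), same chromosome for both mates, not ambiguously mapped,
insert size within [120, 200] bp, and at most 4 mismatches in each mate.
Interpretation choices:

- *Boundary inclusivity.* "Outside the range 120–200 bp" excludes inserts
  <120 or >200; inserts of exactly 120 or 200 bp are retained.
- *Per-mate mismatches.* The cap applies to each read separately
  ("more than 4 mismatches in any read"), not to the pair sum.
- *Ambiguity.* Operationalized as mapping quality 0 (BAM) or an explicit
  flag bit (BEDPE dialect). Aligner-specific multi-hit tags (e.g. BWA XA)
  are not consulted; the criterion is configurable at the input layer.
- *Attribution order.* A pair failing several predicates is counted under
  the first failing class in the order discordant → inter-chromosomal →
  ambiguous → insert-out-of-range → excess-mismatch, making the removal
  report deterministic.

Duplicate marking and adapter trimming are upstream concerns and out of
scope; the pipeline consumes aligned records.

## Occupancy tracks

Dyad estimate: midpoint = floor((start + end)/2) of the 0-based half-open
template interval (ties round down). Track construction, with defaults
width = 40 bp, smooth_width = 20 bp, target_count = 10,000,000, span = 1 bp:

1. *Extend*: each midpoint adds 1 to every base of [m − width//2,
   m − width//2 + width), truncated at chromosome ends (no wraparound or
   reflection).
2. *Scale*: multiply by target_count / n_fragments, so every library is
   expressed on a common effective-count scale. Linear scaling is used
   (not quantile normalization); the choice is exposed so its sensitivity
   can be tested.
3. *Smooth*: centered moving average of smooth_width bp; for even width w
   the window at i is [i − w/2, i + w/2 − 1], and edge windows shrink to
   the available positions.

Extend→scale→smooth is fixed as the order of operations; scaling commutes
with smoothing, extension does not. Consequences used as invariants: the
unsmoothed track sums to width × target_count when no window is truncated;
duplicating every fragment leaves the normalized track unchanged; shifting
all midpoints shifts the track exactly.

The sum-conservation invariant is exact in exact arithmetic; tests allow
~1e-9 relative float tolerance from the cumulative-sum implementation.

## Differential promoter statistics

All gene-relative coordinates are oriented by strand with the +1 nucleosome
dyad at 0 and negative positions upstream (the NDR side). The per-gene
statistic is the mean of (test − reference) occupancy over positions
−150..−50 inclusive (101 positions); index 0 of any window vector is the
most upstream position. Genes whose window overruns a chromosome end are
excluded and flagged, before ranking, per comparison.

- *Blacklist.* Genes not achieving *more than* +0.6 occupancy difference
  (strict inequality, so a gene exactly at 0.6 is removed) are excluded
  from heatmaps. The aggregator is the same −150..−50 window mean — the
  only statistic the procedure defines — with the column configurable.
  Blacklists from several comparisons merge as a plain set union.
- *Ordering.* Decreasing statistic, ties broken by lexicographic gene id
  (stable), so orderings reproduce across platforms; an ordering computed
  on one comparison can be applied to any other comparison's matrix.
- *Top-N.* Default N = 500. When a baseline comparison is designated
  (a rescue-strain control), its per-gene statistic is subtracted before
  ranking.
- Statistics are computed on the linear normalized scale; log2 is reserved
  for heatmap display (the display-only transform), with pseudocount 1.0
  normalized unit to handle zero-occupancy positions.

Note that the +0.6 threshold is an absolute occupancy difference: its
effect depends on the normalization scale and genome size (the effective
per-bp occupancy of a 10⁷-count library is genome-length dependent), which
is why the threshold, like every printed parameter, is configurable.

## Anchored matrices and profiles

Heatmap matrices span ±500 bp around the +1 dyad by default (flank
configurable; the original display extent is not recoverable from the
source text). Row g, column j holds the signal at dyad + j (plus strand)
or dyad − j (minus strand). Heatmap assembly is pure row selection —
ordering then blacklist removal — and never alters surviving values; the
numeric TSV is the testable artifact and the PNG is decorative. Average
profiles are column-wise means of the anchored matrix over a gene set and
therefore equal the matrix row-mean exactly when taken over all genes.

## Synthetic data generator

The generator emulates the *statistical* structure of an MNase-seq
experiment at the level of aligned fragment coordinates:

- Genome: 16 chromosomes × 400 kb (6.4 Mb — yeast-like chromosome count at
  half scale), random sequence; genes in disjoint 2-kb slots, dyads ≥1 kb
  from chromosome ends, alternating strands.
- Per gene: 4 phased nucleosome sources at +1 + k·165 bp (strand-oriented,
  weight 1.0 each, Gaussian dyad jitter sd 10 bp) and one NDR source
  spread uniformly over −160..−20 bp (weight 0.5 at baseline). In the
  perturbed condition the NDR weight of a seed-chosen 1/6 of genes (500 of
  3000) rises by 2.0, i.e. to 5× baseline. The baseline weight 0.5 puts
  the per-bp NDR trough at roughly a quarter of the +1 peak, comparable to
  promoter NDR depth in yeast nucleosome maps; a much deeper trough would
  leave too few NDR fragments for any method to rank reliably at desk
  scale.
- A uniform background source contributes 10% of clean fragments so tracks
  are nonzero between genes; the background model of real intergenic
  signal is a modeling choice, not a measured property.
- Clean fragment lengths ~ round(Normal(150, 15)) truncated to [121, 199],
  so the 120/200 filter boundaries are probed only by deliberately
  injected contaminants and filter tests are exact.
- Contaminants (defaults: discordant 1%, inter-chromosomal 0.5%, short
  insert 1%, long insert 1%, high-mismatch 0.5%) are each constructed to
  fail exactly one predicate (first-failing attribution makes this
  well-defined), with ground-truth labels. Mismatches are carried as
  integer per-mate counts (0 for clean, ≥5 for the high-mismatch class);
  no sequence-level mutation is simulated because the filter consumes only
  the count. No ambiguously-mapped pairs are generated; that predicate is
  exercised by constructed fixtures.
- Class counts are multinomial draws, so empirical rates are binomially
  consistent with the configured rates.
- Everything is deterministic given the seed (default 101); the two
  conditions and the affected-gene choice use independent substreams, so
  the affected set is identical across conditions.

What passing tests on this generator do *not* show: robustness to sequence
composition bias (GC, MNase preference), digestion-level variation,
fragment-length/rotational coupling, or +1 annotation error in real data —
none of which are modeled.

## Problem sizes and numerical choices

The reference recovery study (3000 genes, 500 perturbed, 2×10⁵ pairs per
sample) runs the whole pipeline in well under a minute and is the scale at
which recovery (top-500 precision ≥0.9) and the zero-effect null control
(hypergeometric-consistent top-500 overlap) are asserted; unit tests use a
40-gene study. Determinism of the full pipeline is checked byte-for-byte
on TSV outputs (PNGs and the provenance file, which embeds paths, are
excluded). Degenerate inputs: an empty fragment list yields a zero track
with a warning rather than a division by zero; an empty gene set for a
profile is an error; an all-blacklisted heatmap is an empty matrix with a
warning.

## Known limitations

- The +0.6 blacklist rule applied literally to a genome-wide gene set is
  scale-sensitive (see above); the direction/aggregator ambiguity of the
  published rule is resolved as "window-mean gain ≤ threshold" and left
  configurable rather than guessed further.
- Per-gene exclusion is applied per comparison *before* ordering; the
  alternative (after) is expressible through the API.
- bigWig round trips are float32-exact only; bedGraph output uses
  shortest-round-trip float formatting and is exact.
- The generator emits aligned records, not raw reads: trimming and mapping
  are deliberately outside the artifact.
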