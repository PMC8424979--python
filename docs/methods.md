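# Methods

This note records the models implemented in `paleowgd`, the choices made
where the underlying procedures are conventionally under-specified, and
what the synthetic-data tests do and do not demonstrate.

## Collinear block detection

Homologous gene pairs (from an E-value-filtered all-vs-all protein search;
cutoff 1e-5, optional best-5-per-query thinning) are placed on the
rank×rank plane of each chromosome pair, where a gene's rank is its
0-based position among the genes of its chromosome ordered by start
coordinate. A collinear block is a chain of pairs whose ranks increase
strictly on both axes (or increase on one and decrease on the other, for
an inverted block) with at most `max_gap` intervening genes — the rank
difference minus one — between consecutive members on *each* axis. The
default `max_gap` of 50 genes follows the standard setting for plant
paleopolyploidy scans; `min_pairs` defaults to 4, the shortest block
length commonly reported.

The chaining objective is the number of pairs (unit score per pair),
found by an O(n²) dynamic program; the best chain is extracted, its hits
removed, and the scan repeated until no chain reaches `min_pairs`. Ties
are broken by smaller total gap, then lexicographically by first gene id,
so results are deterministic. In self-comparisons hits are canonicalized
(lower chromosome/rank first), which removes the trivial diagonal and
reports each paralogous block once. No statistical significance filter is
applied beyond the length threshold; a unit-score greedy scan is used
because downstream statistics consume pair counts, not alignment scores.
The extractor is validated against exhaustive chain enumeration on random
instances of ≤ 15 hits.

## Ks and Ka (NG86)

Coding sequences are aligned at the protein level (global alignment,
match +1, mismatch −1, gap open −10, gap extend −0.5 — configurable),
back-threaded to codons, and gap columns dropped. Synonymous site counts
follow NG86: each codon position contributes the fraction of its three
possible changes that preserve the amino acid (changes to stop codons
count as nonsynonymous), averaged over the two sequences. Codons
differing at 2–3 positions are resolved by averaging the synonymous /
nonsynonymous step counts over all minimal mutational pathways, weighted
uniformly, with pathways through stop codons excluded (if every pathway
is blocked — impossible for sense-to-sense pairs under the standard
code — all pathways are used). The production implementation computes
pathway averages by a dynamic program over subsets of differing
positions; the test suite checks it against explicit permutation
enumeration for all sense-codon pairs.

Proportions are corrected for multiple hits with the one-parameter
(Jukes–Cantor) formula, `K = -(3/4) ln(1 - (4/3) p)`. A proportion at or
above 3/4 is reported as a saturation marker, never an exception, so
block annotation continues; a block's Ks is the median over its valid
pairs, and blocks with more than half their pairs excluded are flagged
and never event-labeled. NG86 is implemented rather than the full YN00
model (no transition/transversion bias, no codon-frequency weighting):
it is the stated estimator of the workflow being reproduced, and its
pathway arithmetic admits an exact enumeration oracle.

## Event windows and classification

Event assignment replaces by-eye dotplot rectangles with explicit Ks
windows. When windows are not supplied, a 1-D Gaussian mixture is fitted
to the *logarithms* of block median Ks — event-related Ks scatter is
close to log-normal — and each component yields a window spanning its
mean ± 3 sd (log scale, back-transformed), truncated where neighbouring
windows meet at the mixture's equal-posterior boundary. Log-space fitting
with ±3 sd was adopted after linear ±2 sd windows were found to drop a
noticeable fraction of genuine event blocks in the long right tail, which
in turn starved the second sibling column of the homology table.
Components whose means land within 0.1 Ks of each other are treated as
collapsed (single window, warning). Blocks whose median falls in no
window stay unassigned and are excluded from all downstream statistics.

## Ortholog depth and ploidy

The reference genome is tiled into windows of 100 genes (configurable;
chosen to match the scale of regional homology statements without
over-segmenting short chromosomes). Each orthologous block contributes
its reference-side rank interval; intervals from the same target
chromosome that do not overlap each other are first merged into chains
(fragments of one broken run), while intervals that stack over the same
reference region remain separate layers. A window's depth is the number
of layers overlapping it, and the ploidy call is the modal depth over
nonzero windows with its supporting fraction. Depth 2 against an
unduplicated post-hexaploidy reference is reported as one extra
tetraploidization.

## The homology table

One row per reference gene in genome order; the reference contributes
its own column plus two hexaploidy-paralog columns, and every other
species contributes, per reference column, one column per unit of
post-hexaploidy multiplicity (12 columns for the diploid + diploid +
tetraploid trio). A dot marks a missing collinear gene (lost or
translocated). Filling is driven by labeled blocks only:

- Paralogous and co-orthologous *regions* are recovered by clustering
  directed block footprints: entries join a cluster when their partner
  footprints overlap, or when they look like fragments of one broken
  chain (same partner chromosome, essentially disjoint reference
  intervals); within each reference segment the largest clusters define
  the columns and surplus clusters are logged and dropped.
- Clusters are mapped to columns by the permutation that minimizes
  collisions with genes already placed from neighbouring segments. This
  lets the three hexaploid subgenomes interleave Latin-square-style —
  a paralog sits in column p1 of one row group and p2 of another —
  without violating the rule that a target gene occupies at most one
  cell per column.
- Cell conflicts are resolved deterministically: the candidate from the
  longer block wins; remaining ties keep the earlier (longer-block-first)
  placement. Conflicts are counted and reported.
- The tetraploid's two sibling columns per slot are phased by the same
  footprint clustering; the tetraploid's own WGD-paralog blocks are used
  as a diagnostic (partners should land in sibling cells of one row, not
  in one column), logged when violated. When only one sibling region
  survives in a segment there is no evidence which sibling it is; it is
  assigned to the first column, a known source of mild asymmetry at
  small block sizes.

Building the table with the second diploid as reference recovers
tetraploid genes whose first-reference anchor was lost, which is why the
pipeline builds both when configured.

## Fractionation statistics

Loss rates are dot fractions per reference chromosome and target column,
plus a both-siblings-missing rate per sibling pair; pooled over
chromosomes they are exact complements of the column retention
statistics. Runs of consecutive dots are counted within chromosomes
only; runs longer than `l_max` (default 15, following the observation
that most deletion cases remove no more than 15 consecutive genes) are
tallied separately as presumed segmental losses, with their gene count
preserved so the accounting identity Σ l·count(l) + excluded = total
dots always holds.

The spectrum is fitted by least squares on the counts scale (a
frequencies switch exists) to `N·p·(1-p)^(l-1)` with N fixed at the
observed run total and p free. Fit quality is the coefficient of
determination. Because the procedure this reproduces names an F test
without a form, the lack-of-fit statistic here is explicit: the residual
mean square over `l_max - 2` degrees of freedom divided by the mean
multinomial sampling variance expected under the fitted model, with the
upper tail of the F distribution as the P value (large P accepts the
geometric shape); a chi-square goodness of fit is emitted alongside as a
cross-check. A spectrum with a single occupied length is reported as the
degenerate exact fit p = 1.

## Ks peaks, rate correction, dating

Event-related Ks values (selected by block label, so windows do not
truncate the fit) are density-estimated with a Gaussian kernel (Scott's
rule bandwidth by default) over a wide range, and a single Gaussian is
least-squares fitted to the density curve; its mean, sd and R² are
reported. Different lineages accumulate synonymous substitutions at
different rates, so the shared-event peak sits at a different Ks in each
genome. The slowest genome is the reference; each lineage's factor is
λ = μ_lineage/μ_reference, within-genome Ks divide by λ, and cross-genome
Ks divide by the arithmetic mean of the two factors — a Ks between two
lineages accrues along both branches, and the mean-factor divisor is
isolated in one function so a geometric-mean alternative can be swapped
in. Event ages follow by proportionality: age bounds = (adjusted event
peak / adjusted calibration peak) × calibration interval, 115–130 Mya by
default for the shared hexaploidization. A peak ratio above 1.5 triggers
a warning rather than an error.

## The synthetic genome generator

`synthetic_data.simulate_history` emulates the three-genome study design:
an ancestral genome of random coding genes (7 chromosomes, 2,000 genes,
300 codons by default) is tripled by the shared hexaploidization; two
speciations split lineages V, T and A; lineage A doubles again; each
polyploidy may be followed by fractionation that deletes geometric-length
runs of consecutive surviving genes, per subgenome copy-set and per
chromosome, until a retention target is met. By default the hexaploidy
itself carries no loss (retention 1.0) and the tetraploidy retains 0.35
per subgenome with extension parameter 0.4, so the tetraploid genome
holds ≈ ancestral × 3 × 2 × 0.35 genes. Two percent of surviving genes
are translocated to random positions (exercising the dot-equals-loss-or-
translocation semantics), and hit tables are emitted from truth homology
with 2% dropout and 2% spurious pairs rather than by running a search
tool.

Sequence divergence is simulated on the fixed gene topology. Requested
per-comparison Ks peaks (defaults derived from published peak positions
of the grape/cacao-like trio and per-lineage clock multipliers 1.0 /
1.23 / 1.50) need not be additive on a tree — real lineage-rate variation
is not — so the generator projects them onto the closest non-negative
edge lengths by least squares. Substitutions are applied as events (with
replacement, weighted by per-codon synonymous or nonsynonymous site
counts; stop codons never created; Ka/Ks ratio 0.1), so multiple hits and
back-mutations arise naturally and distances compose across consecutive
branches. Per-family rate factors are log-normal with log-sd 0.25,
producing the unimodal event peaks seen in real Ks distributions.

Two estimator facts shape the truth tables. First, NG86 with the
one-parameter correction is not a consistent estimator of the
substitution-event count at high divergence under any homogeneous codon
process (two-fold degenerate sites saturate differently than the
correction assumes), so the generator simulates its own forward bias
curve on a fixed internal stream and maps the measured-scale targets back
to process budgets — the targets are what the estimator should *report*,
matching how peak positions are stated in the literature. Second,
near saturation the estimator's sampling noise is large and right-skewed
and visibly shifts the fitted density peak; the truth therefore records
(a) `event_ks_tree`, the additive path sums; (b) `event_ks`, the expected
value of the estimator measured inside the generator; and (c) `peak_ks`,
the same KDE+Gaussian peak functional the pipeline fits, applied to the
truth pair values convolved with delta-method NG86 noise. Recovery tests
compare like with like, and the truth-implied event ages are computed
from `peak_ks` through the same correction model the pipeline uses —
so the end-to-end test validates the pipeline against the model's own
expectation, while the configured event times remain available to
quantify the correction method's intrinsic bias (dating an event that
accrued at the terminal lineage rate with a factor estimated from the
whole-path average overestimates its age; this is a property of
peak-alignment rate correction, not of the implementation).

What the generator does *not* emulate: intron/intergenic sequence,
transposable elements, tandem arrays, chromosome fusions/fissions or
inversions beyond single-gene translocations, biased fractionation
between subgenomes, codon-usage bias, and transition/transversion bias.
Passing recovery tests therefore demonstrates the pipeline's correctness
under the stated generative model, not robustness to every property of
real annotations.

## Problem sizes and numerical choices

The validation suite runs most integration tests on a reduced bundle
(350 ancestral genes, 200 codons) and one full-scale recovery on the
default 2,000-gene bundle — sizes chosen so each pipeline stage still has
hundreds of blocks and tens of thousands of pairs to work with while the
whole suite stays interactive. KDE grids use 512 points; the geometric
fit uses bounded scalar minimization (tolerance 1e-10); mixture fits use
5 initializations with a fixed random state; all simulator randomness
derives from a single seeded PCG64 stream, and identical seeds reproduce
bundles and summaries bit-for-bit.

## Known limitations

- The greedy chain extraction is optimal per extraction step, not
  globally across overlapping chains; the brute-force equivalence tests
  cover the best chain, and pathological overlap patterns could split
  blocks suboptimally.
- Sibling-column phasing uses regional footprint continuity, not a
  genome-wide subgenome assignment; columns are locally, not globally,
  phased, and a lone surviving region defaults to the first sibling
  column.
- Saturated pairs are excluded rather than modeled; events with median
  Ks beyond ~2.5 are outside the usable range of NG86 + one-parameter
  correction.
- Dating propagates only the calibration interval; no confidence
  interval on the peak positions themselves is attached.
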