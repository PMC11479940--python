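# Methods

This note documents the models, conventions and numerical choices behind
`svakit`, and what the synthetic study conditions do and do not establish
about real data.

## Coordinate conventions

All intervals are 0-based half-open internally.  GTF records (1-based
inclusive) are converted at the I/O boundary and nowhere else.  An
insertion at position *p* uses insert-before semantics: the inserted
sequence is placed between bases *p−1* and *p* (equivalently after the
1-based base *p*), which makes a two-interval `getfasta`-style splice and a
1-based "last base of the left segment" breakpoint the same operation.
Insertion-call starts are interpreted as the 0-based reference position
before which the consensus is inserted; whether upstream callers report
0- or 1-based starts is declared here rather than inferred.

## Insertion catalog

Quality fields (`UnmapCover`, `TEMatch`) are accepted on either the 0–1 or
0–100 scale and normalized to fractions; column headers are resolved
through a case-insensitive alias table because caller output headers vary.
Filtering keeps calls with UnmapCover ≥ 0.80, TEMatch ≥ 0.80, span-reads
≥ 3 and length **strictly** greater than 1000 bases (the length bound is
exclusive by definition of "greater than 1 kbp"); subfamily allow-lists
are applied only when non-empty.  Cross-sample event matching treats two
calls as the same insertion when chromosome and subfamily agree and starts
differ by at most 50 bp — a declared default absorbing long-read
breakpoint jitter, for which no published value exists.

## Genome augmentation and liftover

`augment_genome` validates the plan (positions in bounds, at most one
insertion per position — ties are rejected rather than ordered
arbitrarily, since silent nondeterminism is worse than an explicit error)
and splices all insertions in one linear pass; the result is provably
independent of application order, so end-to-start processing is an
optimization, not a semantic requirement.  The `CoordinateMap` stores
`(breakpoint, cumulative offset, length, label)` per chromosome.  Liftover
shifts features wholly downstream of *k* inserted bases by *k* and
stretches features that span an insertion point (the insertion becomes
internal, mirroring an intronic insertion); features are never split.
Projection is the exact inverse off inserted segments; positions inside an
insertion project to the insertion point with an `inside_insertion`
status.  Records on chromosomes absent from the map pass through with a
logged warning rather than failing, so partial annotations survive.

## Coverage profiling

Alignment filtering keeps primary records with a single reported hit (when
unique-mapping is requested) and a mismatch rate of at most 0.03 per
aligned base; the comparison is inclusive, mirroring a maximum-allowed-value
aligner flag.  Spike-in scaling multiplies every track value by
`10⁴ / aligned-spike-in-reads`; a zero spike-in count raises an error
rather than producing infinity.

Scale-regions matrices use a 1 kbp rescaled body, 10 kbp fixed flanks and
50 bp bins by default.  The bin size is a declared default chosen to
divide both body and flank evenly.  Body bins average the per-base signal
over fractional genomic intervals with exact partial-base weighting (the
matrix equals an independent per-base averaging oracle to < 1e-9); flank
bins are raw fixed-width averages.  Rows of minus-strand elements are
reversed so columns always read 5′→3′ of the element.  Flank bins falling
off the chromosome are NaN and are excluded from column means — a
missing-aware mean rather than invented zeros; this is a declared choice
where heatmap tools differ.  Boundary enrichment compares the mean over
bins within a window (default 1 kbp) of the two body/flank junctions
against the outermost flank bins; a zero or missing distal mean yields NaN,
never infinity.

## Methylation

Calls are binarized at |LLR| ≥ 2 with a symmetric dead zone; ambiguous
calls are discarded and counted.  The 2.0 threshold is common practice for
nanopore methylation callers and is exposed as a parameter.  Element
summaries use read-level averaging (every retained read-site observation
counts once) because methylation "coverage" displays are read-weighted; a
site-level mode (average within site, then across sites) is provided.
Quarters are anchored at the element's transcription start: for a
minus-strand element the first quarter from the TSS is the genomically
last quarter.  Group comparisons use the two-sided Student's (equal
variance) t-test on per-element summaries; groups with fewer than two
usable elements report the difference but mark the test not applicable.

## Tandem-repeat estimation

The consensus is a per-column plurality vote over {A, C, G, T, −} with
deletion columns removed, ties broken A < C < G < T < deletion, and
columns below `min_depth` emitted as N.

Motif runs are found by a wraparound local alignment against an unbounded
tandem concatenation of the motif.  Matches score +1 and each edit
(substitution, insertion, deletion) costs `(1 − ν)/ν` for noise ceiling ν,
so a segment scores positive exactly when its edit-noise is below ν
(default ν = 0.2).  The exact scoring of published repeat-confirmation
tools is not specified, so unit edit costs with this noise bound are the
declared model.  Matching is phase-agnostic; partial terminal copies count
fractionally (`copy_estimate` = aligned motif positions / motif length).
A reported run must span at least two motif copies — a single isolated
motif occurrence is not a tandem repeat.  Wraparound deletion moves are
resolved with two relaxation passes per row, sufficient because a full
deletion cycle is always score-decreasing.  The headline copy count is the
half-up-rounded estimate of the longest run (ties 5′-most); whether
published repeat lengths count partial terminal copies is unstated, so
the rounding rule is declared here.  For inputs up to a few kilobases the
O(n·m) dynamic program with traceback-free aggregate tracking runs in
milliseconds.

## Expression

TPM uses the feature length as the effective length (no fragment-length
correction) — an approximate TPM adequate for ratio displays.
Median-of-ratios size factors follow the standard formula: per-feature
geometric-mean reference over samples (features with any zero excluded),
per-sample median of count/reference.  Note the factors are defined up to
a common scale: multiplying one sample by *c* multiplies its factor
*relative to the others* by *c*, while the geometric-mean reference
absorbs `c^(1/m)`.  Differential-expression testing itself is out of
scope; only the normalization is implemented.

Element–gene links measure the distance from the nearest element edge to
the gene TSS (gene start on +, gene end on −; 0 when the TSS falls inside
the element, symmetric "adjacent = 1" otherwise) and keep links in a
window of 2–50 kbp by default.  Edge-to-TSS rather than midpoint-to-TSS
is a declared choice.  Readthrough detection walks outward from each
element boundary on each strand, extending while coverage stays at or
above `min_coverage` and bridging gaps up to `max_gap` bases; the longest
extension wins and is labeled antisense when its strand opposes the
overlapped (else nearest) gene.

## Reporting

Cohort summaries use the arithmetic mean and the n−1 sample standard
deviation, excluding and counting records missing the field.  On-target
statistics report both the unweighted mean of per-sample proportions (the
headline) and the pooled proportion; when a user-supplied grand total
disagrees with the per-sample sum, both are reported and never silently
reconciled.  Display rounding is half-up (one decimal for cohort fields,
two-decimal percent for on-target); full-precision values are always
retained in the TSV outputs.

## Synthetic study conditions

The generator's defaults are the study conditions: three 120 kb
chromosomes; six fixed SVA-like elements of 1.2–2.4 kbp with 35–50 hexamer
copies and a 72 % GC body carrying ≥ 20 CpGs; six polymorphic insertions
(plus three decoy calls failing one filter each); 5-fold boundary
enrichment of the repressive mark over a mean-1 background with 2 %
multiplicative noise; a 10⁴-read spike-in; methylation 0.95 in the control
and 0.10 on knockdown-demethylated elements, 12 reads per CpG, LLR
magnitudes in [2.5, 10] so binarization at 2 is unambiguous; a 3-fold
intron-retention increase with a 0.5-fold downstream exon in the
double-knockdown count table (4 replicates per group, Poisson counts); and
one 2 kb antisense readthrough.  Elements are spaced so 10 kb flanks never
overlap another element, one gene with two introns is placed per
chromosome, and one insertion per chromosome is intronic.  The element
body is forced to break the hexamer phase at the head/body junction so the
planted copy number is unambiguous.

Identical configurations reproduce byte-identical files; all randomness
flows from the single seed through per-stage generators.

What the generator does **not** emulate: read-level nanopore signal,
sequencing-error models beyond uniform substitution, mappability structure
(the "unique flank" problem is represented only by construction),
biological variation between replicates beyond Poisson counting noise, and
VNTR length polymorphism.  Passing tests therefore demonstrate that the
algorithms recover planted truth under idealized noise — they do not
validate caller accuracy, alignment quality or biological effect sizes on
real data.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale: 3–10
chromosomes of 120 kb, ≤ 10 elements/insertions, 1000-position coordinate
round-trips, 1000 null simulations for test calibration, and one
full-length (156 Mb) chromosome splice for the stitch-length check.  These
sizes were chosen so the whole suite completes in about a minute while
every code path — including the full-scale splice — is exercised.

## Known limitations

- The insertion-table column alias list covers common variants but not
  every caller dialect; unknown headers raise a named format error.
- `project_to_reference` cannot range-check positions beyond the last
  breakpoint without knowing the augmented chromosome length; negative
  positions are rejected, trailing overruns map past the sequence end.
- The readthrough caller reports a single dominant extension per element
  rather than all four strand/side combinations.
- The wraparound aligner's tie-breaking (diagonal over insertion over
  deletion, earliest cell wins) is deterministic but may differ from other
  repeat finders in degenerate, equal-score cases.
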