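# Methods

## Detection model

A polyXY region is defined operationally through the sliding window: a
window of length *w* is positive when it contains exactly two distinct
residue types, each occurring at least twice; maximal regions are unions
of *overlapping* (≥ 1 shared position) positive windows of the same
unordered pair.  Consequences worth stating explicitly:

- *w* is both the window length and the minimum reportable region length
  (merged overlapping windows can only grow a region).  *w* ≥ 4 is
  required; below 4 no window can hold two residue types twice each.
- Windows of different pairs never merge: merging across pairs would
  create regions with more than two residue types, contradicting the
  definition.  Regions of different pairs may therefore overlap (e.g.
  `AAAGGGSSS` yields an {A,G} region at 1–6 and a {G,S} region at 4–9).
- Two positive same-pair windows that are adjacent but share no position
  are *not* merged; they yield two regions.
- Homorepeats are excluded by construction (one residue type only).

**Non-standard residues.** Characters outside the 20 standard amino
acids (ambiguity codes B/J/X/Z, the rare O/U, stops, gaps) make a window
negative: an ambiguous composition cannot define a bona fide two-residue
region.  Sequences containing them are accepted; only windows touching
them are disqualified.  Sequences are upper-cased on ingest; lower-case
soft-masking is not honored.  Duplicate FASTA ids are a hard error
because per-protein statistics would silently double-count.

**Coordinates.** 1-based, inclusive at both ends, everywhere in the API
and in every file format.

**Gap merging.** Optionally, same-pair regions separated by at most one
or two residues (necessarily outside the pair, since maximal regions
cannot extend over pair residues) can be merged, transitively
left-to-right.  Merged regions contain foreign residues, which breaks
both the direpeat unit coverage and the joined two-run structure, so
they are always categorized shuffled.

## Classification

Categories are tested in a fixed order — direpeat, then joined, then
shuffled — and are mutually exclusive and exhaustive.  For pure
two-letter regions of length ≥ 6 the first two definitions are disjoint
(verified exhaustively in the tests), so the precedence is a safety
device, not a semantic choice.

- **Direpeat**: the sequence equals `u^k` for a unit `u ∈ {XY, YX}`
  (even length), or becomes such after removing a single residue (odd
  length).  This realizes "units with at most one lone residue, at a
  terminus or between units" exactly: with zero lone residues the length
  is even and the tiling must be perfect; with one lone residue the
  length is odd.  The singular reading — at most one lone residue in the
  whole region — is deliberate; a per-position allowance would blur
  direpeats into shuffled.  The unit count is `⌊length/2⌋`; the lone
  residue never counts as a unit (`GLGLLGL` → 3 units).
- **Joined**: exactly two maximal runs, each of length ≥ 2.  Run minima
  follow from the window rule at length 6 (`XXXXXY` is never a region
  since Y occurs once) and are kept for longer regions for consistency.
  The order (first-run residue, second-run residue) is recorded.
- **Shuffled**: the remainder.  On request, shuffled regions are
  searched for embedded joined or direpeat sub-spans of length ≥ *w*.
  The search is not an enumeration of sub-spans: a joined sub-span must
  be a suffix of one maximal run followed by a prefix of the next, and a
  direpeat sub-span lies inside a maximal two-letter stretch and reduces
  to an alternation/defect analysis (an alternating sub-span of length
  ≥ *w* qualifies; a sub-span crossing exactly one defect qualifies iff
  an odd length ≥ *w* fits in the two flanking alternating blocks).
  Both reductions are verified against exhaustive enumeration in the
  test-suite.

Direpeat and shuffled pairs are reported alphabetically; only the joined
category carries order.

## Summary statistics

- Regions per protein and mean region length are plain ratios.  The
  residue-level ratio divides the total residues inside regions by total
  protein residues; residues in overlapping regions of different pairs
  are counted once per region, the most direct reading of a
  "region residues / protein residues" quotient, fixed here so the
  number is auditable.
- Composition usage compares each amino acid's background frequency
  (over all protein residues, normalized over the 20 standard residues)
  with the fraction of regions whose pair contains it.  Each region
  counts once per pair member, so the usage column sums to 2 and the
  natural reference line when plotting usage against background is
  x = y/2.
- Relative position is the region midpoint divided by protein length.
  Midpoint rather than start is used because it is symmetric under
  sequence reversal and matches how N-/C-terminal preference is
  described.  Positional contrasts (e.g. joined XY vs joined YX) use a
  two-sided Mann–Whitney U: exact null distribution for small tie-free
  samples, normal approximation with tie correction otherwise (SciPy's
  policy); the all-tied degenerate case returns U = n₁n₂/2, p = 1.
- Direpeat unit counts are binned as {3, 4, 5, 6, >6} together with the
  fraction above 3 units.

## Overlap with domains and disorder

Containment is strict and boundary-inclusive: the whole region must lie
within a single annotated interval.  Annotations (globular domains,
predicted intrinsically disordered regions) are consumed as plain
interval TSV rather than database flat files, keeping the package
testable offline.  The baseline places, for each region, `n_random`
segments of the same length uniformly at random in the same protein
(default 1, matching the one-placement design; larger values reduce
baseline variance and report the per-region mean).  For a single
interval of length *m* in a protein of length *L* and a region of length
*k*, the containment probability of one placement is
max(0, m − k + 1)/(L − k + 1); the Monte-Carlo estimate is tested
against this closed form.  Regions on proteins without any annotation
count as not contained by default — absence of annotation is informative
in a proteome-wide setting — with a flag to restrict to annotated
proteins.  One seed drives all placements, drawn in region input order,
so reports are bit-reproducible.

## Synthetic data

The generator emulates a proteome as i.i.d. background residues (default
frequencies: the average composition of curated protein databases) into
which planted regions of chosen pair, category and length are spliced,
guarded by two residues outside the plant's pair on each side so a plant
cannot silently extend.  Shuffled plants are rejection-sampled until
every window of the plant is positive and the plant is neither a
direpeat nor joined.  Annotation plans can wrap each plant in a
domain/disorder interval (with padding) and scatter random domains.

Truth is defined **by oracle, not by intent**: the emitted truth table
is the output of an independent brute-force scanner (windows enumerated
directly; same-pair overlaps merged by naive pairwise fixpoint) on the
final sequences.  Background sequences can legitimately form polyXY, and
with database-average frequencies they regularly do; oracle-defined
truth includes them, which is what makes detector-vs-truth comparisons
exact rather than flaky.

What the generator does *not* emulate: residue autocorrelation and
repeat expansion mechanisms of real proteomes, per-taxon composition,
domain architectures, or any dependence between annotation placement and
sequence content beyond the configured plant wrapping.  Tests passing on
fixtures therefore demonstrate correctness of the computations, not
biological conclusions about real proteomes; the pinned-release checks
against archived UniProtKB 2021_04 data cover the latter where those
files are available locally.

## Problem sizes and defaults

The test-suite and the acceptance script run on generated data sized for
exactness of the checks: 1,000 random sequences (lengths 1–500,
alphabets 2–20) for detector/oracle equivalence, 10,000 random
two-letter strings (lengths 6–30) for classifier equivalence, 100 random
fixture specs for truth recovery, and a 300-protein synthetic proteome
(100–600 residues each) for the end-to-end study, with 20,000 placements
for baseline calibration.  These sizes make binomial/Monte-Carlo noise
small relative to the asserted tolerances.

## Known limitations

- The embedded-pattern flags are computed only on request (they are not
  part of the TSV region format), and merged regions (gap > 0) are
  shuffled by fiat rather than re-analysed for interrupted periodicity.
- Fuzzy direpeats with more than one interruption, period-3 repeats, and
  regions of three or more residue types are out of scope.
- Annotation intervals are trusted as given; no disorder prediction or
  domain assignment is performed.
- Proteome-scale reproduction requires the archived UniProtKB release
  the published counts were computed on; current releases give different
  (typically larger) protein sets and hence different counts.
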