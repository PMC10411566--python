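# Methods

## The model

`lsutools` treats a chromosome-level genome as an ordered arrangement of
near-universal single-copy ortholog markers (BUSCO markers from a lineage
dataset such as `lepidoptera_odb10`, ~5,000 markers). Because each marker is
expected once per genome, marker *identity* carries homology across species
without any sequence alignment. The method has three layers:

1. **Synteny units.** The anchor genome's markers are filtered (drop
   `Missing`; drop every line of any marker that appears `Duplicated`,
   since BUSCO cannot say which copy is orthologous; `Fragmented` kept by
   default), grouped by chromosome, and sorted by position. Each anchor
   chromosome's marker subset is one synteny unit (`LSU_i`), and each marker
   gets a 1-based *anchor rank* along its unit. Under the default naming
   policy the unit index follows the chromosome's trailing integer and any
   Z-named chromosome is placed last, so the Z unit always carries the
   highest index (the convention for lepidopteran karyotypes, where the Z is
   the sex chromosome). Opaque names can instead be ordered by descending
   length or by first appearance.

2. **Macrosynteny: fusion and fission calls.** A target genome's filtered
   markers are joined to the units by id and ordered along the target
   chromosomes. The hit-count matrix (target chromosomes × units) is then
   classified:
   - a unit is a *component* of a chromosome iff it contributes
     `min_component_markers` (default 5) markers **and**
     `min_component_fraction` (default 5%) of that chromosome's assigned
     markers;
   - a chromosome is `single` (1 component), `fusion_of_k` (k ≥ 2), or
     `unclassified` (0);
   - a unit is `intact` when one chromosome holds ≥ `intact_fraction`
     (default 95%) of its recovered markers, `split` when it is a component
     of ≥ 2 chromosomes, and `dispersed` otherwise (a unit scattered in
     sub-threshold fragments over many chromosomes).

   The component thresholds are a design choice of this package: their job
   is to keep small transposed fragments from masquerading as fusion
   partners. They are configurable on every command and echoed in all
   output headers.

3. **Collinearity: breakpoints and transpositions.** Rearrangement within
   units is measured on marker order, not coordinates. First, small
   nonreciprocal transpositions are detected: on each target chromosome,
   maximal runs of adjacent markers whose unit is *not* a component of that
   chromosome are collected; runs of length ≤ `max_run` (default 3) are
   transposition events, longer runs are reported separately as
   translocated segments and never counted as transpositions. Second, for
   every (target chromosome × unit) group, transposed markers are removed,
   the remaining shared markers are taken in target order and re-ranked
   1..m by anchor rank restricted to that shared set, and a breakpoint is
   counted at every adjacent pair with |Δ re-rank| ≠ 1.

   Properties that follow from this definition, all exercised by tests:
   - an internal inversion leaves exactly 2 breakpoints; a translocated
     block inside a group leaves 3;
   - a whole-group reversal scores 0 (descending ranks have |Δ| = 1
     throughout) — counting is orientation-free, and strand is parsed but
     unused (a signed mode is left for future work);
   - chromosome ends and the junction between two units on a fused
     chromosome are never breakpoints (groups are per unit);
   - markers missing from the target cannot inflate counts, because
     re-ranking is performed within the shared set — deleting markers
     strictly inside collinear runs leaves every count unchanged;
   - removing transposed runs before counting scores each relocation once
     (as an event), not several times (as breakpoints).

   Counts convert to per-Mbp rates; the denominator defaults to the summed
   lengths of marker-bearing sequences, from a supplied length table
   (`.fai`-style) or, as a fallback, inferred from maximum marker end
   coordinates — inferred denominators are lower bounds and are flagged as
   such in reports.

## Coordinates and dialects

Coordinates are treated as 1-based inclusive throughout; since only
relative order is used, off-by-one conventions cannot change any result and
are documented rather than configurable. The parser accepts the v5
full-table header (with Strand), v3/v4 headers (strand becomes `unknown` on
every record — never silently dropped), headerless tables by column count,
and older outputs embedding coordinates as `scaffold:start-end`. Score and
Length columns are parsed but unused; they are retained for round-trip
fidelity (`parse ∘ write` is the identity on valid record lists). Sort
tie-breaking everywhere is `(start, end, marker_id)`, making every run
deterministic.

## The simulator

The simulator emulates what a BUSCO run on a rearranged descendant of the
anchor would report, without any sequence-level modeling. The default
anchor is 31 chromosomes × 170 markers over ~17 Mbp each (≈100 kb marker
spacing, seeded jitter), matching the scale of a chromosome-level
lepidopteran assembly scored with a ~5,000-marker set and the modal
lepidopteran karyotype of n = 31 with the Z last. Events — fusions,
fissions, inversions (order reversal + strand flip), transpositions of 1–3
adjacent markers, marker loss (→ `Missing`), duplication (→ two
`Duplicated` lines) — are applied in list order with no hidden canonical
ordering, and coordinates are re-emitted per chromosome to restore
monotone spacing. One integer seed drives a single generator stream;
identical seeds give byte-identical tables.

`random_events` draws event lists that are *non-overlapping by
construction*: each chromosome plays at most one role, inversions are
internal (not touching chromosome ends) and mutually separated by at least
one marker, fission cut points leave both products above the component
thresholds, and transposed runs are capped at 4% of their source unit so
the source stays `intact`. It takes per-event-type counts rather than
continuous rates: the analytic guarantees are count-based, and counts make
rejection-free sampling exact. Under these conditions the truth log
carries an analytic expected signature — 2 breakpoints per inversion, one
event per transposed run, `fusion_of_2` / `split` calls per fusion /
fission, computed under the default thresholds — and the pipeline recovers
it exactly. Arbitrary (overlapping) event lists are still applied
faithfully but claim no signature; `apply_events` verifies the
non-overlap conditions itself, so a hand-built spec gets a signature only
when one is actually warranted.

Fractional loss/duplication defaults to *safe interior* sampling: only
markers whose two neighbours are anchor-consecutive (strictly inside a
collinear or inverted-collinear run, and not part of a transposed run) are
eligible. Removing any subset of such markers provably preserves every
breakpoint count (the re-ranking closes the gaps, and segment-end markers
are never eligible, so inversion footprints cannot collapse), which is
what makes the loss-robustness guarantee exact rather than statistical.

## What the synthetic data does and does not show

The generator reproduces the *combinatorial* structure of the problem:
statuses, chromosome-scale marker arrangements, and the event vocabulary.
It does not model unequal marker density, assembly errors, hit-score noise,
fragmented gene models at contig edges, paralog misassignment, or the
W chromosome. Passing the recovery suites therefore demonstrates that the
pipeline's detection logic is exact under its stated definitions, not that
real genomes satisfy those definitions; on real data the marker density
bounds resolution, and rearrangements visible only at the nucleotide level
are invisible by design.

## Problem sizes and numerical choices

The test and acceptance workloads use the full default anchor
(31 × 170 = 5,270 markers) with 200 inversion simulations (k = 1..10 × 20
seeds), 50 fusion/fission mixes, 50 transposition draws, 20 loss-robustness
runs, 1,000 random 50-rank permutations against the brute-force oracle,
and 500-record serialization round trips — sizes chosen so the whole suite
completes in well under a minute per suite while exercising every event
type at realistic scale. Groups with fewer than two shared markers
contribute zero breakpoints; empty chromosomes are simply absent from the
unit table; an anchor with fewer than two marker-bearing sequences warns
but proceeds.

## Known limitations

- Reciprocal translocations are not inferred as such; they surface as
  breakpoints and (if small) transposition events.
- Nucleotide-level breakpoint localization is out of scope; the output
  marks the flanking markers, which is enough to target a subsequent
  sequence-level analysis.
- Whether chromosome ends or fusion junctions should count as breakpoints
  is a genuine definitional choice; this implementation does not count
  them, and states the rule in every report header so cross-study
  comparisons can account for it.
- The per-Mbp denominator (marker-bearing sequences vs whole assembly) is
  likewise a choice; the default is marker-bearing sequences, with the
  provenance (supplied vs inferred lengths) recorded in the report.
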