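# lsutools

Chromosome numbers vary wildly between species, so chromosome *counts* say
little about chromosome *homology*. `lsutools` traces homology directly:
it takes the positional output of a BUSCO run (the `full_table.tsv` of
near-universal single-copy orthologs) on a chromosome-level anchor genome,
defines each anchor chromosome's marker subset as a **synteny unit**
(LSU — the usage comes from lepidopteran comparative genomics, where the
anchor is a butterfly genome with the ancestral n = 31 karyotype and the
Z chromosome is the last unit), and then maps any other genome's BUSCO
table onto those units by marker identity alone. No alignment, no
lift-over — just a join on ortholog ids.

From that mapping it answers three questions for each target genome:

- **Macrosynteny** — which units make up each target chromosome? One
  target chromosome carrying two units is a *fusion*; one unit spread as a
  major component over two chromosomes is a *split* (fission); a unit
  scattered in sub-threshold fragments is *dispersed*.
- **Collinearity** — how scrambled is marker order within each unit? For
  every (target chromosome × unit) group the shared markers are re-ranked
  1..m by their anchor order, and a **breakpoint** is counted at every
  adjacent pair whose re-ranks differ by more than 1. An inversion leaves
  2 breakpoints, a translocated block 3.
- **Small transpositions** — runs of 1–3 adjacent markers relocated onto a
  chromosome dominated by another unit are detected and reported as
  events, and excluded from breakpoint counting so nothing is scored twice.

Counts convert to per-Mbp rates from a supplied length table or from
lengths inferred off the markers themselves (flagged as lower-resolution).

A seeded rearrangement simulator (`lsu simulate`) generates anchor/target
table pairs under known fusions, fissions, inversions, transpositions,
losses and duplications, together with a ground-truth log carrying the
analytic expected signature — the basis of the package's exact recovery
tests. See `docs/methods.md` for definitions, thresholds and guarantees.

Intended users: comparative genomicists with chromosome-level assemblies
and BUSCO runs in hand who want karyotype homology, fusion/fission
histories, and rearrangement rates without whole-genome alignment.

## Worked example

Simulate a descendant genome with 3 inversions and 2 single/short
transpositions, then run the full workflow:

```sh
lsu simulate --seed 7 --n-inversions 3 --n-transpositions 2 -o sim
lsu define --anchor sim/anchor_full_table.tsv -o units
lsu assign --units units/lsu_table.tsv --target sim/target_full_table.tsv -o comp
lsu breakpoints --units units/lsu_table.tsv --target sim/target_full_table.tsv \
    --lengths sim/target_lengths.tsv -o bp
```

The commands print one summary line each:

```
simulate        events=5        analytic_truth=True
define          units=31        markers=5270
assign          chromosomes=31  fusions=0       split_units=0
breakpoints     within_lsus=6   single=2        grouped=0
```

Reading this: the anchor's 5,270 usable markers define 31 units; the
descendant still has 31 chromosomes with no fusions or splits; the 3
simulated inversions left exactly `6 = 2 × 3` order breakpoints; and both
transposed runs were single markers (`single=2, grouped=0`). The last line
of `bp/breakpoints.tsv` carries the rates:

```
summary  breakpoints_within_lsus=6  per_mbp=0.0113  transpositions_single=2  transpositions_grouped=0  transpositions_per_mbp=0.0038
```

i.e. 6 breakpoints over the ~531 Mbp of marker-bearing chromosomes.
`comp/hit_counts.tsv` holds the chromosome × unit matrix,
`comp/composition_calls.tsv` the fusion/split/dispersed calls, and
`sim/truth.json` the resolved event log with the expected signature the
pipeline just recovered. Every output starts with `#` header lines echoing
the version and configuration; re-running any command with the same inputs
reproduces the files byte for byte.

The same analysis on real data starts from your own BUSCO outputs: run
`lsu define` on the anchor genome's `full_table.tsv` (with its `.fai` via
`--lengths` for coverage sizes), then `lsu assign` / `lsu breakpoints` on
each target genome's table.

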