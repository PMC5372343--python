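# panscaf — core-genome scaffold comparison for bacterial pan-genomes

Closely related bacterial strains (one species, many complete genomes)
differ by gross chromosomal rearrangements: inversions, transpositions,
block interchanges.  Long inversions in particular are typically mediated by
recombination between a pair of Inverted Repeats (IRs, usually IS elements)
— the sequence between the two copies flips, the copies and everything
outside them are conserved.  `panscaf` is a library (plus a thin CLI) for
studying this mechanism:

* build per-strain **core-genome scaffolds**: order the core blocks (shared
  by all strains) along each chromosome, drop short blocks, and merge runs
  of blocks that are consecutive with consistent orientation in every
  strain;
* group strains with identical scaffolds and, for each group, find the
  **closest group** by exact inversion distance;
* before computing distances, **eliminate independent rearrangement
  events** — transpositions, inverted transpositions, block interchanges
  and inverted block interchanges whose application resolves every
  breakpoint at their junctions — since an inversion-only distance would
  miscount them (3 inversions for the plain kinds, 2 for the inverted
  kinds);
* compute the **exact minimum inversion distance** and an optimal scenario
  by breakpoint-graph theory (see below), verified against an exhaustive
  search oracle;
* test whether each inversion is **flanked by an IR pair** in the actual
  sequences, and whether transposition-like events carry direct-repeat
  copies at all junctions (end conservation);
* generate **synthetic multi-strain datasets** with planted repeats and
  repeat-mediated events, with a truth log, so the whole pipeline is
  testable without downloads.

## The core model

A scaffold is a signed permutation `G2 = π1 π2 … πn` of the n merged core
blocks; the reference scaffold is the identity `G1 = +1 +2 … +n`.  An
inversion reverses a block run and flips its signs.  The minimum number of
inversions transforming one scaffold into the other is

    d = (n + 1) − c + h + f

where `c` counts alternating cycles of the breakpoint graph of the capped
permutation, `h` counts hurdles (unoriented components that do not separate
other unoriented components) and `f` flags a fortress.  An *independent*
transposition is an adjacent swap `… π(i+1) π(i) …` whose resolution leaves
four consecutive same-strand values `+(q−1) +q +(q+1) +(q+2)` (or the
negative mirror) — its three breakpoints sit on one 6-edge cycle and vanish
together.  Independent block interchanges are the separated-swap analogue
(4 breakpoints, two interleaving 4-edge cycles), and the inverted variants
additionally restore operand signs.  Eliminating these before the distance
computation, on the common-adjacency-merged pair, leaves a residual
inversion count `Inv_d` plus an independent-event count `R_d`.

## Worked example

```
$ python examples/02_independent_events.py
after merging: target +1 +2 +3 +4, source +1 +3 +2 +4
merged runs: {1: (1, 2), 2: (3, 4, 5), 3: (6, 7), 4: (8,)}

inversion distance without elimination: 3
eliminated events: {'transposition': 1, 'inverted_transposition': 0, 'block_interchange': 0, 'inverted_block_interchange': 0}
  transposition: regions (6, 7) and (3, 4, 5) swap
residual inversion distance: 0 (R_d = 1)
```

The scaffold `+1+2+6+7+3+4+5+8` looks three inversions away from the
identity, but after merging commonly-adjacent runs the difference is a
single independent transposition of the regions (6,7) and (3,4,5): the true
rearrangement history is one event, not three.

Running the full pipeline on the bundled synthetic study
(`python examples/03_synthetic_pipeline.py`) prints the closest-pair table:

```
sG  cG  Inv_d  inversion  l(mbp)  IR    R_d
1   4   0      None       N/A     N/A   1
2   1   2      (-4,-2)    0.0387  A(2)  0
               (-7,-6)    0.042   B(2)
3   1   3      (-9,-9)    0.0392  C(2)  0
               (-11,-11)  0.0281  D(2)
               (-13,-13)  0.0209  E(2)
4   1   0      None       N/A     N/A   1

5/5 inversions IR-flanked; 5/5 of the long (> 10000 bp) ones
```

All five planted IR-mediated inversions are recovered with their lengths,
each flanked by its mediating repeat pair (presence code 2: found in
strains of both groups), and the planted direct-repeat transposition shows
up as `R_d = 1` with `Inv_d = 0`.

The other examples: `01_inversion_distance.py` (the canonical event-cost
patterns: a transposition costs 3 inversions, an inverted transposition 2,
a block interchange 3, an inverted block interchange 2),
`04_repeat_flanks.py` (IR detection and cross-strain occurrence mapping).

## Command line

```
panscaf simulate --seed 0 --out data/            # synthetic dataset + truth
panscaf scaffold --blockmap data/blockmap.tsv --min-len 500 --out scaf/
panscaf distance --source A.perm --target B.perm --scenario out.json
panscaf events --source A.perm --target B.perm --report events.json
panscaf report --blockmap data/blockmap.tsv --genomes data/genomes --out out/
```

Permutation files use the GRIMM-style plain-text format (`>name` header,
signed integers, optional `$`).  Block maps are TSV with columns
`strain block contig start end strand` (0-based half-open coordinates);
MAF alignments in the Mugsy dialect are accepted instead via `--maf`.

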