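# Methods

## Scaffolds as signed permutations

Each strain's chromosome is reduced to the ordered, signed sequence of its
merged core blocks.  Permutations are linear (bacterial chromosomes are
circular, but the scaffolds are compared as written, anchored at a shared
origin); sentinels +0 and +(n+1) cap the two ends so that adjacencies at the
chromosome boundaries are first-class.  Positions inside a permutation are
1-based; all genomic coordinates are 0-based half-open.

A capped adjacency (a, b) is conserved iff b = a + 1 in signed notation,
which covers both `+i,+(i+1)` and `−(i+1),−i`; anything else is a
breakpoint.  Circular rotation equivalence, multichromosomal permutations
and translocation/fission/fusion are out of scope.

## Exact inversion distance

The distance of a permutation to the identity is computed from the
breakpoint graph of the capped permutation (standard signed→unsigned
doubling, +x → (2x−1, 2x), −x → (2x, 2x−1), caps 0 and 2n+1):

    d = (n + 1) − c + h + f

* `c` — number of alternating black/gray cycles.
* `h` — hurdles.  Cycles whose gray edges interleave are grouped into
  components; a component is unoriented if none of its gray edges joins two
  positions of equal parity.  Component spans nest or are disjoint; a
  hurdle is an unoriented component that is minimal in the containment
  order, or the one containing all other unoriented components.
* `f` — fortress flag: 1 iff the number of hurdles is odd and deleting any
  one of them does not lower the hurdle count (every hurdle is protected by
  a non-hurdle unoriented component).

Correctness is contractually defined as equality with an exhaustive
breadth-first-search oracle over the n(n+1)/2 reversal moves; the test
suite verifies this for **every** signed permutation with n ≤ 5 (the
acceptance suite; n ≤ 7 was swept exhaustively during development, 645,120
permutations) and for 500 random permutations each at n = 6 and 7 on every
run.  Fortress configurations require more breakpoints than n ≤ 7 affords,
so the `f` term follows the standard theory but is not reachable by the
exhaustive sweep; it is exercised structurally by the decomposition
invariant d = (n+1) − c + h + f asserted on random permutations.

Scenarios are produced greedily: at each step, among all inversions that
reduce the remaining distance by one (at least one always exists when
d > 0), the one with the smallest left position, then smallest right
position, is applied.  This makes scenarios deterministic; optimal
scenarios are generally not unique, and only the scenario's validity
(applying it reaches the target) and its length (equal to the distance) are
contractual.

The BFS oracle caches a full distance table per n for n ≤ 7 (the n = 7
table costs roughly half a minute once per process) and switches to
bidirectional search at n = 8; larger n are refused.

## Independent events

Four event kinds are eliminated before the inversion distance is computed.
On the capped permutation:

* independent transposition at i: swapping the adjacent blocks at i and
  i+1 turns the window π(i−1)..π(i+2) into four consecutive same-strand
  values (`+(q−1)+q+(q+1)+(q+2)` or `−(q+2)−(q+1)−q−(q−1)`); exactly 3
  breakpoints disappear;
* independent inverted transposition: same, with one operand's sign
  restored (two patterns, depending on which operand was negated); 3
  breakpoints;
* independent block interchange at (i, k), k ≥ i+2: swapping the single
  blocks at i and k makes both flanking triples consecutive; 4 breakpoints;
* independent inverted block interchange: the separated swap with both
  signs restored; 4 breakpoints.

The breakpoint deltas (3/3/4/4) are asserted at every application, and the
detectors are verified against a brute-force oracle (apply every candidate
swap, accept iff the breakpoint count drops by the kind's constant) on all
signed permutations with n ≤ 4 plus random n = 5 sweeps.

Elimination loops: merge commonly-adjacent runs (so single-block swaps
stand for region swaps), scan in a fixed priority — transposition, inverted
transposition, block interchange, inverted block interchange, leftmost
first — apply the first hit, re-merge, repeat.  Scan order when several
events overlap is not dictated by the theory; the fixed priority is a
determinism convention and is recorded in the CLI event report.  The loop
terminates because every application strictly reduces the breakpoint count.
Elimination is performed in the target scaffold's frame; events carry the
original (pre-merge) block labels of their operands.

Common-adjacency merging is maximal: two consecutive elements of one
permutation fuse iff the other permutation reads them identically or
reverse-complemented.  A single left-to-right grouping pass reaches the
fixpoint, because an adjacency between two merged runs reduces to the
adjacency of their border elements.  (The operation's classical worked
example merges only some of the mergeable runs; this implementation always
merges all of them, and the un-merge record maps every new id back to its
run of old signed ids.)

## Scaffold construction

* Block maps come from a TSV (`strain block contig start end strand`) or a
  MAF alignment in the Mugsy dialect ('a'/'s' lines; reverse-strand starts
  are converted to forward coordinates with the source-length field).
* Blocks are classified core / dispensable / strain-specific by strain
  coverage.  Core blocks shorter than `min_block_len` (default 500 bp,
  boundary keeps exactly-500) are dropped; lengths are measured in a
  designated reference strain (default: first alphabetically) because
  per-strain lengths differ slightly.
* Core blocks merge iff they are genomically adjacent *among core blocks*
  (dispensable sequence in between is ignored) with consistent relative
  orientation in every strain; blocks with repeated copies in any strain
  never merge.  Merged ids are renumbered by reference-strain order.
* Strains are single-chromosome; multi-contig input is rejected rather than
  silently concatenated.
* Groups are strains with bit-identical signed scaffolds, numbered from 1
  by descending size (ties: first strain in input order), so Group 1 is the
  largest.
* Repeated block copies are resolved against a duplicate-free reference
  scaffold: the copy sharing the most signed adjacencies with the reference
  is kept (ties: first occurrence).  This adjacency-maximizing rule is a
  convention; duplicate resolution is genuinely under-determined.
* For each group, every other group is tried; the comparison with minimum
  residual `Inv_d` wins (ties: smaller `R_d`, then lower group id).  Note
  that a pair related by one independent event (Inv_d 0, R_d 1) outranks a
  pair one true inversion away (Inv_d 1, R_d 0) under this rule.

Inversion lengths are the summed lengths of the covered merged blocks in
the source group's canonical strain, reported in mbp (raw bp kept in the
JSON report, avoiding rounding drift).

## Repeat flanks

Breakpoint windows span from the end of the core block preceding an
inversion endpoint to the start of the first inverted block, widened by
`margin` on both sides and clipped to `window_cap` and the genome bounds.
Inverted-repeat search compares the left window against the reverse
complement of the right window: exact k-mer seeds (`seed_k`) grouped by
diagonal (32 bp band), chained, and the chained span verified by edlib edit
distance; the highest-scoring pair with length ≥ `repeat_min_len` and
identity ≥ `repeat_min_id` is reported.  Direct-repeat search is the same
without reverse-complementing.  A detected repeat may extend a few bases
beyond a planted element when the flanking bases match by chance; detection
length is therefore a lower-bounded estimate, not an exact element
boundary.

Defaults: `repeat_min_len` 50 bp, `repeat_min_id` 0.90, `seed_k` 15,
`margin` 2,000 bp, `window_cap` 20,000 bp, `long_threshold` 10,000 bp.
Only the long-inversion threshold is an empirical constant of the studied
phenomenon (long inversions are the IR-flanked ones); the others are
detection conventions, all configurable.  "Flanked" requires each repeat
copy to lie within its breakpoint window — whether the copies must touch
the cut sites exactly is not decidable from scaffold coordinates alone.

Repeat labels (A, B, C, …) are assigned by clustering detected repeat
sequences at ≥ 90% identity in discovery order.  The presence code per
inversion re-locates the repeat in the strains of the source and closest
groups: 0 = source only, 1 = closest only, 2 = both.  Occurrence search is
seed-anchored and verified by semi-global edlib alignment at the identity
threshold, both strands, all strains.

Event-end checks for transposition-like events compare all junction-window
pairs (3 junctions for transposition kinds, 4 for interchanges), direct
orientation first, inverted also for the inverted kinds; the event's ends
are "conserved" when every junction shares a repeat with some other
junction.

## Synthetic data

The generator emulates: an ancestor chromosome of `n_blocks` core blocks
(uniform 2–8 kb by default — desk-scale; real core blocks range up to
~80 kb) separated by 200–600 bp spacers, i.i.d. nucleotides at configurable
GC; IS-like repeats (0.7–1.5 kb) planted in chosen inter-block gaps with
chosen orientations; and per-strain event scripts of two primitives, IR
inversion (reverse-complement strictly between an inverted pair) and DR
transposition (swap the interiors between three same-strand copies).
Inverted transpositions and inverted block interchanges are generated as
two IR inversions each — that decomposition is itself the mechanism by
which such events can arise, so no bespoke cut-and-paste primitive exists.
Each event conserves the sequence outside the outermost mediating repeat
copies bitwise; this is asserted literally in the tests.

Substitution noise is off by default so that end-conservation is exact; an
optional per-strain mutation rate (0.001 when enabled) exercises the
approximate repeat matching.  What the generator does *not* emulate:
indels, gene gain/loss and HGT, IS transposition chemistry, phylogenetic
structure deeper than one ancestor→strain step, and circularity.  Passing
tests therefore demonstrate correctness of the block-level and
sequence-level bookkeeping and the detection machinery under clean
conditions, not robustness to real-genome noise sources such as assembly
error or fragmented alignments.

The default desk-scale study (seed 0): 5 strains × 40 blocks (~234 kb
each), five long (> 10 kb) IR-mediated inversions (two in strain02, three
in strain03), one DR transposition (strain04), strain05 an unrearranged
clone.  Repeat pairs are placed ≥ 6 block gaps apart so every planted
inversion exceeds the long-inversion threshold.  The pipeline recovers the
planted per-pair event counts exactly and flags all five inversions as
IR-flanked; this is the main end-to-end regression.

Determinism: one integer seed drives all sequence draws (numpy Generator);
identical configs produce byte-identical FASTA/TSV/JSON output.

## Numerical and degenerate-input choices

* Empty permutations, n < 1, duplicate ids in a permutation, mismatched
  block sets, multi-contig strains, out-of-range inversion indices,
  non-IUPAC characters in sequence input, and event scripts referencing
  absent repeat copies are all rejected with typed exceptions.
* Zero-length interiors (adjacent repeat copies) make the recombination
  primitives no-ops, as they should.
* The BFS oracle refuses n > 8 outright (state space 10^7+).
* Problem sizes in the test and acceptance suites (n ≤ 7 exhaustive
  distance sweeps, 200-kb synthetic genomes, 200-pair scenario checks) are
  chosen so the whole suite runs in about a minute on one CPU while still
  crossing every code path; the library itself handles the ~50–70-block
  scaffolds of real species directly.

## Known limitations

* Only inversion distance is a metric here; transpositions and
  interchanges are handled solely through their independent forms, not as
  weighted operations in a mixed-distance model.
* The closest-pair tie-break and the event scan order are conventions;
  alternative optimal scenarios and event orderings exist.
* When the residual distance is large, the computed inversion scenario is
  one of many optima and should not be read as the true event history.
* Duplicate-copy resolution is heuristic (adjacency-maximizing); scaffolds
  with many repeated blocks inflate uncertainty that the pipeline does not
  quantify.
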