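"""Detection and elimination of *independent* rearrangement events.

An inversion-only distance overcounts events that were really single
transpositions or block interchanges: a transposition/block interchange
costs 3 inversions and their inverted variants cost 2.  Before computing
inversion distances, this module removes the *independent* forms of four
event kinds — those whose application resolves every breakpoint at the
event's junctions:

* independent transposition: two consecutive blocks swap so that a window
  of four consecutive capped elements becomes a consecutive run
  +(q-1)+q+(q+1)+(q+2) (or its negative mirror); the 6-edge breakpoint-graph
  cycle splits into three 2-edge cycles, i.e. 3 breakpoints disappear.
* independent inverted transposition: as above, with one operand's sign
  restored; 3 breakpoints disappear.
* independent block interchange: two separated single blocks swap so that
  both flanking triples become consecutive runs; the two interleaving
  4-edge cycles become four 2-edge cycles — 4 breakpoints disappear.
* independent inverted block interchange: the separated swap with both
  signs restored; 4 breakpoints disappear.

Because detection runs on the common-adjacency-collapsed pair, a "block"
here may stand for a whole merged region, so single-block swaps represent
region swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .permutation import (
    BlockGrouping,
    PermutationError,
    SignedPermutation,
    breakpoints,
    collapse_common_adjacencies,
    identity,
    relabel_pair,
)

KINDS = (
    "transposition",
    "inverted_transposition",
    "block_interchange",
    "inverted_block_interchange",
)


@dataclass(frozen=True)
class RearrangementEvent:
    """One typed rearrangement event on a (collapsed) permutation.

    ``positions`` are 1-based interior positions at detection time: ``(i,)``
    for the adjacent-swap kinds (blocks at i and i+1), ``(i, k)`` for the
    interchange kinds, ``(i, j)`` for inversions.  ``blocks`` carries the
    original (pre-merge, pre-relabel) signed block labels of the operands,
    one tuple per operand.  ``sign_detail`` says which operand's sign the
    event flips ("first", "second", "both", or "" for the plain kinds).
    """

    kind: str
    positions: tuple[int, ...]
    blocks: tuple[tuple[int, ...], ...] = ()
    sign_detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS + ("inversion",):
            raise ValueError(f"unknown event kind {self.kind!r}")


def _consecutive_run(window: tuple[int, ...]) -> bool:
    """True iff the signed values read v, v+1, ..., all on the same strand.

    Covers +q +(q+1) ... and the negative mirror -(q+k) ... -q, which also
    ascends by 1 in signed value.  Caps (0 and n+1) count as forward-strand.
    """
    if any(b != a + 1 for a, b in zip(window, window[1:])):
        return False
    return all(x >= 0 for x in window) or all(x < 0 for x in window)


# ---------------------------------------------------------------------------
# Detection on a capped permutation
# ---------------------------------------------------------------------------

def find_independent_transpositions(perm: SignedPermutation) -> list[RearrangementEvent]:
    """Positions i where swapping blocks i and i+1 yields a 4-run."""
    c = perm.capped()
    out = []
    for i in range(1, perm.n):           # window c[i-1 .. i+2]
        w0, w1, w2, w3 = c[i - 1:i + 3]
        if _consecutive_run((w0, w2, w1, w3)):
            out.append(RearrangementEvent("transposition", (i,)))
    return out


def find_independent_inverted_transpositions(
    perm: SignedPermutation,
) -> list[RearrangementEvent]:
    """Adjacent swaps that additionally restore one operand's sign."""
    c = perm.capped()
    out = []
    for i in range(1, perm.n):
        w0, w1, w2, w3 = c[i - 1:i + 3]
        # pattern 1: current reads pi_{i-1} -pi_{i+1} pi_i pi_{i+2}
        if _consecutive_run((w0, w2, -w1, w3)):
            out.append(RearrangementEvent(
                "inverted_transposition", (i,), sign_detail="first"))
        # pattern 2: current reads pi_{i-1} pi_{i+1} -pi_i pi_{i+2}
        elif _consecutive_run((w0, -w2, w1, w3)):
            out.append(RearrangementEvent(
                "inverted_transposition", (i,), sign_detail="second"))
    return out


def find_independent_block_interchanges(
    perm: SignedPermutation,
) -> list[RearrangementEvent]:
    """Separated single-block swaps (i, k), k >= i+2, resolving both triples."""
    c = list(perm.capped())
    out = []
    for i in range(1, perm.n - 1):
        for k in range(i + 2, perm.n + 1):
            c[i], c[k] = c[k], c[i]
            ok = (_consecutive_run(tuple(c[i - 1:i + 2]))
                  and _consecutive_run(tuple(c[k - 1:k + 2])))
            c[i], c[k] = c[k], c[i]
            if ok:
                out.append(RearrangementEvent("block_interchange", (i, k)))
    return out


def find_independent_inverted_block_interchanges(
    perm: SignedPermutation,
) -> list[RearrangementEvent]:
    """Separated swaps with both signs restored: current reads
    ... pi_{i-1} -pi_k ... -pi_i pi_{k+1} ..."""
    c = list(perm.capped())
    out = []
    for i in range(1, perm.n - 1):
        for k in range(i + 2, perm.n + 1):
            c[i], c[k] = -c[k], -c[i]
            ok = (_consecutive_run(tuple(c[i - 1:i + 2]))
                  and _consecutive_run(tuple(c[k - 1:k + 2])))
            c[i], c[k] = -c[k], -c[i]
            if ok:
                out.append(RearrangementEvent(
                    "inverted_block_interchange", (i, k), sign_detail="both"))
    return out


_FINDERS: tuple[tuple[str, Callable], ...] = (
    ("transposition", find_independent_transpositions),
    ("inverted_transposition", find_independent_inverted_transpositions),
    ("block_interchange", find_independent_block_interchanges),
    ("inverted_block_interchange", find_independent_inverted_block_interchanges),
)

# breakpoints resolved per event kind
BREAKPOINT_DELTA = {
    "transposition": 3,
    "inverted_transposition": 3,
    "block_interchange": 4,
    "inverted_block_interchange": 4,
}


def apply_event(perm: SignedPermutation, event: RearrangementEvent) -> SignedPermutation:
    """Apply the resolving swap of an independent event."""
    e = list(perm.elements)
    if event.kind == "transposition":
        i = event.positions[0]
        e[i - 1], e[i] = e[i], e[i - 1]
    elif event.kind == "inverted_transposition":
        i = event.positions[0]
        if event.sign_detail == "first":
            e[i - 1], e[i] = e[i], -e[i - 1]
        else:
            e[i - 1], e[i] = -e[i], e[i - 1]
    elif event.kind == "block_interchange":
        i, k = event.positions
        e[i - 1], e[k - 1] = e[k - 1], e[i - 1]
    elif event.kind == "inverted_block_interchange":
        i, k = event.positions
        e[i - 1], e[k - 1] = -e[k - 1], -e[i - 1]
    else:
        raise ValueError(f"cannot apply event of kind {event.kind!r}")
    return SignedPermutation(tuple(e))


# ---------------------------------------------------------------------------
# Elimination loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EliminationResult:
    """Outcome of the pre-inversion event elimination on a pair."""

    source: SignedPermutation        # reduced source, in reduced labels
    target: SignedPermutation        # identity on the reduced label set
    events: tuple[RearrangementEvent, ...]
    label_map: tuple[tuple[int, ...], ...]
    # label_map[k] = original signed labels merged into reduced block k+1,
    # in the target's reading direction

    @property
    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in KINDS}
        for ev in self.events:
            out[ev.kind] += 1
        return out

    @property
    def r_d(self) -> int:
        """Count of eliminated independent events (the R_d statistic)."""
        return len(self.events)

    def expand_label(self, signed_reduced: int) -> tuple[int, ...]:
        run = self.label_map[abs(signed_reduced) - 1]
        return run if signed_reduced > 0 else tuple(-x for x in reversed(run))


def eliminate_independent_events(
    source: SignedPermutation, target: SignedPermutation
) -> EliminationResult:
    """Collapse common adjacencies, then repeatedly detect and apply
    independent events until none remains.

    Scan order is fixed for determinism: transposition, then inverted
    transposition, then block interchange, then inverted block interchange,
    leftmost occurrence first.  Every applied transposition kind must reduce
    the breakpoint count by exactly 3 and every interchange kind by exactly
    4; this is asserted.

    Events transform ``source`` toward ``target``.  Block labels attached to
    events are the original labels of ``target``'s frame (tuples, since a
    collapsed block may cover a merged run).
    """
    if sorted(abs(e) for e in source.elements) != sorted(
            abs(e) for e in target.elements):
        raise PermutationError("source and target are over different block sets")
    if len({abs(e) for e in source.elements}) != source.n:
        raise PermutationError("duplicated blocks: deduplicate upstream")

    # work in the target's frame: target -> identity
    _, current = relabel_pair(target, source)
    # label_map: reduced id -> original signed labels (target frame ids map
    # 1:1 to target's original labels)
    label_map: list[tuple[int, ...]] = [(e,) for e in target.elements]
    events: list[RearrangementEvent] = []

    while True:
        ident, current, grouping = collapse_common_adjacencies(
            identity(current.n), current)
        # compose grouping with accumulated label map
        new_map: list[tuple[int, ...]] = []
        for run in grouping.runs:
            merged: list[int] = []
            for old in run:
                prev = label_map[abs(old) - 1]
                merged.extend(prev if old > 0 else tuple(-x for x in reversed(prev)))
            new_map.append(tuple(merged))
        label_map = new_map

        found: RearrangementEvent | None = None
        for _, finder in _FINDERS:
            hits = finder(current)
            if hits:
                found = hits[0]
                break
        if found is None:
            break

        # attach original labels of the operands
        if len(found.positions) == 1:
            i = found.positions[0]
            ops = (current[i], current[i + 1])
        else:
            i, k = found.positions
            ops = (current[i], current[k])
        labeled = RearrangementEvent(
            kind=found.kind,
            positions=found.positions,
            blocks=tuple(
                tuple(label_map[abs(o) - 1]) if o > 0
                else tuple(-x for x in reversed(label_map[abs(o) - 1]))
                for o in ops),
            sign_detail=found.sign_detail,
        )
        before = breakpoints(current)
        current = apply_event(current, found)
        delta = before - breakpoints(current)
        expected = BREAKPOINT_DELTA[found.kind]
        if delta != expected:  # pragma: no cover - guarded by detection patterns
            raise AssertionError(
                f"{found.kind} removed {delta} breakpoints, expected {expected}")
        events.append(labeled)

    return EliminationResult(
        source=current,
        target=identity(current.n),
        events=tuple(events),
        label_map=tuple(label_map),
    )
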