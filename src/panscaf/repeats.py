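"""Inverted/direct repeat detection at rearrangement breakpoints.

Long bacterial inversions are typically mediated by recombination between a
pair of Inverted Repeats (IRs, usually IS elements): the sequence between
the two repeat copies is reverse-complemented while the copies themselves
and everything outside them stay unchanged.  Transposition-like events show
the same end-conservation with *direct* repeat copies at their junctions.

This module extracts sequence windows around breakpoints, finds IR/DR pairs
between windows with a seed-and-extend strategy (exact k-mer seeds, banded
edit-distance verification via edlib), locates repeat occurrences across
strains, and summarizes how often inversions are repeat-flanked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .events import RearrangementEvent
from .scaffold import Scaffold

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh",
                            "TGCAYRMKVBHDtgcayrmkvbhd")
_VALID = set("ACGTNRYKMSWBVDH")


class SequenceError(ValueError):
    """Sequence contains characters outside the IUPAC nucleotide set."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check(seq: str, name: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise SequenceError(f"{name} contains non-nucleotide characters {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointWindow:
    """Sequence slice around one side of a rearrangement breakpoint."""

    strain: str
    side: str                      # 'left' or 'right' (or a junction tag)
    start: int                     # 0-based half-open, on the strain genome
    end: int
    sequence: str


@dataclass(frozen=True)
class RepeatPair:
    """Two repeat copies with orientation, length, and identity.

    ``occ1``/``occ2`` are (start, end, strand) intervals, each relative to
    the window (or genome) it was found in; orientation is 'inverted' when
    the strands differ, 'direct' when equal.
    """

    label: str
    occ1: tuple[int, int, str]
    occ2: tuple[int, int, str]
    orientation: str
    length: int
    identity: float

    def __post_init__(self) -> None:
        strands_differ = self.occ1[2] != self.occ2[2]
        assert (self.orientation == "inverted") == strands_differ


@dataclass
class FlankReport:
    """Repeat-flanking verdict for one inversion call."""

    length_bp: int | None
    long_inversion: bool
    ir_found: bool
    repeat: RepeatPair | None = None
    presence_code: int | None = None   # 0 source only / 1 closest only / 2 both


# ---------------------------------------------------------------------------
# Breakpoint windows
# ---------------------------------------------------------------------------

def _scaffold_positions(scaffold: Scaffold) -> dict[int, int]:
    return {abs(e): idx for idx, e in enumerate(scaffold.elements)}


def inversion_breakpoint_windows(
    start_block: int,
    end_block: int,
    scaffold: Scaffold,
    genome: str,
    margin: int = 2000,
    cap: int = 20000,
) -> tuple[BreakpointWindow, BreakpointWindow]:
    """Windows at the two ends of an inversion segment.

    The segment runs from ``start_block`` to ``end_block`` (signed labels in
    the scaffold).  The left window spans from (end of the preceding core
    block - margin) to (start of the first inverted block + margin); the
    right window is symmetric.  Windows are clipped to ``cap`` bp and to the
    genome bounds.
    """
    if not scaffold.coordinates:
        raise ValueError("scaffold carries no coordinates")
    pos = _scaffold_positions(scaffold)
    try:
        p1, p2 = pos[abs(start_block)], pos[abs(end_block)]
    except KeyError as exc:
        raise ValueError(f"block {exc} missing from scaffold") from exc
    if p1 > p2:
        p1, p2 = p2, p1
    coords = scaffold.coordinates

    left_anchor = coords[p1 - 1][2] if p1 > 0 else 0          # end of previous block
    left_lo = max(0, left_anchor - margin)
    left_hi = min(len(genome), coords[p1][1] + margin)        # start of first block
    right_anchor = coords[p2][2]                              # end of last block
    right_lo = max(0, right_anchor - margin)
    right_hi = min(len(genome),
                   (coords[p2 + 1][1] if p2 + 1 < len(coords) else len(genome))
                   + margin)
    right_hi = min(right_hi, len(genome))

    def clip(lo: int, hi: int) -> tuple[int, int]:
        if hi - lo > cap:
            mid = (lo + hi) // 2
            lo, hi = mid - cap // 2, mid + cap // 2
        return max(0, lo), min(len(genome), hi)

    left_lo, left_hi = clip(left_lo, left_hi)
    right_lo, right_hi = clip(right_lo, right_hi)
    return (
        BreakpointWindow(scaffold.strain, "left", left_lo, left_hi,
                         genome[left_lo:left_hi]),
        BreakpointWindow(scaffold.strain, "right", right_lo, right_hi,
                         genome[right_lo:right_hi]),
    )


# ---------------------------------------------------------------------------
# Seed-and-extend repeat detection
# ---------------------------------------------------------------------------

def _seed_hits(a: str, b: str, k: int) -> dict[int, list[tuple[int, int]]]:
    """Exact k-mer matches grouped by diagonal (pos_a - pos_b)."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i:i + k], []).append(i)
    diags: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(b) - k + 1):
        for i in index.get(b[j:j + k], ()):
            diags.setdefault(i - j, []).append((i, j))
    return diags


def _best_match(
    a: str, b: str, min_len: int, min_id: float, seed_k: int
) -> tuple[int, int, int, int, float] | None:
    """Highest-scoring gapless-seeded, banded-verified match of a vs b.

    Returns (a_start, a_end, b_start, b_end, identity) or None.  Seeds on a
    common diagonal (within a small band) are chained; the chained span is
    verified with edlib's edit distance (NW over the two spans).
    """
    if min(len(a), len(b)) < max(min_len, seed_k):
        return None
    diags = _seed_hits(a, b, seed_k)
    if not diags:
        return None
    # cluster diagonals within a band of 32 bp
    band = 32
    items = sorted(diags.items())
    clusters: list[list[tuple[int, int]]] = []
    last_d = None
    for d, hits in items:
        if last_d is not None and d - last_d <= band:
            clusters[-1].extend(hits)
        else:
            clusters.append(list(hits))
        last_d = d
    best = None
    for hits in clusters:
        a_lo = min(h[0] for h in hits)
        a_hi = max(h[0] for h in hits) + seed_k
        b_lo = min(h[1] for h in hits)
        b_hi = max(h[1] for h in hits) + seed_k
        span_a, span_b = a[a_lo:a_hi], b[b_lo:b_hi]
        if min(len(span_a), len(span_b)) < min_len:
            continue
        res = edlib.align(span_a, span_b, task="distance")
        aln_len = max(len(span_a), len(span_b))
        ident = 1.0 - res["editDistance"] / aln_len
        if ident < min_id:
            continue
        cand = (a_lo, a_hi, b_lo, b_hi, ident)
        if best is None or (aln_len * ident) > (
                max(best[1] - best[0], best[3] - best[2]) * best[4]):
            best = cand
    return best


def find_inverted_repeat(
    left: str,
    right: str,
    min_len: int = 50,
    min_id: float = 0.90,
    seed_k: int = 15,
    label: str = "",
) -> RepeatPair | None:
    """Best inverted-repeat pair between two breakpoint windows.

    The left window is compared against the reverse complement of the
    right; coordinates of the second occurrence are reported on the right
    window's forward strand.
    """
    if not left or not right:
        return None
    left, right = _check(left, "left"), _check(right, "right")
    hit = _best_match(left, revcomp(right), min_len, min_id, seed_k)
    if hit is None:
        return None
    a_lo, a_hi, b_lo, b_hi, ident = hit
    r_lo, r_hi = len(right) - b_hi, len(right) - b_lo
    return RepeatPair(
        label=label,
        occ1=(a_lo, a_hi, "+"),
        occ2=(r_lo, r_hi, "-"),
        orientation="inverted",
        length=max(a_hi - a_lo, r_hi - r_lo),
        identity=ident,
    )


def find_direct_repeat(
    left: str,
    right: str,
    min_len: int = 50,
    min_id: float = 0.90,
    seed_k: int = 15,
    label: str = "",
) -> RepeatPair | None:
    """Best same-strand repeat pair between two windows."""
    if not left or not right:
        return None
    left, right = _check(left, "left"), _check(right, "right")
    hit = _best_match(left, right, min_len, min_id, seed_k)
    if hit is None:
        return None
    a_lo, a_hi, b_lo, b_hi, ident = hit
    return RepeatPair(
        label=label,
        occ1=(a_lo, a_hi, "+"),
        occ2=(b_lo, b_hi, "+"),
        orientation="direct",
        length=max(a_hi - a_lo, b_hi - b_lo),
        identity=ident,
    )


def locate_repeat_occurrences(
    repeat: str,
    genomes: Mapping[str, str],
    min_id: float = 0.90,
    seed_k: int = 15,
) -> list[tuple[str, tuple[int, int], str]]:
    """All approximate occurrences of a repeat, both strands, every strain.

    Candidate loci are anchored with exact k-mer seeds and verified with an
    infix (semi-global) edlib alignment at the identity threshold.
    Overlapping candidates are merged, keeping one call per locus.
    """
    repeat = _check(repeat, "repeat")
    max_ed = int((1.0 - min_id) * len(repeat))
    out: list[tuple[str, tuple[int, int], str]] = []
    for strain, genome in genomes.items():
        genome = genome.upper()
        for strand, query in (("+", repeat), ("-", revcomp(repeat))):
            hits = _seed_hits(genome, query, seed_k)
            # diagonal d = genome_pos - query_pos is the implied genome start
            merged: list[int] = []
            for s in sorted(hits):
                if merged and s - merged[-1] < len(repeat) // 2:
                    continue
                merged.append(s)
            for s in merged:
                lo = max(0, s - max_ed - 8)
                hi = min(len(genome), s + len(repeat) + max_ed + 8)
                res = edlib.align(query, genome[lo:hi], mode="HW",
                                  task="locations", k=max_ed)
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                out.append((strain, (lo + loc[0], lo + loc[1] + 1), strand))
    # dedup per strain/locus (both strands can report palindromes once each)
    dedup: list[tuple[str, tuple[int, int], str]] = []
    for hit in sorted(out):
        if any(h[0] == hit[0] and h[2] == hit[2]
               and abs(h[1][0] - hit[1][0]) < len(repeat) // 2 for h in dedup):
            continue
        dedup.append(hit)
    return dedup


# ---------------------------------------------------------------------------
# Event-end conservation
# ---------------------------------------------------------------------------

def check_event_ends(
    event: RearrangementEvent,
    windows: Sequence[BreakpointWindow],
    min_len: int = 50,
    min_id: float = 0.90,
    seed_k: int = 15,
) -> dict:
    """Repeat report for the junctions of a transposition-like event.

    Transposition-kind events have 3 junctions, interchange-kind events 4.
    Junction windows are compared pairwise — direct-orientation for plain
    transpositions, both orientations for the inverted kinds — and the
    report says whether every junction carries a shared repeat.
    """
    expected = 3 if event.kind in ("transposition", "inverted_transposition") else 4
    if event.kind == "inversion":
        expected = 2
    if len(windows) != expected:
        raise ValueError(
            f"{event.kind} has {expected} junctions, got {len(windows)} windows")

    pair_hits: dict[tuple[int, int], RepeatPair] = {}
    for a in range(len(windows)):
        for b in range(a + 1, len(windows)):
            wa, wb = windows[a].sequence, windows[b].sequence
            hit = find_direct_repeat(wa, wb, min_len, min_id, seed_k)
            if hit is None and event.kind.startswith("inverted"):
                hit = find_inverted_repeat(wa, wb, min_len, min_id, seed_k)
            if hit is not None:
                pair_hits[(a, b)] = hit
    covered = set()
    for (a, b) in pair_hits:
        covered.update((a, b))
    return {
        "kind": event.kind,
        "junctions": expected,
        "pair_hits": pair_hits,
        "junctions_covered": sorted(covered),
        "all_ends_conserved": len(covered) == expected,
    }


def summarize_prevalence(
    reports: Iterable[FlankReport], long_threshold: int = 10000
) -> dict:
    """Counts of inversions and IR-flanked inversions, split at the
    long-inversion threshold (default 10 kb)."""
    reports = list(reports)
    n = len(reports)
    flanked = sum(1 for r in reports if r.ir_found)
    long_reports = [r for r in reports
                    if r.length_bp is not None and r.length_bp > long_threshold]
    long_flanked = sum(1 for r in long_reports if r.ir_found)
    return {
        "inversions": n,
        "ir_flanked": flanked,
        "long_inversions": len(long_reports),
        "long_ir_flanked": long_flanked,
        "long_fraction_flanked": (long_flanked / len(long_reports)
                                  if long_reports else None),
        "long_threshold": long_threshold,
    }


def occurrences_to_bed(
    occurrences: Iterable[tuple[str, tuple[int, int], str]],
    label: str,
    identity: float = 1.0,
) -> str:
    """BED6 lines for repeat occurrences (score = identity x 1000)."""
    lines = []
    score = int(round(identity * 1000))
    for strain, (start, end), strand in occurrences:
        lines.append(f"{strain}\t{start}\t{end}\t{label}\t{score}\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")
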