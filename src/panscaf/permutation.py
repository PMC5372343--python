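"""Signed permutations, breakpoint graphs, and common-adjacency merging.

A bacterial core-genome scaffold is modelled as a *signed permutation*: an
ordering of the n core blocks in which block i appears exactly once as +i
(forward strand) or -i (reverse strand).  All rearrangement mathematics in
this package — inversion distance, independent-event detection — is carried
out on this representation.

Conventions
-----------
* Permutations are linear.  For adjacency and breakpoint bookkeeping they are
  *capped* with sentinels +0 on the left and +(n+1) on the right, which makes
  adjacencies at the two chromosome ends first-class.
* Positions inside a permutation are 1-based (position 1 .. n); the caps sit
  at positions 0 and n+1.
* An adjacency (a, b) between consecutive capped elements is *conserved* iff
  b == a + 1 in signed notation (this covers both +i,+(i+1) and
  -(i+1),-i read-throughs); otherwise it is a *breakpoint*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


class PermutationError(ValueError):
    """Invalid permutation input (bad block set, out-of-range position...)."""


# ---------------------------------------------------------------------------
# SignedPermutation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedPermutation:
    """An ordering of blocks 1..n, each with a + or - orientation.

    ``elements`` holds nonzero signed integers; ``abs`` values are exactly
    the set {1..n}.
    """

    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        elems = tuple(int(e) for e in self.elements)
        object.__setattr__(self, "elements", elems)
        n = len(elems)
        if n == 0:
            raise PermutationError("empty permutation")
        if any(e == 0 for e in elems):
            raise PermutationError("0 is reserved for the left cap")
        if sorted(abs(e) for e in elems) != list(range(1, n + 1)):
            raise PermutationError(
                f"elements {elems} are not a signed permutation of 1..{n}"
            )

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[int]:
        return iter(self.elements)

    def __getitem__(self, pos: int) -> int:
        """1-based access: perm[1] is the first block."""
        if not 1 <= pos <= self.n:
            raise PermutationError(f"position {pos} out of range 1..{self.n}")
        return self.elements[pos - 1]

    def __str__(self) -> str:
        return " ".join(f"{e:+d}" for e in self.elements)

    # -- derived views -----------------------------------------------------
    def capped(self) -> tuple[int, ...]:
        """Extended sequence +0, pi_1..pi_n, +(n+1)."""
        return (0, *self.elements, self.n + 1)

    def is_identity(self) -> bool:
        return self.elements == tuple(range(1, self.n + 1))

    def inverse_position(self) -> dict[int, tuple[int, int]]:
        """Map block id -> (1-based position, sign)."""
        return {abs(e): (p, 1 if e > 0 else -1)
                for p, e in enumerate(self.elements, start=1)}


def identity(n: int) -> SignedPermutation:
    """The reference scaffold +1 +2 ... +n."""
    if n < 1:
        raise PermutationError(f"n must be >= 1, got {n}")
    return SignedPermutation(tuple(range(1, n + 1)))


def apply_inversion(perm: SignedPermutation, i: int, j: int) -> SignedPermutation:
    """Reverse positions i..j (1-based, inclusive) and flip their signs.

    This is the elementary reversal operation; applying the same (i, j)
    twice returns the input.
    """
    if not (1 <= i <= j <= perm.n):
        raise PermutationError(
            f"inversion ({i},{j}) out of range for n={perm.n}")
    e = perm.elements
    middle = tuple(-x for x in reversed(e[i - 1:j]))
    return SignedPermutation(e[:i - 1] + middle + e[j:])


def breakpoints(perm: SignedPermutation) -> int:
    """Number of capped adjacencies (a, b) with b != a + 1."""
    c = perm.capped()
    return sum(1 for a, b in zip(c, c[1:]) if b != a + 1)


# ---------------------------------------------------------------------------
# Breakpoint graph
# ---------------------------------------------------------------------------

def _doubled(perm: SignedPermutation) -> tuple[int, ...]:
    """Unsigned doubling with caps.

    +x contributes (2x-1, 2x), -x contributes (2x, 2x-1); the left cap is
    vertex 0 and the right cap vertex 2n+1.  Length is 2n+2.
    """
    out = [0]
    for e in perm.elements:
        x = abs(e)
        out.extend((2 * x - 1, 2 * x) if e > 0 else (2 * x, 2 * x - 1))
    out.append(2 * perm.n + 1)
    return tuple(out)


@dataclass(frozen=True)
class BreakpointGraph:
    """Black/gray edge structure of a permutation vs the identity.

    Vertices are 0..2n+1 from the standard signed->unsigned doubling.  Black
    edges encode the permutation's capped adjacencies, gray edges the
    identity's.  ``cycles`` is the partition of edges into alternating
    cycles; each entry lists the vertices of one cycle.
    """

    n: int
    vertices: tuple[int, ...]            # doubled sequence, index = position
    black_edges: tuple[tuple[int, int], ...]
    gray_edges: tuple[tuple[int, int], ...]
    cycles: tuple[tuple[int, ...], ...]  # vertex sets, one per cycle

    @property
    def cycle_edge_counts(self) -> tuple[int, ...]:
        """Edges per cycle (a cycle over k vertices has k edges)."""
        return tuple(len(c) for c in self.cycles)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_trivial_cycles(self) -> int:
        """2-edge cycles, i.e. conserved adjacencies."""
        return sum(1 for c in self.cycles if len(c) == 2)


def breakpoint_graph(perm: SignedPermutation) -> BreakpointGraph:
    """Build the breakpoint graph of ``perm`` against the identity."""
    n = perm.n
    u = _doubled(perm)
    # black edges join positions (2p, 2p+1), p = 0..n
    black = tuple((u[2 * p], u[2 * p + 1]) for p in range(n + 1))
    gray = tuple((2 * i, 2 * i + 1) for i in range(n + 1))

    black_of = {}
    gray_of = {}
    for a, b in black:
        black_of[a] = b
        black_of[b] = a
    for a, b in gray:
        gray_of[a] = b
        gray_of[b] = a

    seen: set[int] = set()
    cycles: list[tuple[int, ...]] = []
    for start in range(2 * n + 2):
        if start in seen:
            continue
        cyc = []
        v, use_black = start, True
        while v not in seen:
            seen.add(v)
            cyc.append(v)
            v = black_of[v] if use_black else gray_of[v]
            use_black = not use_black
        cycles.append(tuple(cyc))
    return BreakpointGraph(n=n, vertices=u, black_edges=black,
                           gray_edges=gray, cycles=tuple(cycles))


# ---------------------------------------------------------------------------
# Common-adjacency merging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockGrouping:
    """Record of a merge: new block id -> ordered run of old signed ids.

    The run is stored in the orientation of the *first* (reference) input,
    so applying the grouping to the reference reads forward.
    """

    runs: tuple[tuple[int, ...], ...]    # runs[k] = old signed ids of new id k+1

    def expand(self, signed_new: int) -> tuple[int, ...]:
        """Old signed ids for a signed new id (reversed+negated if negative)."""
        run = self.runs[abs(signed_new) - 1]
        if signed_new > 0:
            return run
        return tuple(-x for x in reversed(run))


def _signed_adjacencies(perm: SignedPermutation) -> set[tuple[int, int]]:
    """All conserved-readable ordered pairs of consecutive elements
    (each adjacency contributes both (u, v) and (-v, -u))."""
    out: set[tuple[int, int]] = set()
    e = perm.elements
    for u, v in zip(e, e[1:]):
        out.add((u, v))
        out.add((-v, -u))
    return out


def relabel_pair(
    a: SignedPermutation, b: SignedPermutation
) -> tuple[SignedPermutation, SignedPermutation]:
    """Rename blocks so that ``a`` becomes the identity; ``b`` is rewritten
    in the same frame.  Distances and adjacencies are invariant under this."""
    if a.n != b.n:
        raise PermutationError("permutations have different sizes")
    mapping = a.inverse_position()          # block -> (new id, sign)
    if set(mapping) != {abs(e) for e in b.elements}:
        raise PermutationError("permutations are over different block sets")
    new_b = []
    for e in b.elements:
        pos, sign = mapping[abs(e)]
        new_b.append(pos * sign * (1 if e > 0 else -1))
    return identity(a.n), SignedPermutation(tuple(new_b))


def collapse_common_adjacencies(
    a: SignedPermutation, b: SignedPermutation
) -> tuple[SignedPermutation, SignedPermutation, BlockGrouping]:
    """Maximally merge blocks that are adjacent, with consistent relative
    orientation, in *both* permutations; renumber so ``a`` maps to the
    identity.

    Two consecutive elements (u, v) of ``a`` fuse iff ``b`` also reads u
    immediately followed by v, or -v immediately followed by -u.  Merging is
    run to fixpoint by grouping maximal runs in a single left-to-right scan
    of ``a`` (adjacencies between merged blocks reduce to adjacencies of
    their border elements, so one scan is already maximal).

    Returns ``(a', b', grouping)`` where ``a'`` is the identity on the
    merged block set and ``grouping`` maps each new id to its run of old
    signed ids (in ``a``'s reading direction).
    """
    if a.n != b.n or {abs(e) for e in a.elements} != {abs(e) for e in b.elements}:
        raise PermutationError("permutations are over different block sets")
    common = _signed_adjacencies(a) & _signed_adjacencies(b)

    runs: list[list[int]] = []
    for e in a.elements:
        if runs and (runs[-1][-1], e) in common:
            runs[-1].append(e)
        else:
            runs.append([e])

    grouping = BlockGrouping(tuple(tuple(r) for r in runs))
    m = len(runs)
    a_new = identity(m)

    # rewrite b: each run occurs contiguously, forward or reversed+negated
    first_of = {}   # first old signed element of each run -> (new id, +1)
    last_of = {}    # negated last element -> (new id, -1)
    length_of = {}
    for k, r in enumerate(grouping.runs, start=1):
        first_of[r[0]] = k
        last_of[-r[-1]] = k
        length_of[k] = len(r)

    b_new: list[int] = []
    i = 0
    be = b.elements
    while i < b.n:
        e = be[i]
        if e in first_of:
            k = first_of[e]
            run = grouping.runs[k - 1]
            if tuple(be[i:i + len(run)]) != run:
                raise PermutationError(
                    "inconsistent common adjacencies (duplicate block ids?)")
            b_new.append(k)
            i += len(run)
        elif e in last_of:
            k = last_of[e]
            run = tuple(-x for x in reversed(grouping.runs[k - 1]))
            if tuple(be[i:i + len(run)]) != run:
                raise PermutationError(
                    "inconsistent common adjacencies (duplicate block ids?)")
            b_new.append(-k)
            i += len(run)
        else:  # pragma: no cover - unreachable for valid permutations
            raise PermutationError(f"element {e} does not start any run")
    return a_new, SignedPermutation(tuple(b_new)), grouping


# ---------------------------------------------------------------------------
# GRIMM-style plain-text permutation format
# ---------------------------------------------------------------------------

def write_grimm(perms: dict[str, SignedPermutation]) -> str:
    """Serialize named permutations: '>name' header, signed ints, '$'."""
    chunks = []
    for name, perm in perms.items():
        chunks.append(f">{name}\n{perm} $\n")
    return "".join(chunks)


def read_grimm(text: str) -> dict[str, SignedPermutation]:
    """Parse the GRIMM-style stanza format written by :func:`write_grimm`.

    The '$' terminator is optional; blank lines are ignored.
    """
    perms: dict[str, SignedPermutation] = {}
    name: str | None = None
    acc: list[int] = []

    def flush() -> None:
        if name is not None:
            if not acc:
                raise PermutationError(f"genome {name!r} has no blocks")
            perms[name] = SignedPermutation(tuple(acc))

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            acc = []
            continue
        if name is None:
            raise PermutationError("permutation data before any '>' header")
        for tok in line.replace("$", " ").split():
            acc.append(int(tok))
    flush()
    return perms
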