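"""Exact minimum-inversion (reversal) distance and optimal scenarios.

The distance of a signed permutation pi to the identity follows the
breakpoint-graph theory of sorting by reversals:

    d(pi) = (n + 1) - c(pi) + h(pi) + f(pi)

where c is the number of alternating cycles of the breakpoint graph of the
capped permutation, h the number of hurdles (unoriented components that do
not separate other unoriented components), and f is 1 iff the permutation is
a fortress (an odd number of hurdles, all of them superhurdles).

The module also ships a breadth-first-search oracle over the full reversal
move graph; the analytic distance is contractually equal to it (the test
suite checks this exhaustively for small n).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .permutation import (
    PermutationError,
    SignedPermutation,
    apply_inversion,
    identity,
    relabel_pair,
    _doubled,
)


@dataclass(frozen=True)
class DistanceDetail:
    """Exact distance with its breakpoint-graph decomposition."""

    distance: int
    cycles: int
    hurdles: int
    fortress: int
    n: int

    def __post_init__(self) -> None:
        assert self.distance == (self.n + 1) - self.cycles + self.hurdles + self.fortress


@dataclass(frozen=True)
class InversionScenario:
    """Ordered (i, j) reversal steps transforming a source into a target.

    Steps are expressed on the evolving source frame: step t applies to the
    permutation produced by steps 1..t-1.
    """

    steps: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.steps)

    def apply(self, perm: SignedPermutation) -> SignedPermutation:
        for i, j in self.steps:
            perm = apply_inversion(perm, i, j)
        return perm


# ---------------------------------------------------------------------------
# Hannenhalli-Pevzner machinery
# ---------------------------------------------------------------------------

def _graph_structure(perm: SignedPermutation):
    """Cycles and gray-edge geometry of the breakpoint graph.

    Returns (n_cycles, components) where each component is a dict with keys
    ``oriented`` (bool) and ``span`` = (min position, max position) over its
    gray-edge endpoints.  Trivial components (single conserved adjacency)
    are excluded.
    """
    n = perm.n
    u = _doubled(perm)
    pos = {v: p for p, v in enumerate(u)}

    black_of = {}
    for p in range(n + 1):
        a, b = u[2 * p], u[2 * p + 1]
        black_of[a] = b
        black_of[b] = a
    gray_of = {}
    for i in range(n + 1):
        gray_of[2 * i] = 2 * i + 1
        gray_of[2 * i + 1] = 2 * i

    # cycle id per vertex
    cycle_of: dict[int, int] = {}
    n_cycles = 0
    for start in range(2 * n + 2):
        if start in cycle_of:
            continue
        v, use_black = start, True
        while v not in cycle_of:
            cycle_of[v] = n_cycles
            v = black_of[v] if use_black else gray_of[v]
            use_black = not use_black
        n_cycles += 1

    # gray edges as position intervals; trivial ones span adjacent positions
    edges = []  # (lo, hi, oriented, cycle id)
    for i in range(n + 1):
        p1, p2 = pos[2 * i], pos[2 * i + 1]
        lo, hi = min(p1, p2), max(p1, p2)
        if hi == lo + 1:            # conserved adjacency, trivial cycle
            continue
        oriented = (p1 + p2) % 2 == 0
        edges.append((lo, hi, oriented, cycle_of[2 * i]))

    # union cycles whose gray edges interleave
    parent = list(range(n_cycles))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for a in range(len(edges)):
        lo1, hi1, _, c1 = edges[a]
        for b in range(a + 1, len(edges)):
            lo2, hi2, _, c2 = edges[b]
            if (lo1 < lo2 < hi1 < hi2) or (lo2 < lo1 < hi2 < hi1):
                union(c1, c2)

    comps: dict[int, dict] = {}
    for lo, hi, oriented, c in edges:
        root = find(c)
        comp = comps.setdefault(root, {"oriented": False, "span": (lo, hi)})
        comp["oriented"] = comp["oriented"] or oriented
        s = comp["span"]
        comp["span"] = (min(s[0], lo), max(s[1], hi))
    return n_cycles, list(comps.values())


def _hurdle_set(spans: list[tuple[int, int]]) -> list[int]:
    """Indices of hurdles among unoriented-component spans.

    Spans of distinct components are nested or disjoint.  A hurdle is a
    minimal component (containing no other) or the greatest component (one
    containing all the others), i.e. a component that does not separate two
    other unoriented components.
    """
    hurdles = []
    k = len(spans)
    for i, (lo, hi) in enumerate(spans):
        contains = [j for j in range(k) if j != i
                    and lo <= spans[j][0] and spans[j][1] <= hi]
        if not contains:                     # minimal
            hurdles.append(i)
        elif len(contains) == k - 1:         # greatest
            hurdles.append(i)
    return hurdles


def _hurdles_fortress(components: list[dict]) -> tuple[int, int]:
    spans = [c["span"] for c in components if not c["oriented"]]
    if not spans:
        return 0, 0
    hurdle_idx = _hurdle_set(spans)
    h = len(hurdle_idx)
    if h % 2 == 0:
        return h, 0
    # fortress iff every hurdle is a superhurdle: deleting it does not
    # lower the hurdle count (a protecting non-hurdle becomes one).
    for i in hurdle_idx:
        rest = [s for j, s in enumerate(spans) if j != i]
        if len(_hurdle_set(rest)) < h:
            return h, 0
    return h, 1


def inversion_distance(perm: SignedPermutation) -> DistanceDetail:
    """Exact minimum number of inversions from ``perm`` to the identity."""
    n_cycles, components = _graph_structure(perm)
    h, f = _hurdles_fortress(components)
    d = (perm.n + 1) - n_cycles + h + f
    return DistanceDetail(distance=d, cycles=n_cycles, hurdles=h,
                          fortress=f, n=perm.n)


def pairwise_distance(a: SignedPermutation, b: SignedPermutation) -> DistanceDetail:
    """Inversion distance between two scaffolds over the same block set."""
    _, b_rel = relabel_pair(a, b)
    # d(a, b) = d(b expressed in a's frame, identity); symmetric by theory
    return inversion_distance(b_rel)


def optimal_scenario(a: SignedPermutation, b: SignedPermutation) -> InversionScenario:
    """A minimum-length inversion scenario transforming ``a`` into ``b``.

    Deterministic tie-break: at every step, among all inversions that
    decrease the remaining distance, the one with the smallest left
    position, then smallest right position, is applied.
    """
    _, source = relabel_pair(b, a)   # express a in b's frame; target = identity
    steps: list[tuple[int, int]] = []
    d = inversion_distance(source).distance
    while d > 0:
        found = False
        for i in range(1, source.n + 1):
            for j in range(i, source.n + 1):
                cand = apply_inversion(source, i, j)
                if inversion_distance(cand).distance == d - 1:
                    steps.append((i, j))
                    source, d, found = cand, d - 1, True
                    break
            if found:
                break
        if not found:  # pragma: no cover - impossible if the distance is exact
            raise RuntimeError("no distance-decreasing inversion found")
    return InversionScenario(tuple(steps))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_N = 8
_TABLE_MAX_N = 7


@lru_cache(maxsize=None)
def _moves(n: int) -> tuple[tuple[int, int], ...]:
    return tuple((i, j) for i in range(n) for j in range(i + 1, n + 1))


def _successors(state: tuple[int, ...], n: int):
    for i, j in _moves(n):
        yield state[:i] + tuple(-x for x in reversed(state[i:j])) + state[j:]


@lru_cache(maxsize=None)
def bfs_table(n: int) -> dict[tuple[int, ...], int]:
    """Distance-from-identity for every signed permutation of size n (n<=7),
    by breadth-first search over all n(n+1)/2 reversal moves."""
    if n > _TABLE_MAX_N:
        raise PermutationError(f"full BFS table limited to n<={_TABLE_MAX_N}")
    start = tuple(range(1, n + 1))
    dist = {start: 0}
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for s in frontier:
            for t in _successors(s, n):
                if t not in dist:
                    dist[t] = d
                    nxt.append(t)
        frontier = nxt
    return dist


def bfs_oracle(perm: SignedPermutation) -> int:
    """Exact distance by exhaustive breadth-first search (n <= 8 only)."""
    n = perm.n
    if n > _ORACLE_MAX_N:
        raise PermutationError(
            f"BFS oracle refuses n={n} > {_ORACLE_MAX_N} (state space too large)")
    state = perm.elements
    if n <= _TABLE_MAX_N:
        return bfs_table(n)[state]
    return _bidirectional_bfs(state, n)


def _bidirectional_bfs(state: tuple[int, ...], n: int) -> int:
    goal = tuple(range(1, n + 1))
    if state == goal:
        return 0
    fwd = {state: 0}
    bwd = {goal: 0}
    f_frontier, b_frontier = [state], [goal]
    while f_frontier and b_frontier:
        # expand the smaller side (reversals are involutions: same move set)
        if len(f_frontier) <= len(b_frontier):
            frontier, dist, other = f_frontier, fwd, bwd
            f_frontier = nxt = []
        else:
            frontier, dist, other = b_frontier, bwd, fwd
            b_frontier = nxt = []
        base = dist[frontier[0]]
        for s in frontier:
            for t in _successors(s, n):
                if t in other:
                    return base + 1 + other[t]
                if t not in dist:
                    dist[t] = base + 1
                    nxt.append(t)
    raise RuntimeError("reversal move graph is connected; unreachable")
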