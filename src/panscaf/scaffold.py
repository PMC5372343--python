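"""Per-strain core-genome scaffolds from a block map or MAF alignment.

The pipeline stages here mirror standard bacterial pan-genome practice:
alignment blocks are classified as core (present in every strain),
dispensable (a subset) or strain-specific (one strain); short core blocks
are discarded; core blocks that are consecutive with consistent orientation
in *every* strain are merged; each strain's ordered, signed sequence of
merged blocks is its scaffold; strains with identical scaffolds form
groups; and each group is compared against its closest group by inversion
distance after independent-event elimination.

Genomic coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .distance import DistanceDetail, optimal_scenario, pairwise_distance
from .events import EliminationResult, eliminate_independent_events
from .permutation import PermutationError, SignedPermutation, apply_inversion

BLOCKMAP_COLUMNS = ["strain", "block", "contig", "start", "end", "strand"]


class BlockMapError(ValueError):
    """Malformed or inconsistent block map input."""


# ---------------------------------------------------------------------------
# BlockMap
# ---------------------------------------------------------------------------

@dataclass
class BlockMap:
    """Table of block occurrences across strains.

    ``occurrences`` has columns strain, block, contig, start, end, strand.
    A block may occur several times in one strain (repeated copies).
    """

    occurrences: pd.DataFrame
    strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.occurrences
        missing = [c for c in BLOCKMAP_COLUMNS if c not in df.columns]
        if missing:
            raise BlockMapError(f"block map missing columns: {missing}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise BlockMapError("block map requires 0 <= start < end")
        if not self.strains:
            self.strains = tuple(sorted(df["strain"].unique()))

    # -- classification ----------------------------------------------------
    def classify(self) -> dict[int, str]:
        """Block -> core / dispensable / strain_specific by strain coverage."""
        n = len(self.strains)
        cover = self.occurrences.groupby("block")["strain"].nunique()
        out = {}
        for block, k in cover.items():
            if k == n:
                out[block] = "core"
            elif k == 1:
                out[block] = "strain_specific"
            else:
                out[block] = "dispensable"
        return out

    def core_blocks(self) -> list[int]:
        return sorted(b for b, c in self.classify().items() if c == "core")

    def core_only(self) -> "BlockMap":
        core = set(self.core_blocks())
        df = self.occurrences[self.occurrences["block"].isin(core)]
        return BlockMap(df.reset_index(drop=True), strains=self.strains)

    def block_length(self, block: int, strain: str) -> int:
        rows = self.occurrences
        sel = rows[(rows["block"] == block) & (rows["strain"] == strain)]
        if sel.empty:
            raise BlockMapError(f"block {block} absent from strain {strain}")
        return int((sel["end"] - sel["start"]).iloc[0])

    # -- serialization -----------------------------------------------------
    def to_tsv(self) -> str:
        return self.occurrences[BLOCKMAP_COLUMNS].to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "BlockMap":
        df = pd.read_csv(io.StringIO(text), sep="\t",
                         dtype={"strain": str, "contig": str, "strand": str})
        return cls(df)


def blocks_from_maf(text: str, strains: Sequence[str] | None = None) -> BlockMap:
    """Build a block map from a MAF multiple whole-genome alignment
    (the 'a'/'s' line dialect written by Mugsy).

    Each alignment block becomes one map block with an occurrence per
    participating strain.  The 's' source field is split at the first '.'
    into strain and contig; '-' strand starts are converted to
    forward-strand 0-based coordinates using the source length field.
    """
    rows = []
    block = 0
    in_block = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            in_block = False if not line else in_block
            continue
        if line.startswith("a"):
            block += 1
            in_block = True
            continue
        if line.startswith("s "):
            if not in_block:
                raise BlockMapError(f"line {lineno}: 's' line outside a block")
            parts = line.split()
            if len(parts) < 7:
                raise BlockMapError(f"line {lineno}: malformed 's' line")
            src, start, size, strand, src_size = (
                parts[1], parts[2], parts[3], parts[4], parts[5])
            try:
                start, size, src_size = int(start), int(size), int(src_size)
            except ValueError as exc:
                raise BlockMapError(f"line {lineno}: non-integer field") from exc
            if strand not in "+-":
                raise BlockMapError(f"line {lineno}: bad strand {strand!r}")
            strain, _, contig = src.partition(".")
            contig = contig or src
            fwd_start = start if strand == "+" else src_size - start - size
            rows.append({"strain": strain, "block": block, "contig": contig,
                         "start": fwd_start, "end": fwd_start + size,
                         "strand": strand})
    df = pd.DataFrame(rows, columns=BLOCKMAP_COLUMNS)
    if strains is not None:
        known = set(df["strain"])
        unknown = known - set(strains)
        if unknown:
            raise BlockMapError(f"MAF contains unlisted strains: {sorted(unknown)}")
        return BlockMap(df, strains=tuple(strains))
    return BlockMap(df)


def filter_short_blocks(
    block_map: BlockMap, min_len: int = 500, reference: str | None = None
) -> BlockMap:
    """Drop core blocks shorter than ``min_len`` bp.

    Length is measured in the designated reference strain (default: first
    strain alphabetically), since per-strain lengths differ slightly.  The
    boundary keeps blocks of exactly ``min_len``.
    """
    if reference is None:
        reference = sorted(block_map.strains)[0]
    df = block_map.occurrences
    classes = block_map.classify()
    ref = df[df["strain"] == reference]
    short = set()
    for block, cls in classes.items():
        if cls != "core":
            continue
        sel = ref[ref["block"] == block]
        if sel.empty:
            continue
        if int((sel["end"] - sel["start"]).iloc[0]) < min_len:
            short.add(block)
    out = df[~df["block"].isin(short)]
    return BlockMap(out.reset_index(drop=True), strains=block_map.strains)


# ---------------------------------------------------------------------------
# Scaffolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """One strain's ordered, signed sequence of core blocks.

    ``elements`` may contain repeated block ids (duplicated copies are
    resolved later by :func:`dedup_duplicates`).  ``coordinates`` holds the
    per-element (contig, start, end) intervals, in scaffold order.
    """

    strain: str
    elements: tuple[int, ...]
    coordinates: tuple[tuple[str, int, int], ...] = ()

    def signed_sequence(self) -> tuple[int, ...]:
        return self.elements

    def has_duplicates(self) -> bool:
        ids = [abs(e) for e in self.elements]
        return len(ids) != len(set(ids))

    def to_permutation(self) -> SignedPermutation:
        if self.has_duplicates():
            raise PermutationError(
                f"scaffold of {self.strain} has duplicated blocks; deduplicate first")
        return _as_permutation(self.elements)


def _as_permutation(elements: Sequence[int]) -> SignedPermutation:
    """Rank block ids to 1..n preserving order of ids, keep signs."""
    order = {b: r for r, b in enumerate(sorted({abs(e) for e in elements}), start=1)}
    return SignedPermutation(tuple(
        order[abs(e)] * (1 if e > 0 else -1) for e in elements))


def scaffolds_from_map(block_map: BlockMap) -> list[Scaffold]:
    """Order each strain's core blocks by genomic position.

    Strains must be single-chromosome: more than one contig per strain is
    rejected (bacterial chromosomes; concatenate contigs upstream if that
    is really wanted).
    """
    core = block_map.core_only()
    out = []
    for strain in core.strains:
        sub = core.occurrences[core.occurrences["strain"] == strain]
        contigs = sub["contig"].unique()
        if len(contigs) > 1:
            raise BlockMapError(
                f"strain {strain} spans {len(contigs)} contigs; "
                "single-chromosome input required")
        sub = sub.sort_values(["start", "end"])
        elems = tuple(int(b) if s == "+" else -int(b)
                      for b, s in zip(sub["block"], sub["strand"]))
        coords = tuple((str(c), int(s), int(e))
                       for c, s, e in zip(sub["contig"], sub["start"], sub["end"]))
        out.append(Scaffold(strain=strain, elements=elems, coordinates=coords))
    return out


def merge_core_blocks(block_map: BlockMap, reference: str | None = None) -> BlockMap:
    """Fuse core blocks that are consecutive, with consistent relative
    orientation, in *every* strain; repeat to fixpoint.

    Adjacency is taken among core blocks only (dispensable or
    strain-specific sequence in between is ignored).  Blocks with repeated
    copies in any strain never merge.  Merged blocks are renumbered 1..m by
    their order in the reference strain (default: first alphabetically);
    per-strain coordinates span from the first to the last member.
    """
    if reference is None:
        reference = sorted(block_map.strains)[0]
    core = block_map.core_only()
    scaffolds = {s.strain: s for s in scaffolds_from_map(core)}
    dup = set()
    for s in scaffolds.values():
        ids = [abs(e) for e in s.elements]
        dup.update(b for b in ids if ids.count(b) > 1)

    # directed signed adjacencies present in every strain
    common: set[tuple[int, int]] | None = None
    for s in scaffolds.values():
        adj = set()
        for u, v in zip(s.elements, s.elements[1:]):
            if abs(u) in dup or abs(v) in dup:
                continue
            adj.add((u, v))
            adj.add((-v, -u))
        common = adj if common is None else (common & adj)
    common = common or set()

    # group the reference scaffold into maximal runs
    ref = scaffolds[reference]
    runs: list[list[int]] = []
    for e in ref.elements:
        if runs and (runs[-1][-1], e) in common:
            runs[-1].append(e)
        else:
            runs.append([e])
    # orient each run as forward in the new numbering
    run_defs = [tuple(r) if r[0] > 0 or len(r) == 1 else r for r in runs]
    new_ids = {}
    for k, run in enumerate(run_defs, start=1):
        new_ids[tuple(run)] = k

    # rewrite every strain
    first_of = {run[0]: (k, 1) for run, k in ((tuple(r), new_ids[tuple(r)])
                for r in run_defs)}
    last_of = {-run[-1]: (k, -1) for run, k in ((tuple(r), new_ids[tuple(r)])
               for r in run_defs)}
    rows = []
    for strain, s in scaffolds.items():
        i = 0
        elems = s.elements
        while i < len(elems):
            e = elems[i]
            if e in first_of:
                k, sign = first_of[e]
                run = run_defs[k - 1]
                matched = tuple(elems[i:i + len(run)]) == tuple(run)
            elif e in last_of:
                k, sign = last_of[e]
                run = tuple(-x for x in reversed(run_defs[k - 1]))
                matched = tuple(elems[i:i + len(run)]) == run
            else:
                matched = False
            if not matched:
                # duplicated or unmergeable block: stands alone
                b = abs(e)
                key = (b,)
                if key not in new_ids:
                    # duplicated block keeps its own merged id
                    new_ids[key] = len(new_ids) + 1
                    run_defs.append(key)
                k = new_ids[key]
                sign = 1 if e > 0 else -1
                span = 1
            else:
                span = len(run_defs[k - 1])
            coords = s.coordinates[i:i + span]
            rows.append({"strain": strain, "block": k,
                         "contig": coords[0][0],
                         "start": min(c[1] for c in coords),
                         "end": max(c[2] for c in coords),
                         "strand": "+" if sign > 0 else "-"})
            i += span
    df = pd.DataFrame(rows, columns=BLOCKMAP_COLUMNS)
    return BlockMap(df.reset_index(drop=True), strains=block_map.strains)


# ---------------------------------------------------------------------------
# Groups and comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldGroup:
    """Strains sharing an identical signed block sequence."""

    id: int
    strains: tuple[str, ...]
    canonical: Scaffold


def build_groups(scaffolds: Sequence[Scaffold]) -> list[ScaffoldGroup]:
    """Partition scaffolds by exact signed-sequence equality.

    Groups are numbered from 1 by descending size, ties broken by the
    position of their first strain in the input order (so the largest group
    is Group 1, matching the usual reporting convention).
    """
    buckets: dict[tuple[int, ...], list[int]] = {}
    for idx, s in enumerate(scaffolds):
        buckets.setdefault(s.elements, []).append(idx)
    ordered = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    return [
        ScaffoldGroup(
            id=g,
            strains=tuple(scaffolds[i].strain for i in idxs),
            canonical=scaffolds[idxs[0]],
        )
        for g, (_, idxs) in enumerate(ordered, start=1)
    ]


def dedup_duplicates(scaffold: Scaffold, reference: Scaffold) -> SignedPermutation:
    """Resolve repeated block copies against a duplicate-free reference.

    For every block with several copies, the copy sharing the most signed
    adjacencies with the reference is kept (ties: first occurrence).  The
    result is a strict signed permutation on ranked ids.
    """
    if reference.has_duplicates():
        raise PermutationError("reference scaffold has duplicated blocks")
    ref_ids = {abs(e) for e in reference.elements}
    ids = [abs(e) for e in scaffold.elements]
    if set(ids) - ref_ids:
        raise PermutationError(
            f"blocks {sorted(set(ids) - ref_ids)} absent from the reference")

    ref_adj = set()
    r = reference.elements
    for u, v in zip(r, r[1:]):
        ref_adj.add((u, v))
        ref_adj.add((-v, -u))

    elems = scaffold.elements
    keep: list[bool] = [True] * len(elems)
    for block in sorted({b for b in ids if ids.count(b) > 1}):
        positions = [p for p, e in enumerate(elems) if abs(e) == block]
        best_p, best_score = positions[0], -1
        for p in positions:
            score = 0
            if p > 0 and (elems[p - 1], elems[p]) in ref_adj:
                score += 1
            if p + 1 < len(elems) and (elems[p], elems[p + 1]) in ref_adj:
                score += 1
            if score > best_score:
                best_p, best_score = p, score
        for p in positions:
            keep[p] = p == best_p
    kept = tuple(e for e, k in zip(elems, keep) if k)
    return _as_permutation(kept)


@dataclass
class InversionCall:
    """One inversion of a minimum scenario, in original block labels."""

    start_block: int            # signed label of the segment's first block
    end_block: int              # signed label of the segment's last block
    length_bp: int | None       # core-genome length of the inverted segment
    ir_code: int | None = None  # 0/1/2 repeat presence (filled by repeat stage)
    repeat_label: str | None = None


@dataclass
class PairComparison:
    """Closest-group comparison row (the Table-1-style record)."""

    source_group: int
    closest_group: int
    inv_d: int
    r_d: int
    event_counts: dict[str, int]
    inversions: list[InversionCall]
    elimination: EliminationResult
    detail: DistanceDetail


def _comparison_perms(
    source: ScaffoldGroup, target: ScaffoldGroup
) -> tuple[SignedPermutation, SignedPermutation]:
    """Duplicate-resolved permutations for a group pair."""
    tgt_scaf = target.canonical
    if tgt_scaf.has_duplicates():
        # keep first copies so the scaffold can serve as a reference
        seen: set[int] = set()
        kept = []
        coords = []
        for e, c in zip(tgt_scaf.elements,
                        tgt_scaf.coordinates or [("", 0, 0)] * len(tgt_scaf.elements)):
            if abs(e) in seen:
                continue
            seen.add(abs(e))
            kept.append(e)
            coords.append(c)
        tgt_scaf = Scaffold(tgt_scaf.strain, tuple(kept), tuple(coords))
    src = dedup_duplicates(source.canonical, tgt_scaf)
    tgt = tgt_scaf.to_permutation()
    return src, tgt


def compare_pair(
    source: ScaffoldGroup,
    target: ScaffoldGroup,
    block_lengths: dict[int, int] | None = None,
) -> PairComparison:
    """Eliminate independent events, compute the residual inversion distance
    and a minimum scenario from ``source`` toward ``target``.

    ``block_lengths`` maps original (merged) block ids to bp lengths in the
    source strain; when given, each inversion call carries the core length
    of its segment.
    """
    src, tgt = _comparison_perms(source, target)
    elim = eliminate_independent_events(src, tgt)
    detail = pairwise_distance(elim.source, elim.target)
    scenario = optimal_scenario(elim.source, elim.target)

    calls: list[InversionCall] = []
    current = elim.source
    for i, j in scenario.steps:
        seg = current.elements[i - 1:j]
        start_run = elim.expand_label(seg[0])
        end_run = elim.expand_label(seg[-1])
        length = None
        if block_lengths is not None:
            length = sum(
                block_lengths.get(abs(b), 0)
                for e in seg for b in elim.expand_label(e))
        calls.append(InversionCall(
            start_block=start_run[0], end_block=end_run[-1], length_bp=length))
        current = apply_inversion(current, i, j)

    return PairComparison(
        source_group=source.id,
        closest_group=target.id,
        inv_d=detail.distance,
        r_d=elim.r_d,
        event_counts=elim.counts,
        inversions=calls,
        elimination=elim,
        detail=detail,
    )


def closest_pairs(
    groups: Sequence[ScaffoldGroup],
    block_map: BlockMap | None = None,
) -> list[PairComparison]:
    """For every group, compare against the group at minimum inversion
    distance (after independent-event elimination).

    Ties are broken by smaller independent-event count, then lower group
    id.  ``block_map`` (the merged map) supplies per-strain block lengths
    for inversion-length reporting.
    """
    if len(groups) < 2:
        raise ValueError("need at least two scaffold groups")
    out = []
    for src in groups:
        lengths = None
        if block_map is not None:
            df = block_map.occurrences
            sub = df[df["strain"] == src.canonical.strain]
            lengths = {int(b): int(e - s)
                       for b, s, e in zip(sub["block"], sub["start"], sub["end"])}
        best: PairComparison | None = None
        for tgt in groups:
            if tgt.id == src.id:
                continue
            comp = compare_pair(src, tgt, block_lengths=lengths)
            key = (comp.inv_d, comp.r_d, tgt.id)
            if best is None or key < (best.inv_d, best.r_d, best.closest_group):
                best = comp
        assert best is not None
        out.append(best)
    return out
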