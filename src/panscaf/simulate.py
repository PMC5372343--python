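"""Seeded generator of multi-strain bacterial-like genomes with planted
repeats and repeat-mediated rearrangements.

The generator emulates the input structure of a single-chromosome bacterial
pan-genome: an ancestor chromosome of ordered core blocks separated by
short spacers, IS-like repeat elements (0.7-1.5 kb) planted in the
inter-block gaps in either orientation, and derived strains obtained by
recombination events that conserve the sequence at the event ends:

* IR inversion — the sequence strictly between an inverted-repeat pair is
  reverse-complemented in place;
* DR transposition — the two segments between three same-strand copies of
  one repeat are swapped.

Inverted transpositions and inverted block interchanges are realized as two
IR inversions each (that two-inversion decomposition is itself a valid
mechanism for both composite events).

Every event is recorded in a truth log whose block-level effects, replayed
on the ancestor scaffold, reproduce each strain's scaffold exactly — this
is what end-to-end pipeline tests check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .permutation import SignedPermutation, write_grimm
from .repeats import revcomp
from .scaffold import BLOCKMAP_COLUMNS, BlockMap, Scaffold


class SimulationError(ValueError):
    """Inconsistent simulation configuration or script."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatPlacement:
    """Plant one copy of a labelled repeat in the gap after a block.

    ``after_block`` 0 places the copy before block 1; orientation +1/-1 is
    the strand of the copy.
    """

    after_block: int
    label: str
    orientation: int = 1


@dataclass(frozen=True)
class ScriptEvent:
    """One recombination event in a strain's derivation script.

    kind 'ir_inversion' uses ``copies`` = (c1, c2): the c1-th and c2-th
    genomic copy (0-based, left to right) of ``label``, which must lie on
    opposite strands.  kind 'dr_transposition' uses three same-strand
    copies.  ``tag`` optionally names the composite event this step belongs
    to (e.g. both halves of an inverted block interchange).
    """

    kind: str
    label: str
    copies: tuple[int, ...]
    tag: str = ""


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_strains: int = 5
    n_blocks: int = 40
    block_len: tuple[int, int] = (2000, 8000)      # uniform, bp
    spacer_len: tuple[int, int] = (200, 600)
    repeat_len: tuple[int, int] = (700, 1500)
    gc: float = 0.5
    mutation_rate: float = 0.0                     # per-base substitutions
    placements: tuple[RepeatPlacement, ...] = ()
    scripts: tuple[tuple[ScriptEvent, ...], ...] = ()   # one per strain

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise SimulationError("n_blocks must be >= 1")
        if self.n_strains < 1:
            raise SimulationError("n_strains must be >= 1")
        if not 0.0 <= self.gc <= 1.0:
            raise SimulationError("gc must be in [0, 1]")
        if self.scripts and len(self.scripts) != self.n_strains:
            raise SimulationError("need one event script per strain")


# ---------------------------------------------------------------------------
# Segment model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    kind: str            # 'block' | 'spacer' | 'repeat'
    label: int | str | None
    sign: int
    seq: str


def _draw_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _concat(segments: list[Segment]) -> str:
    return "".join(s.seq for s in segments)


def _scaffold_elements(segments: list[Segment]) -> tuple[int, ...]:
    return tuple(s.label * s.sign for s in segments if s.kind == "block")


def _blockmap_rows(strain: str, segments: list[Segment]) -> list[dict]:
    rows, pos = [], 0
    for s in segments:
        if s.kind == "block":
            rows.append({"strain": strain, "block": s.label, "contig": "chr",
                         "start": pos, "end": pos + len(s.seq),
                         "strand": "+" if s.sign > 0 else "-"})
        pos += len(s.seq)
    return rows


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

@dataclass
class AncestorModel:
    segments: list[Segment]
    repeat_seqs: dict[str, str]

    @property
    def genome(self) -> str:
        return _concat(self.segments)


def generate_ancestor(config: SimulationConfig) -> tuple[str, BlockMap, Scaffold]:
    """Ancestor chromosome, its block map, and its (identity) scaffold."""
    model = build_ancestor(config)
    rows = _blockmap_rows("ancestor", model.segments)
    bm = BlockMap(pd.DataFrame(rows, columns=BLOCKMAP_COLUMNS),
                  strains=("ancestor",))
    scaf = Scaffold(
        strain="ancestor",
        elements=_scaffold_elements(model.segments),
        coordinates=tuple((r["contig"], r["start"], r["end"]) for r in rows),
    )
    return model.genome, bm, scaf


def build_ancestor(config: SimulationConfig) -> AncestorModel:
    rng = np.random.default_rng(config.seed)
    by_gap: dict[int, list[RepeatPlacement]] = {}
    for pl in config.placements:
        if not 0 <= pl.after_block <= config.n_blocks:
            raise SimulationError(f"placement after_block {pl.after_block} out of range")
        by_gap.setdefault(pl.after_block, []).append(pl)

    repeat_seqs: dict[str, str] = {}
    for pl in config.placements:
        if pl.label not in repeat_seqs:
            length = int(rng.integers(*config.repeat_len, endpoint=True))
            repeat_seqs[pl.label] = _draw_seq(rng, length, config.gc)

    segments: list[Segment] = []

    def emit_gap(gap: int) -> None:
        segments.append(Segment("spacer", None, 1,
                                _draw_seq(rng, int(rng.integers(
                                    *config.spacer_len, endpoint=True)),
                                    config.gc)))
        for pl in by_gap.get(gap, ()):
            seq = repeat_seqs[pl.label]
            segments.append(Segment(
                "repeat", pl.label, pl.orientation,
                seq if pl.orientation > 0 else revcomp(seq)))
            segments.append(Segment("spacer", None, 1,
                                    _draw_seq(rng, int(rng.integers(
                                        *config.spacer_len, endpoint=True)),
                                        config.gc)))

    emit_gap(0)
    for b in range(1, config.n_blocks + 1):
        length = int(rng.integers(*config.block_len, endpoint=True))
        segments.append(Segment("block", b, 1, _draw_seq(rng, length, config.gc)))
        emit_gap(b)
    return AncestorModel(segments=segments, repeat_seqs=repeat_seqs)


# ---------------------------------------------------------------------------
# Sequence-level primitives
# ---------------------------------------------------------------------------

def plant_repeats(genome: str, placements: list[tuple[int, str, str]]) -> str:
    """Insert repeat copies at point positions of a raw genome.

    ``placements`` is a list of (position, sequence, strand); positions
    refer to the original genome and must be strictly increasing (equal
    positions would overlap).
    """
    last = -1
    for pos, _, strand in placements:
        if not 0 <= pos <= len(genome):
            raise SimulationError(f"placement position {pos} outside genome")
        if pos <= last:
            raise SimulationError("overlapping placements (positions must increase)")
        if strand not in "+-":
            raise SimulationError(f"bad strand {strand!r}")
        last = pos
    out, prev = [], 0
    for pos, seq, strand in placements:
        out.append(genome[prev:pos])
        out.append(seq if strand == "+" else revcomp(seq))
        prev = pos
    out.append(genome[prev:])
    return "".join(out)


def apply_ir_inversion(
    genome: str, occ1: tuple[int, int, str], occ2: tuple[int, int, str]
) -> str:
    """Recombination between an inverted-repeat pair: reverse-complement the
    sequence strictly between the two copies; the copies and everything
    outside them are untouched (the genome outside is bitwise conserved)."""
    (s1, e1, st1), (s2, e2, st2) = sorted([occ1, occ2])
    if st1 == st2:
        raise SimulationError("IR inversion requires copies on opposite strands")
    if e1 > s2:
        raise SimulationError("repeat copies overlap")
    return genome[:e1] + revcomp(genome[e1:s2]) + genome[s2:]


def apply_dr_transposition(
    genome: str,
    occ1: tuple[int, int, str],
    occ2: tuple[int, int, str],
    occ3: tuple[int, int, str],
) -> str:
    """Recombination at three same-strand repeat copies R1 < R2 < R3: the
    interiors (R1..R2) and (R2..R3) swap; the three copies and the external
    sequence are untouched."""
    occs = sorted([occ1, occ2, occ3])
    if len({o[2] for o in occs}) != 1:
        raise SimulationError("DR transposition requires same-strand copies")
    (s1, e1, _), (s2, e2, _), (s3, e3, _) = occs
    if e1 > s2 or e2 > s3:
        raise SimulationError("repeat copies overlap")
    a = genome[e1:s2]       # interior R1..R2
    b = genome[e2:s3]       # interior R2..R3
    return genome[:e1] + b + genome[s2:e2] + a + genome[s3:]


# ---------------------------------------------------------------------------
# Event-script engine (segment level, with truth logging)
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    strain: str
    kind: str
    tag: str
    repeat_label: str
    copies: tuple[int, ...]
    repeat_coords: tuple[tuple[int, int, str], ...]  # at application time
    scaffold_before: tuple[int, ...]
    scaffold_after: tuple[int, ...]


@dataclass
class TruthLog:
    ancestor_scaffold: tuple[int, ...]
    events: list[TruthEvent]

    def counts(self, strain: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            if ev.strain == strain:
                out[ev.kind] = out.get(ev.kind, 0) + 1
        return out

    def replay_ok(self, strain: str, final_scaffold: tuple[int, ...]) -> bool:
        """Each logged step chains from the previous scaffold and the last
        one matches the strain's final scaffold."""
        cur = self.ancestor_scaffold
        for ev in self.events:
            if ev.strain != strain:
                continue
            if ev.scaffold_before != cur:
                return False
            cur = ev.scaffold_after
        return cur == final_scaffold

    def to_json(self) -> str:
        return json.dumps({
            "ancestor_scaffold": list(self.ancestor_scaffold),
            "events": [{
                "strain": e.strain, "kind": e.kind, "tag": e.tag,
                "repeat_label": e.repeat_label, "copies": list(e.copies),
                "repeat_coords": [list(c) for c in e.repeat_coords],
                "scaffold_before": list(e.scaffold_before),
                "scaffold_after": list(e.scaffold_after),
            } for e in self.events],
        }, indent=1)


def _repeat_copy_indices(segments: list[Segment], label: str) -> list[int]:
    return [i for i, s in enumerate(segments) if s.kind == "repeat"
            and s.label == label]


def _segment_coords(segments: list[Segment]) -> list[tuple[int, int]]:
    coords, pos = [], 0
    for s in segments:
        coords.append((pos, pos + len(s.seq)))
        pos += len(s.seq)
    return coords


def _invert_segments(segments: list[Segment], i: int, j: int) -> list[Segment]:
    """Reverse-complement segments strictly between segment indices i < j."""
    middle = [replace(s, sign=-s.sign, seq=revcomp(s.seq))
              for s in reversed(segments[i + 1:j])]
    return segments[:i + 1] + middle + segments[j:]


def apply_script_event(
    segments: list[Segment], event: ScriptEvent
) -> tuple[list[Segment], tuple[tuple[int, int, str], ...]]:
    """Apply one script event; returns new segments and the genomic
    coordinates (at application time) of the mediating repeat copies."""
    idx = _repeat_copy_indices(segments, event.label)
    if any(c >= len(idx) or c < 0 for c in event.copies):
        raise SimulationError(
            f"repeat {event.label!r} has {len(idx)} copies; "
            f"script references {event.copies}")
    coords = _segment_coords(segments)

    def occ(seg_i: int) -> tuple[int, int, str]:
        lo, hi = coords[seg_i]
        return (lo, hi, "+" if segments[seg_i].sign > 0 else "-")

    if event.kind == "ir_inversion":
        if len(event.copies) != 2:
            raise SimulationError("ir_inversion takes two copies")
        i, j = sorted(idx[c] for c in event.copies)
        if segments[i].sign == segments[j].sign:
            raise SimulationError(
                f"copies of {event.label!r} are not an inverted pair")
        reps = (occ(i), occ(j))
        return _invert_segments(segments, i, j), reps

    if event.kind == "dr_transposition":
        if len(event.copies) != 3:
            raise SimulationError("dr_transposition takes three copies")
        i, j, k = sorted(idx[c] for c in event.copies)
        if not (segments[i].sign == segments[j].sign == segments[k].sign):
            raise SimulationError(
                f"copies of {event.label!r} are not a direct triple")
        reps = (occ(i), occ(j), occ(k))
        # interiors swap; the three copies stay in place: R1 B R2 A R3
        new = (segments[:i + 1] + segments[j + 1:k] + [segments[j]]
               + segments[i + 1:j] + [segments[k]] + segments[k + 1:])
        return new, reps

    raise SimulationError(f"unknown script event kind {event.kind!r}")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genomes: dict[str, str]
    block_map: BlockMap
    scaffolds: list[Scaffold]
    truth: TruthLog
    repeat_seqs: dict[str, str]


def apply_event_script(config: SimulationConfig) -> SimulatedDataset:
    """Derive one genome per strain from the configured ancestor and event
    scripts, with a consistent truth log."""
    model = build_ancestor(config)
    anc_scaffold = _scaffold_elements(model.segments)
    scripts = config.scripts or tuple(() for _ in range(config.n_strains))

    rng = np.random.default_rng(config.seed + 1)
    genomes: dict[str, str] = {}
    rows: list[dict] = []
    scaffolds: list[Scaffold] = []
    truth = TruthLog(ancestor_scaffold=anc_scaffold, events=[])

    for s_idx, script in enumerate(scripts):
        strain = f"strain{s_idx + 1:02d}"
        segments = list(model.segments)
        for event in script:
            before = _scaffold_elements(segments)
            segments, reps = apply_script_event(segments, event)
            truth.events.append(TruthEvent(
                strain=strain, kind=event.kind, tag=event.tag,
                repeat_label=event.label, copies=event.copies,
                repeat_coords=reps,
                scaffold_before=before,
                scaffold_after=_scaffold_elements(segments),
            ))
        genome = _concat(segments)
        if config.mutation_rate > 0:
            genome = _mutate(genome, config.mutation_rate, rng)
        genomes[strain] = genome
        strain_rows = _blockmap_rows(strain, segments)
        rows.extend(strain_rows)
        scaffolds.append(Scaffold(
            strain=strain,
            elements=_scaffold_elements(segments),
            coordinates=tuple((r["contig"], r["start"], r["end"])
                              for r in strain_rows),
        ))

    bm = BlockMap(pd.DataFrame(rows, columns=BLOCKMAP_COLUMNS),
                  strains=tuple(sorted(genomes)))
    return SimulatedDataset(config=config, genomes=genomes, block_map=bm,
                            scaffolds=scaffolds, truth=truth,
                            repeat_seqs=model.repeat_seqs)


def _mutate(genome: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(genome.encode(), dtype="S1").copy()
    n_mut = rng.binomial(len(arr), rate)
    sites = rng.choice(len(arr), size=n_mut, replace=False)
    bases = np.array([b"A", b"C", b"G", b"T"])
    for site in sites:
        choices = bases[bases != arr[site]]
        arr[site] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Default desk-scale study conditions
# ---------------------------------------------------------------------------

def default_desk_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale study conditions: 5 strains, 40 core blocks (~200 kb),
    five planted long (>10 kb) IR-mediated inversions and one DR-mediated
    transposition, no substitution noise.

    strain01 is the ancestor; strain02 carries two IR inversions, strain03
    three, strain04 the transposition, strain05 is an unrearranged clone.
    """
    placements = (
        RepeatPlacement(1, "A", +1), RepeatPlacement(8, "A", -1),
        RepeatPlacement(10, "B", +1), RepeatPlacement(17, "B", -1),
        RepeatPlacement(19, "C", +1), RepeatPlacement(25, "C", -1),
        RepeatPlacement(27, "D", +1), RepeatPlacement(33, "D", -1),
        RepeatPlacement(34, "E", -1), RepeatPlacement(39, "E", +1),
        RepeatPlacement(3, "R", +1), RepeatPlacement(6, "R", +1),
        RepeatPlacement(13, "R", +1),
    )
    scripts = (
        (),
        (ScriptEvent("ir_inversion", "A", (0, 1)),
         ScriptEvent("ir_inversion", "B", (0, 1))),
        (ScriptEvent("ir_inversion", "C", (0, 1)),
         ScriptEvent("ir_inversion", "D", (0, 1)),
         ScriptEvent("ir_inversion", "E", (0, 1))),
        (ScriptEvent("dr_transposition", "R", (0, 1, 2)),),
        (),
    )
    return SimulationConfig(seed=seed, n_strains=5, n_blocks=40,
                            placements=placements, scripts=scripts)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emit(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA per strain, block-map TSV, GRIMM scaffolds, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genomes_dir = outdir / "genomes"
    genomes_dir.mkdir(exist_ok=True)
    for strain, genome in dataset.genomes.items():
        p = genomes_dir / f"{strain}.fasta"
        with open(p, "w") as fh:
            fh.write(f">{strain} chr\n")
            for i in range(0, len(genome), 70):
                fh.write(genome[i:i + 70] + "\n")
        paths[f"fasta:{strain}"] = p

    paths["blockmap"] = outdir / "blockmap.tsv"
    paths["blockmap"].write_text(dataset.block_map.to_tsv())

    perms = {s.strain: s.to_permutation() for s in dataset.scaffolds}
    paths["scaffolds"] = outdir / "scaffolds.perm"
    paths["scaffolds"].write_text(write_grimm(perms))

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(dataset.truth.to_json())
    return paths


def read_fasta(path: str | Path) -> dict[str, str]:
    """Single-record-per-file FASTA reader used by the pipeline stages."""
    from Bio import SeqIO
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out
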