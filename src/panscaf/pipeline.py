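"""End-to-end orchestration: block map -> scaffolds -> groups -> events ->
distances -> repeat flanks -> report.

The report reproduces the shape of a per-species closest-pair table: for
each scaffold group, the closest group by inversion distance (after
independent-event elimination), each inversion with its core-genome length
in mbp, which inverted-repeat pair (if any) flanks it with a presence code
(0 = repeat found only in source-group strains, 1 = only in closest-group
strains, 2 = both), and the count of eliminated independent events (R_d).
"""

from __future__ import annotations

import io
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .permutation import SignedPermutation
from .repeats import (
    FlankReport,
    RepeatPair,
    find_inverted_repeat,
    inversion_breakpoint_windows,
    locate_repeat_occurrences,
    summarize_prevalence,
)
from .scaffold import (
    BlockMap,
    PairComparison,
    Scaffold,
    ScaffoldGroup,
    blocks_from_maf,
    build_groups,
    closest_pairs,
    filter_short_blocks,
    merge_core_blocks,
    scaffolds_from_map,
)

logger = logging.getLogger("panscaf")


class PipelineConfigError(ValueError):
    """Missing or contradictory pipeline inputs."""


@dataclass
class PipelineConfig:
    blockmap: str | Path | None = None        # TSV path
    maf: str | Path | None = None             # alternative alignment input
    genomes: Mapping[str, str] | None = None  # strain -> sequence (optional)
    min_block_len: int = 500
    reference: str | None = None
    repeat_min_len: int = 50
    repeat_min_id: float = 0.90
    seed_k: int = 15
    margin: int = 2000
    window_cap: int = 20000
    long_threshold: int = 10000
    outdir: str | Path | None = None


@dataclass
class PipelineReport:
    groups: list[ScaffoldGroup]
    comparisons: list[PairComparison]
    flank_reports: dict[int, list[FlankReport]]      # source group -> rows
    repeat_library: dict[str, str]                   # label -> sequence
    prevalence: dict | None

    def to_dict(self) -> dict:
        rows = []
        for comp in self.comparisons:
            flanks = self.flank_reports.get(comp.source_group, [])
            inversions = []
            for idx, call in enumerate(comp.inversions):
                fr = flanks[idx] if idx < len(flanks) else None
                inversions.append({
                    "start_block": call.start_block,
                    "end_block": call.end_block,
                    "length_bp": call.length_bp,
                    "length_mbp": (round(call.length_bp / 1e6, 4)
                                   if call.length_bp is not None else None),
                    "ir": (fr.repeat.label if fr and fr.repeat else None),
                    "ir_code": fr.presence_code if fr else None,
                })
            rows.append({
                "sG": comp.source_group,
                "cG": comp.closest_group,
                "inv_d": comp.inv_d,
                "r_d": comp.r_d,
                "event_counts": comp.event_counts,
                "inversions": inversions,
            })
        return {
            "groups": [{"id": g.id, "strains": list(g.strains)}
                       for g in self.groups],
            "pairs": rows,
            "prevalence": self.prevalence,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_text(self) -> str:
        """Markdown-ish closest-pair table."""
        d = self.to_dict()
        lines = ["# Scaffold groups"]
        for g in d["groups"]:
            lines.append(f"Group {g['id']}: {', '.join(g['strains'])}")
        lines.append("")
        lines.append("sG\tcG\tInv_d\tinversion\tl(mbp)\tIR\tR_d")
        for row in d["pairs"]:
            if not row["inversions"]:
                lines.append(f"{row['sG']}\t{row['cG']}\t{row['inv_d']}\t"
                             f"None\tN/A\tN/A\t{row['r_d']}")
            for idx, inv in enumerate(row["inversions"]):
                ir = (f"{inv['ir']}({inv['ir_code']})"
                      if inv["ir"] else "None")
                lmbp = inv["length_mbp"] if inv["length_mbp"] is not None else "N/A"
                prefix = (f"{row['sG']}\t{row['cG']}\t{row['inv_d']}"
                          if idx == 0 else "\t\t")
                lines.append(f"{prefix}\t({inv['start_block']},"
                             f"{inv['end_block']})\t{lmbp}\t{ir}\t"
                             f"{row['r_d'] if idx == 0 else ''}")
        if d["prevalence"]:
            p = d["prevalence"]
            lines.append("")
            lines.append(
                f"{p['ir_flanked']}/{p['inversions']} inversions IR-flanked; "
                f"{p['long_ir_flanked']}/{p['long_inversions']} of the long "
                f"(> {p['long_threshold']} bp) ones")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Repeat labelling
# ---------------------------------------------------------------------------

class _RepeatLibrary:
    """Assign stable letter labels to detected repeats, clustering copies
    of the same element at >= 90% identity in discovery order."""

    def __init__(self, min_id: float = 0.90) -> None:
        self.min_id = min_id
        self.seqs: dict[str, str] = {}

    def label_for(self, seq: str) -> str:
        import edlib

        from .repeats import revcomp
        for label, known in self.seqs.items():
            for cand in (seq, revcomp(seq)):
                res = edlib.align(cand, known, task="distance")
                ident = 1.0 - res["editDistance"] / max(len(cand), len(known))
                if ident >= self.min_id:
                    return label
        label = chr(ord("A") + len(self.seqs))
        self.seqs[label] = seq
        return label


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_blockmap(config: PipelineConfig) -> BlockMap:
    if config.blockmap is not None:
        return BlockMap.from_tsv(Path(config.blockmap).read_text())
    if config.maf is not None:
        return blocks_from_maf(Path(config.maf).read_text())
    raise PipelineConfigError("either a block map TSV or a MAF is required")


def _flank_stage(
    comparisons: Sequence[PairComparison],
    groups: Sequence[ScaffoldGroup],
    scaffolds: Mapping[str, Scaffold],
    genomes: Mapping[str, str],
    config: PipelineConfig,
    library: _RepeatLibrary,
) -> dict[int, list[FlankReport]]:
    by_id = {g.id: g for g in groups}
    out: dict[int, list[FlankReport]] = {}
    for comp in comparisons:
        src_group = by_id[comp.source_group]
        dst_group = by_id[comp.closest_group]
        strain = src_group.canonical.strain
        scaffold = scaffolds[strain]
        genome = genomes.get(strain)
        reports: list[FlankReport] = []
        for call in comp.inversions:
            report = FlankReport(
                length_bp=call.length_bp,
                long_inversion=(call.length_bp or 0) > config.long_threshold,
                ir_found=False,
            )
            if genome is not None:
                left, right = inversion_breakpoint_windows(
                    call.start_block, call.end_block, scaffold, genome,
                    margin=config.margin, cap=config.window_cap)
                pair = find_inverted_repeat(
                    left.sequence, right.sequence,
                    min_len=config.repeat_min_len,
                    min_id=config.repeat_min_id, seed_k=config.seed_k)
                if pair is not None:
                    rep_seq = left.sequence[pair.occ1[0]:pair.occ1[1]]
                    label = library.label_for(rep_seq)
                    report.ir_found = True
                    report.repeat = RepeatPair(
                        label=label, occ1=pair.occ1, occ2=pair.occ2,
                        orientation=pair.orientation, length=pair.length,
                        identity=pair.identity)
                    call.repeat_label = label
                    report.presence_code = _presence_code(
                        rep_seq, src_group, dst_group, genomes, config)
                    call.ir_code = report.presence_code
            reports.append(report)
        out[comp.source_group] = reports
    return out


def _presence_code(
    rep_seq: str,
    src_group: ScaffoldGroup,
    dst_group: ScaffoldGroup,
    genomes: Mapping[str, str],
    config: PipelineConfig,
) -> int:
    def found(group: ScaffoldGroup) -> bool:
        sub = {s: genomes[s] for s in group.strains if s in genomes}
        return bool(locate_repeat_occurrences(
            rep_seq, sub, min_id=config.repeat_min_id, seed_k=config.seed_k))

    in_src, in_dst = found(src_group), found(dst_group)
    if in_src and in_dst:
        return 2
    return 0 if in_src else 1


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order; see the module docstring.

    Without genome sequences the repeat-flank stage is skipped (a degraded
    report with empty IR columns, logged as a warning).
    """
    t0 = time.time()
    raw = _load_blockmap(config)
    logger.info("loaded block map: %d occurrences, %d strains",
                len(raw.occurrences), len(raw.strains))
    filtered = filter_short_blocks(raw, min_len=config.min_block_len,
                                   reference=config.reference)
    merged = merge_core_blocks(filtered, reference=config.reference)
    scaffolds = scaffolds_from_map(merged)
    logger.info("scaffolds: %d strains x %d merged core blocks",
                len(scaffolds), len(merged.core_blocks()))
    groups = build_groups(scaffolds)
    logger.info("groups: %d", len(groups))
    comparisons = closest_pairs(groups, merged)

    scaffold_by_strain = {s.strain: s for s in scaffolds}
    library = _RepeatLibrary(min_id=config.repeat_min_id)
    prevalence = None
    flank_reports: dict[int, list[FlankReport]] = {}
    if config.genomes:
        flank_reports = _flank_stage(comparisons, groups, scaffold_by_strain,
                                     config.genomes, config, library)
        all_reports = [r for rows in flank_reports.values() for r in rows]
        prevalence = summarize_prevalence(all_reports,
                                          long_threshold=config.long_threshold)
    else:
        logger.warning("no genome sequences given: repeat-flank stage skipped")

    report = PipelineReport(groups=groups, comparisons=comparisons,
                            flank_reports=flank_reports,
                            repeat_library=dict(library.seqs),
                            prevalence=prevalence)
    logger.info("pipeline finished in %.1fs", time.time() - t0)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(report.to_text())
    return report


# ---------------------------------------------------------------------------
# Supplementary-style scaffold tables
# ---------------------------------------------------------------------------

def parse_supplementary_scaffolds(text: str) -> list[Scaffold]:
    """Parse a per-strain scaffold table (TSV/CSV export of a supplementary
    worksheet): one row per strain, first field the strain name, remaining
    field(s) the signed block sequence (whitespace- or comma-separated).
    """
    scaffolds = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            name, _, rest = line.partition("\t")
        else:
            name, _, rest = line.partition(",")
        if not rest.strip():
            raise PipelineConfigError(
                f"line {lineno}: no block sequence for strain {name!r}")
        try:
            elems = tuple(int(tok) for tok in
                          rest.replace(",", " ").split())
        except ValueError as exc:
            raise PipelineConfigError(
                f"line {lineno}: non-integer block id") from exc
        scaffolds.append(Scaffold(strain=name.strip(), elements=elems))
    return scaffolds


def compare_scaffold_table(text: str) -> PipelineReport:
    """Group a supplementary-style scaffold table and run the closest-pair
    comparison (no sequences, so no repeat stage)."""
    scaffolds = parse_supplementary_scaffolds(text)
    groups = build_groups(scaffolds)
    comparisons = closest_pairs(groups)
    return PipelineReport(groups=groups, comparisons=comparisons,
                          flank_reports={}, repeat_library={},
                          prevalence=None)
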