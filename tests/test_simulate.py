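import json

import pytest

from panscaf.permutation import read_grimm
from panscaf.repeats import revcomp
from panscaf.scaffold import BlockMap
from panscaf.simulate import (
    RepeatPlacement,
    ScriptEvent,
    SimulationConfig,
    SimulationError,
    apply_dr_transposition,
    apply_event_script,
    apply_ir_inversion,
    build_ancestor,
    default_desk_config,
    emit,
    generate_ancestor,
    plant_repeats,
)


class TestGenerateAncestor:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=11, n_blocks=10)
        g1, _, _ = generate_ancestor(cfg)
        g2, _, _ = generate_ancestor(cfg)
        assert g1 == g2

    def test_genome_size_tracks_block_lengths(self):
        cfg = SimulationConfig(seed=1, n_blocks=20, block_len=(5000, 5000),
                               spacer_len=(200, 200))
        genome, bm, scaf = generate_ancestor(cfg)
        assert len(genome) == 20 * 5000 + 21 * 200
        assert scaf.elements == tuple(range(1, 21))
        assert len(bm.occurrences) == 20

    def test_zero_blocks_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_blocks=0)

    def test_block_coordinates_match_sequence(self):
        cfg = SimulationConfig(seed=2, n_blocks=5)
        genome, bm, scaf = generate_ancestor(cfg)
        for (contig, start, end), e in zip(scaf.coordinates, scaf.elements):
            assert 0 <= start < end <= len(genome)


class TestPlantRepeats:
    def test_empty_placements_identity(self):
        assert plant_repeats("ACGTACGT", []) == "ACGTACGT"

    def test_insertion_and_reverse_orientation(self):
        out = plant_repeats("AAAATTTT", [(4, "CG", "+"), (8, "CG", "-")])
        assert out == "AAAACGTTTTCG"

    def test_overlapping_placements_rejected(self):
        with pytest.raises(SimulationError):
            plant_repeats("ACGT", [(2, "GG", "+"), (2, "CC", "+")])

    def test_out_of_range_rejected(self):
        with pytest.raises(SimulationError):
            plant_repeats("ACGT", [(9, "GG", "+")])


class TestIrInversion:
    GENOME = "AAAA" + "GGCC" + "TTTTTTTT" + "GGCC"[::-1].translate(
        str.maketrans("ACGT", "TGCA")) + "CCCC"

    def occs(self):
        return (4, 8, "+"), (16, 20, "-")

    def test_interior_reverse_complemented_flanks_conserved(self):
        o1, o2 = self.occs()
        out = apply_ir_inversion(self.GENOME, o1, o2)
        assert out[:8] == self.GENOME[:8]            # left flank + repeat
        assert out[16:] == self.GENOME[16:]          # repeat + right flank
        assert out[8:16] == revcomp(self.GENOME[8:16])

    def test_involution(self):
        o1, o2 = self.occs()
        once = apply_ir_inversion(self.GENOME, o1, o2)
        assert apply_ir_inversion(once, o1, o2) == self.GENOME

    def test_direct_pair_rejected(self):
        with pytest.raises(SimulationError):
            apply_ir_inversion(self.GENOME, (4, 8, "+"), (16, 20, "+"))

    def test_zero_interior_is_noop(self):
        g = "AAGGCCTT"
        assert apply_ir_inversion(g, (2, 4, "+"), (4, 6, "-")) == g


class TestDrTransposition:
    # R at 2-4, 8-10, 14-16; interiors 'CCCC' and 'GGGG'
    GENOME = "AA" + "TT" + "CCCC" + "TT" + "GGGG" + "TT" + "AA"

    def occs(self):
        return (2, 4, "+"), (8, 10, "+"), (14, 16, "+")

    def test_interiors_swap_ends_conserved(self):
        out = apply_dr_transposition(self.GENOME, *self.occs())
        assert out == "AA" + "TT" + "GGGG" + "TT" + "CCCC" + "TT" + "AA"

    def test_involution(self):
        o = self.occs()
        once = apply_dr_transposition(self.GENOME, *o)
        assert apply_dr_transposition(once, *o) == self.GENOME

    def test_opposite_strands_rejected(self):
        with pytest.raises(SimulationError):
            apply_dr_transposition(self.GENOME, (2, 4, "+"), (8, 10, "-"),
                                   (14, 16, "+"))

    def test_zero_length_interiors_noop(self):
        g = "AATTTTTTAA"
        assert apply_dr_transposition(g, (2, 4, "+"), (4, 6, "+"),
                                      (6, 8, "+")) == g


class TestEventScript:
    def test_empty_scripts_clone_ancestor(self):
        cfg = SimulationConfig(seed=3, n_strains=3, n_blocks=8,
                               scripts=((), (), ()))
        ds = apply_event_script(cfg)
        seqs = set(ds.genomes.values())
        assert len(seqs) == 1
        assert all(s.elements == tuple(range(1, 9)) for s in ds.scaffolds)

    def test_script_referencing_missing_repeat_rejected(self):
        cfg = SimulationConfig(
            seed=3, n_strains=1, n_blocks=8,
            placements=(RepeatPlacement(2, "A", 1), RepeatPlacement(5, "A", -1)),
            scripts=((ScriptEvent("ir_inversion", "A", (0, 3)),),))
        with pytest.raises(SimulationError):
            apply_event_script(cfg)

    def test_same_strand_pair_rejected_for_inversion(self):
        cfg = SimulationConfig(
            seed=3, n_strains=1, n_blocks=8,
            placements=(RepeatPlacement(2, "A", 1), RepeatPlacement(5, "A", 1)),
            scripts=((ScriptEvent("ir_inversion", "A", (0, 1)),),))
        with pytest.raises(SimulationError):
            apply_event_script(cfg)

    def test_end_conservation_outside_mediating_repeats(self):
        """The generator's central mechanism: for every logged event, the
        sequence outside the outermost repeat copies is bitwise identical
        before and after the event."""
        ds = apply_event_script(default_desk_config(seed=0))
        # re-derive each strain step by step to capture pre/post genomes
        from panscaf.simulate import apply_script_event, build_ancestor, _concat
        cfg = ds.config
        model = build_ancestor(cfg)
        for s_idx, script in enumerate(cfg.scripts):
            segments = list(model.segments)
            for event in script:
                before = _concat(segments)
                segments, reps = apply_script_event(segments, event)
                after = _concat(segments)
                lo = min(r[0] for r in reps)
                hi = max(r[1] for r in reps)
                assert before[:lo] == after[:lo]
                assert before[hi:] == after[hi:]
                # the outermost copies stay in place (interiors may differ
                # in length, so inner copies of a transposition can shift)
                for (a, b, _) in (reps[0], reps[-1]):
                    assert before[a:b] == after[a:b]

    def test_truth_log_replays_to_final_scaffolds(self):
        ds = apply_event_script(default_desk_config(seed=0))
        for scaf in ds.scaffolds:
            assert ds.truth.replay_ok(scaf.strain, scaf.elements)

    def test_breakpoint_reuse_script(self):
        """Three inversions can share one repeat junction: a four-copy
        repeat (one orientation flipped per step) mediates successive
        inversions whose truth entries reuse a common boundary."""
        placements = (
            RepeatPlacement(2, "B", -1),
            RepeatPlacement(5, "B", +1),
            RepeatPlacement(8, "B", -1),
            RepeatPlacement(11, "B", -1),
        )
        script = (
            ScriptEvent("ir_inversion", "B", (0, 1)),
            ScriptEvent("ir_inversion", "B", (1, 2)),
            ScriptEvent("ir_inversion", "B", (1, 3)),
        )
        cfg = SimulationConfig(seed=5, n_strains=1, n_blocks=14,
                               placements=placements, scripts=(script,))
        ds = apply_event_script(cfg)
        events = ds.truth.events
        assert len(events) == 3
        # copy 1's junction participates in all three events
        assert all(1 in ev.copies for ev in events)
        assert ds.truth.replay_ok("strain01", ds.scaffolds[0].elements)


class TestEmitRoundTrip:
    def test_written_files_read_back_equal(self, tmp_path):
        ds = apply_event_script(default_desk_config(seed=0))
        paths = emit(ds, tmp_path)
        bm = BlockMap.from_tsv(paths["blockmap"].read_text())
        assert bm.occurrences.equals(
            ds.block_map.occurrences.reset_index(drop=True))
        perms = read_grimm(paths["scaffolds"].read_text())
        assert perms["strain02"].elements == ds.scaffolds[1].to_permutation().elements
        truth = json.loads(paths["truth"].read_text())
        assert len(truth["events"]) == len(ds.truth.events)

    def test_truth_json_validates_against_shipped_schema(self, tmp_path):
        from panscaf.schema import SchemaError, load_schema, validate
        ds = apply_event_script(default_desk_config(seed=0))
        paths = emit(ds, tmp_path)
        schema = load_schema("truth")
        validate(json.loads(paths["truth"].read_text()), schema)
        with pytest.raises(SchemaError):
            validate({"events": []}, schema)   # ancestor_scaffold missing

    def test_fasta_is_bit_stable(self, tmp_path):
        ds1 = apply_event_script(default_desk_config(seed=0))
        ds2 = apply_event_script(default_desk_config(seed=0))
        p1 = emit(ds1, tmp_path / "a")["fasta:strain02"].read_bytes()
        p2 = emit(ds2, tmp_path / "b")["fasta:strain02"].read_bytes()
        assert p1 == p2
        lines = p1.decode().splitlines()
        assert lines[0].startswith(">strain02")
        assert all(len(l) <= 70 for l in lines[1:])
        assert all(l.isupper() for l in lines[1:])
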