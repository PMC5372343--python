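import random

import pytest

from panscaf.events import RearrangementEvent
from panscaf.repeats import (
    BreakpointWindow,
    FlankReport,
    SequenceError,
    check_event_ends,
    find_direct_repeat,
    find_inverted_repeat,
    inversion_breakpoint_windows,
    locate_repeat_occurrences,
    occurrences_to_bed,
    revcomp,
    summarize_prevalence,
)
from panscaf.scaffold import Scaffold

RNG = random.Random(2024)


def seq(n, rng=RNG):
    return "".join(rng.choice("ACGT") for _ in range(n))


# an IS-element-sized repeat; flanking bases are fixed so that chance
# extension beyond the planted copies is impossible
X = "A" + seq(818, random.Random(7)) + "A"


def guarded_windows():
    # in the left-vs-revcomp(right) comparison frame the bases adjacent to
    # the planted copies differ (C/A and C/A), so no chance extension
    left = seq(2000, random.Random(1)) + "C" + X + "C" + seq(499, random.Random(2))
    right = (seq(400, random.Random(3)) + "T" + revcomp(X) + "T"
             + seq(1499, random.Random(4)))
    return left, right


class TestFindInvertedRepeat:
    def test_planted_pair_found_exactly(self):
        left, right = guarded_windows()
        pair = find_inverted_repeat(left, right)
        assert pair is not None
        assert pair.orientation == "inverted"
        assert pair.length == 820
        assert pair.identity == 1.0
        assert left[pair.occ1[0]:pair.occ1[1]] == X
        assert revcomp(right[pair.occ2[0]:pair.occ2[1]]) == X

    def test_direct_copy_is_not_inverted(self):
        left, _ = guarded_windows()
        right = seq(400, random.Random(3)) + "G" + X + "G" + seq(1499, random.Random(4))
        assert find_inverted_repeat(left, right) is None

    def test_random_sequences_yield_nothing(self):
        assert find_inverted_repeat(seq(5000, random.Random(5)),
                                    seq(5000, random.Random(6)),
                                    min_len=50) is None

    def test_empty_windows_yield_nothing(self):
        assert find_inverted_repeat("", "ACGT") is None

    def test_non_nucleotide_rejected(self):
        with pytest.raises(SequenceError):
            find_inverted_repeat("ACGTX" * 20, "ACGT" * 25)

    def test_reverse_complement_symmetry(self):
        left, right = guarded_windows()
        fwd = find_inverted_repeat(left, right)
        mirrored = find_inverted_repeat(revcomp(right), revcomp(left))
        assert fwd is not None and mirrored is not None
        assert fwd.length == mirrored.length
        assert fwd.identity == mirrored.identity
        # coordinates mirror across the window ends
        assert fwd.occ1[0] == len(left) - mirrored.occ2[1]
        assert fwd.occ2[0] == len(right) - mirrored.occ1[1]

    def test_thresholds_are_monotone(self):
        """Raising min_len or min_id never turns a miss into a hit."""
        left, right = guarded_windows()
        found_loose = find_inverted_repeat(left, right, min_len=50, min_id=0.5)
        found_tight = find_inverted_repeat(left, right, min_len=900, min_id=0.5)
        assert found_loose is not None and found_tight is None
        assert find_inverted_repeat(left, right, min_len=50, min_id=1.0) is not None
        # and on a null input nothing appears at any threshold
        null = (seq(3000, random.Random(8)), seq(3000, random.Random(9)))
        for ml in (50, 200, 800):
            assert find_inverted_repeat(*null, min_len=ml) is None


class TestFindDirectRepeat:
    def test_planted_direct_copy_found(self):
        left = seq(1000, random.Random(10)) + "C" + X + "C" + seq(200, random.Random(11))
        right = seq(300, random.Random(12)) + "G" + X + "G" + seq(700, random.Random(13))
        pair = find_direct_repeat(left, right)
        assert pair is not None and pair.orientation == "direct"
        assert pair.length == 820 and pair.identity == 1.0

    def test_inverted_copy_only_yields_nothing(self):
        left = seq(1000, random.Random(10)) + "C" + X + "C" + seq(200, random.Random(11))
        right = seq(300, random.Random(12)) + "G" + revcomp(X) + "G" + seq(700, random.Random(13))
        assert find_direct_repeat(left, right) is None


class TestLocateOccurrences:
    def test_planted_strains_and_strands(self):
        genomes = {
            "s1": seq(3000, random.Random(20)) + X + seq(1000, random.Random(21)),
            "s2": seq(500, random.Random(22)) + revcomp(X) + seq(2000, random.Random(23)),
            "s3": seq(4000, random.Random(24)),
            "s4": seq(100, random.Random(25)) + X + seq(100, random.Random(26)),
            "s5": seq(2500, random.Random(27)),
        }
        occ = locate_repeat_occurrences(X, genomes)
        by_strain = {o[0]: o for o in occ}
        assert set(by_strain) == {"s1", "s2", "s4"}
        assert by_strain["s1"][2] == "+" and by_strain["s2"][2] == "-"
        assert by_strain["s1"][1] == (3000, 3820)

    def test_forward_and_reverse_in_one_strain(self):
        g = {"s": seq(500, random.Random(30)) + X + seq(400, random.Random(31))
             + revcomp(X) + seq(200, random.Random(32))}
        occ = locate_repeat_occurrences(X, g)
        assert [o[2] for o in occ] == ["+", "-"]

    def test_empty_genome_set(self):
        assert locate_repeat_occurrences(X, {}) == []


class TestBreakpointWindows:
    @staticmethod
    def scaffold_and_genome():
        rng = random.Random(40)
        blocks = [seq(3000, rng) for _ in range(4)]
        spacers = [seq(300, rng) for _ in range(5)]
        genome, coords, pos = "", [], 0
        genome += spacers[0]
        pos = len(genome)
        for i, b in enumerate(blocks):
            coords.append(("chr", pos, pos + len(b)))
            genome += b + spacers[i + 1]
            pos = len(genome)
        scaf = Scaffold("s", (1, 2, 3, 4), tuple(coords))
        return scaf, genome

    def test_windows_cover_the_gaps(self):
        scaf, genome = self.scaffold_and_genome()
        left, right = inversion_breakpoint_windows(2, 3, scaf, genome,
                                                   margin=100, cap=10000)
        # left window straddles the junction between blocks 1 and 2
        assert left.start <= scaf.coordinates[0][2] <= scaf.coordinates[1][1] <= left.end
        assert right.start <= scaf.coordinates[2][2] <= scaf.coordinates[3][1] <= right.end
        assert left.sequence == genome[left.start:left.end]

    def test_window_at_scaffold_start_clips_at_origin(self):
        scaf, genome = self.scaffold_and_genome()
        left, _ = inversion_breakpoint_windows(1, 2, scaf, genome,
                                               margin=10**6, cap=10**7)
        assert left.start == 0

    def test_cap_limits_window_size(self):
        scaf, genome = self.scaffold_and_genome()
        left, right = inversion_breakpoint_windows(2, 3, scaf, genome,
                                                   margin=10**6, cap=2000)
        assert left.end - left.start <= 2000
        assert right.end - right.start <= 2000

    def test_missing_block_rejected(self):
        scaf, genome = self.scaffold_and_genome()
        with pytest.raises(ValueError):
            inversion_breakpoint_windows(1, 9, scaf, genome)


class TestCheckEventEnds:
    def test_direct_triple_covers_all_junctions(self):
        rng = random.Random(50)
        windows = [
            BreakpointWindow("s", f"j{i}", 0, 0,
                             seq(600, rng) + "C" + X + "C" + seq(400, rng))
            for i in range(3)
        ]
        report = check_event_ends(
            RearrangementEvent("transposition", (2,)), windows)
        assert report["all_ends_conserved"]
        assert report["junctions_covered"] == [0, 1, 2]
        assert all(p.orientation == "direct" for p in report["pair_hits"].values())

    def test_no_repeats_reports_unconserved(self):
        rng = random.Random(51)
        windows = [BreakpointWindow("s", f"j{i}", 0, 0, seq(800, rng))
                   for i in range(3)]
        report = check_event_ends(
            RearrangementEvent("transposition", (2,)), windows)
        assert not report["all_ends_conserved"]
        assert report["pair_hits"] == {}

    def test_junction_count_enforced(self):
        with pytest.raises(ValueError):
            check_event_ends(RearrangementEvent("block_interchange", (1, 3)),
                             [BreakpointWindow("s", "j", 0, 0, "ACGT")] * 3)

    def test_inverted_interchange_two_ir_pairs(self):
        rng = random.Random(52)
        Y = "A" + seq(900, random.Random(53)) + "A"
        windows = [
            BreakpointWindow("s", "j0", 0, 0, seq(500, rng) + "C" + X + "C" + seq(300, rng)),
            BreakpointWindow("s", "j1", 0, 0, seq(500, rng) + "G" + revcomp(X) + "G" + seq(300, rng)),
            BreakpointWindow("s", "j2", 0, 0, seq(500, rng) + "C" + Y + "C" + seq(300, rng)),
            BreakpointWindow("s", "j3", 0, 0, seq(500, rng) + "G" + revcomp(Y) + "G" + seq(300, rng)),
        ]
        report = check_event_ends(
            RearrangementEvent("inverted_block_interchange", (2, 5),
                               sign_detail="both"), windows)
        assert report["all_ends_conserved"]


class TestSummarizePrevalence:
    def test_empty(self):
        s = summarize_prevalence([])
        assert s["inversions"] == 0 and s["long_fraction_flanked"] is None

    def test_planted_long_all_flanked(self):
        reports = ([FlankReport(15000, True, True)] * 5
                   + [FlankReport(3000, False, False)] * 2)
        s = summarize_prevalence(reports)
        assert (s["long_inversions"], s["long_ir_flanked"]) == (5, 5)
        assert s["long_fraction_flanked"] == 1.0

    def test_mixed_thirteen_with_seven_flagged(self):
        reports = ([FlankReport(20000, True, True)] * 7
                   + [FlankReport(5000, False, False)] * 6)
        s = summarize_prevalence(reports)
        assert (s["inversions"], s["ir_flanked"]) == (13, 7)


def test_bed_output_format():
    bed = occurrences_to_bed([("s1", (10, 830), "+"), ("s2", (5, 825), "-")],
                             label="A", identity=0.995)
    assert bed.splitlines() == [
        "s1\t10\t830\tA\t995\t+",
        "s2\t5\t825\tA\t995\t-",
    ]
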