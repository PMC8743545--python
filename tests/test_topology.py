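"""Boundary detection, junction evidence and circularization calls,
including the worked examples with the published clone coordinates."""

import numpy as np
import pytest

from lintopo import (
    AlignmentSegment,
    CircularizationCall,
    JunctionEvidence,
    TerminalBoundary,
    call_topology,
    deletion_sizes_kb,
    detect_boundary,
    find_junctions,
    genome_loss_fraction,
)
from lintopo.model import CoverageProfile
from lintopo.topology import AmbiguousTopologyError, RepliconAbsentError

CHR_N = 6_748_580
PUBLISHED_LENGTHS = {
    "chromosome": 6_748_580,
    "pSCL4": 1_794_824,
    "pSCL2": 149_702,
    "pSCL1": 11_696,
}


def _profile(n, covered_from=1, covered_to=None, depth=30):
    covered_to = n if covered_to is None else covered_to
    d = np.zeros(n, dtype=np.int64)
    d[covered_from - 1 : covered_to] = depth
    return CoverageProfile("chr", d)


def _junction(L, R, qid="j", anchors=(75, 75), gap=0):
    return JunctionEvidence(qid, R, L, anchors[0], anchors[1], gap)


def _boundary(end, pos, rep="chr"):
    return TerminalBoundary(rep, end, pos, 30.0)


class TestDetectBoundary:
    def test_full_coverage_returns_termini(self):
        p = _profile(10_000)
        assert detect_boundary(p, "left").position == 1
        assert detect_boundary(p, "right").position == 10_000

    def test_terminal_deletions_located(self):
        p = _profile(10_000, covered_from=2_001, covered_to=8_500)
        assert detect_boundary(p, "left", terminal_dip=150).position == 2_001
        assert detect_boundary(p, "right", terminal_dip=150).position == 8_500

    def test_terminal_dip_snaps_to_terminus(self):
        # linear molecules are under-covered over ~a read length at the ends
        p = _profile(10_000, covered_from=90, covered_to=9_930)
        assert detect_boundary(p, "left", terminal_dip=150).position == 1
        assert detect_boundary(p, "right", terminal_dip=150).position == 10_000

    def test_stray_coverage_beyond_boundary_ignored(self):
        # isolated chimeric/PCR-artifact coverage must not move the boundary:
        # detection keys on a sustained run, not the first covered base
        d = np.zeros(10_000, dtype=np.int64)
        d[2_000:8_000] = 25
        d[100:130] = 3  # stray spike far left of the true boundary
        p = CoverageProfile("chr", d)
        assert detect_boundary(p, "left", min_run=100, terminal_dip=150).position == 2_001

    def test_absent_replicon_raises(self):
        p = CoverageProfile("chr", np.zeros(5_000, dtype=np.int64))
        with pytest.raises(RepliconAbsentError):
            detect_boundary(p, "left")

    def test_bad_end_rejected(self):
        with pytest.raises(ValueError, match="left.*right"):
            detect_boundary(_profile(1_000), "middle")


class TestFindJunctions:
    N = 10_000

    def _segs(self, qid, right_end, left_start, strand="+", anchor=150):
        """Two segments modelling a query spanning right-end -> left-start."""
        if strand == "+":
            return [
                AlignmentSegment(qid, 1, anchor, "chr", right_end - anchor + 1,
                                 right_end, "+"),
                AlignmentSegment(qid, anchor + 1, 2 * anchor, "chr", left_start,
                                 left_start + anchor - 1, "+", role="supplementary"),
            ]
        return [
            AlignmentSegment(qid, anchor + 1, 2 * anchor, "chr", right_end - anchor + 1,
                             right_end, "-"),
            AlignmentSegment(qid, 1, anchor, "chr", left_start,
                             left_start + anchor - 1, "-", role="supplementary"),
        ]

    def test_perfect_zero_deletion_junction(self):
        segs = self._segs("q", self.N, 1)
        (ev,) = find_junctions(segs, "chr", self.N, terminal_window=2_000)
        assert (ev.R, ev.L, ev.junction_gap) == (self.N, 1, 0)

    def test_minus_strand_junction_detected(self):
        segs = self._segs("q", self.N - 500, 300, strand="-")
        (ev,) = find_junctions(segs, "chr", self.N, terminal_window=2_000)
        assert (ev.R, ev.L) == (self.N - 500, 300)

    def test_same_end_split_gives_no_evidence(self):
        segs = [
            AlignmentSegment("q", 1, 150, "chr", 9_000, 9_149, "+"),
            AlignmentSegment("q", 151, 300, "chr", 9_500, 9_649, "+", role="supplementary"),
        ]
        assert find_junctions(segs, "chr", self.N, terminal_window=2_000) == []

    def test_opposite_strand_segments_give_no_evidence(self):
        segs = self._segs("q", self.N, 1)
        segs[1].strand = "-"
        assert find_junctions(segs, "chr", self.N, terminal_window=2_000) == []

    def test_wrong_query_order_gives_no_evidence(self):
        # left anchor before right anchor along the (plus-strand) query
        # reads as left-end -> right-end, not a circularization junction
        segs = [
            AlignmentSegment("q", 1, 150, "chr", 1, 150, "+"),
            AlignmentSegment("q", 151, 300, "chr", 9_851, 10_000, "+", role="supplementary"),
        ]
        assert find_junctions(segs, "chr", self.N, terminal_window=2_000) == []

    def test_short_anchor_excluded(self):
        segs = self._segs("q", self.N, 1, anchor=30)
        assert find_junctions(segs, "chr", self.N, min_anchor=50,
                              terminal_window=2_000) == []

    def test_ambiguous_placements_excluded(self):
        segs = self._segs("q", self.N, 1)
        for s in segs:
            s.ambiguous = True
        assert find_junctions(segs, "chr", self.N, terminal_window=2_000) == []


class TestCallTopology:
    def test_published_junction_coordinates_first_clone(self):
        """Junction contiguity across positions 98,994 and 6,632,666 of a
        6,748,580 bp chromosome: deletions 98,993 / 115,914 bp = 99/116 kb."""
        call = call_topology(
            _boundary("left", 98_990),
            _boundary("right", 6_632_670),
            [_junction(98_994, 6_632_666, f"q{i}") for i in range(3)],
            CHR_N,
        )
        assert call.status == "circularized"
        assert (call.L, call.R) == (98_994, 6_632_666)
        assert (call.left_deletion, call.right_deletion) == (98_993, 115_914)
        assert deletion_sizes_kb(call) == (99, 116)

    def test_published_boundaries_second_clone(self):
        """Coverage lost before 120,225 and after 6,660,447: deletions
        120,224 / 88,133 bp = 120/88 kb."""
        call = call_topology(
            _boundary("left", 120_225),
            _boundary("right", 6_660_447),
            [_junction(120_225, 6_660_447, f"q{i}") for i in range(2)],
            CHR_N,
        )
        assert (call.left_deletion, call.right_deletion) == (120_224, 88_133)
        assert deletion_sizes_kb(call) == (120, 88)

    def test_intact_chromosome(self):
        call = call_topology(_boundary("left", 1), _boundary("right", CHR_N), [], CHR_N)
        assert call.status == "intact"
        assert (call.left_deletion, call.right_deletion) == (0, 0)
        assert deletion_sizes_kb(call) == (0, 0)

    def test_deletions_without_junction_stay_open(self):
        # terminal loss with no junction-spanning query: the data shows
        # deletion but cannot establish circularization
        call = call_topology(
            _boundary("left", 50_000), _boundary("right", 6_600_000), [], CHR_N
        )
        assert call.status == "terminal_deletion_only"
        assert (call.L, call.R) == (50_000, 6_600_000)

    def test_single_read_insufficient_by_default(self):
        call = call_topology(
            _boundary("left", 98_990),
            _boundary("right", 6_632_670),
            [_junction(98_994, 6_632_666)],
            CHR_N,
        )
        assert call.status == "terminal_deletion_only"

    def test_single_long_anchor_contig_is_decisive(self):
        # one assembled contig with kb-scale anchors on both sides carries
        # the weight of several reads
        call = call_topology(
            _boundary("left", 98_990),
            _boundary("right", 6_632_670),
            [_junction(98_994, 6_632_666, "contig", anchors=(7_000, 7_900))],
            CHR_N,
        )
        assert call.status == "circularized"

    def test_min_evidence_monotonicity(self):
        junctions = [_junction(98_994, 6_632_666, f"q{i}") for i in range(3)]
        args = (_boundary("left", 98_990), _boundary("right", 6_632_670), junctions, CHR_N)
        statuses = [call_topology(*args, min_evidence=m).status for m in (1, 2, 3, 4, 5)]
        # once the call degrades to terminal_deletion_only it never reverts
        assert statuses == sorted(statuses, key=lambda s: s != "circularized")
        assert statuses[0] == "circularized" and statuses[-1] == "terminal_deletion_only"

    def test_junction_far_from_boundaries_not_accepted(self):
        call = call_topology(
            _boundary("left", 98_990),
            _boundary("right", 6_632_670),
            [_junction(500_000, 6_000_000, f"q{i}") for i in range(5)],
            CHR_N,
        )
        assert call.status == "terminal_deletion_only"
        assert call.warnings

    def test_conflicting_clusters_raise(self):
        junctions = [_junction(98_994, 6_632_666, f"a{i}") for i in range(3)]
        junctions += [_junction(98_000, 6_640_000, f"b{i}") for i in range(3)]
        with pytest.raises(AmbiguousTopologyError):
            call_topology(
                _boundary("left", 98_990), _boundary("right", 6_632_670),
                junctions, CHR_N, tolerance=2_000,
            )

    def test_microhomology_overlap_canonicalised(self):
        # anchors overlapping by one query base (junction microhomology)
        # must not shift the consensus off the true first retained position
        junctions = [_junction(98_993, 6_632_666, f"q{i}", gap=-1) for i in range(3)]
        call = call_topology(
            _boundary("left", 98_990), _boundary("right", 6_632_670), junctions, CHR_N
        )
        assert call.L == 98_994


class TestDeletionArithmetic:
    @pytest.mark.parametrize(
        "deletions,expected",
        [
            ((98_993, 115_914), (99, 116)),
            ((120_224, 88_133), (120, 88)),
            ((0, 0), (0, 0)),
            ((1_500, 2_499), (2, 2)),  # .5 rounds away from zero
            ((2_500, 499), (3, 0)),
        ],
    )
    def test_kb_rounding(self, deletions, expected):
        dl, dr = deletions
        call = CircularizationCall(
            "chr", CHR_N, dl + 1, CHR_N - dr, "terminal_deletion_only"
        )
        assert deletion_sizes_kb(call) == expected

    def test_genome_loss_with_published_lengths(self):
        call = CircularizationCall(
            "chromosome", CHR_N, 98_994, 6_632_666, "terminal_deletion_only"
        )
        loss = genome_loss_fraction(PUBLISHED_LENGTHS, ["pSCL4"], call)
        assert loss == pytest.approx(23.0877, abs=0.001)
        assert loss >= 20.0

    def test_no_losses_zero_percent(self):
        assert genome_loss_fraction(PUBLISHED_LENGTHS, []) == 0.0

    def test_whole_single_replicon_lost_is_total(self):
        assert genome_loss_fraction({"chr": 1_000}, ["chr"]) == 100.0

    def test_unknown_replicon_rejected(self):
        with pytest.raises(ValueError, match="unknown replicon"):
            genome_loss_fraction(PUBLISHED_LENGTHS, ["pXYZ"])
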