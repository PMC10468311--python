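"""Junction clustering, TSD-overlap insertion calling, and annotation."""

import pytest

from trapmap.seqio import FeatureRecord
from trapmap.split_align import FIVE, THREE, SegmentHit, SplitRead
from trapmap.te_mapper import (
    ONE_SIDED,
    InsertionCall,
    call_insertions,
    classify_reference_status,
    cluster_junctions,
    terminus_offset,
)


def mk_split(pos, side, orientation="+", contig="chr1", te="tx", read_id="r"):
    g = SegmentHit(contig, max(0, pos - 50), pos, "+", 0, 50)
    t = SegmentHit(te, 0, 50, "+", 50, 100)
    return SplitRead(read_id, g, t, pos, side, orientation)


class TestClusterJunctions:
    def test_empty_input(self):
        assert cluster_junctions([], 3) == []

    def test_modal_breakpoint_with_tolerance(self):
        reads = [mk_split(p, FIVE, read_id=f"r{i}")
                 for i, p in enumerate([1050, 1051, 1050])]
        [cl] = cluster_junctions(reads, cluster_tol=3)
        assert (cl.breakpoint, cl.support) == (1050, 3)
        assert sorted(cl.members) == ["r0", "r1", "r2"]

    def test_modal_tie_breaks_to_smaller_coordinate(self):
        reads = [mk_split(p, FIVE, read_id=f"r{i}")
                 for i, p in enumerate([1051, 1050])]
        [cl] = cluster_junctions(reads, cluster_tol=3)
        assert cl.breakpoint == 1050

    def test_sides_stratify_into_separate_clusters(self):
        reads = [mk_split(1050, FIVE), mk_split(1050, THREE)]
        assert len(cluster_junctions(reads, 3)) == 2

    def test_gap_beyond_tolerance_splits_clusters(self):
        reads = [mk_split(p, FIVE) for p in (1050, 1054)]
        assert len(cluster_junctions(reads, cluster_tol=3)) == 2
        assert len(cluster_junctions(reads, cluster_tol=4)) == 1

    def test_partition_preserves_membership(self):
        reads = [mk_split(p, FIVE, read_id=f"r{p}") for p in range(1000, 1020)]
        clusters = cluster_junctions(reads, 1)
        assert sorted(m for c in clusters for m in c.members) == sorted(
            r.read_id for r in reads)


def _genome_with_octamer():
    seq = "T" * 1050 + "ACGTAAAA" + "G" * 1000
    return {"chr1": seq}


class TestCallInsertions:
    def test_tsd_from_junction_overlap(self):
        # left junction 1058, right junction 1050 -> TSD genome[1050:1058]
        reads = ([mk_split(1058, FIVE, read_id=f"a{i}") for i in range(3)]
                 + [mk_split(1050, THREE, read_id=f"b{i}") for i in range(2)])
        clusters = cluster_junctions(reads, 3)
        [call] = call_insertions(clusters, _genome_with_octamer())
        assert (call.tsd_len, call.tsd_seq, call.report_pos) == (8, "ACGTAAAA", 1051)
        assert (call.support_left, call.support_right) == (3, 2)

    def test_minus_orientation_pairs_via_swapped_sides(self):
        # for '-' insertions the left junction abuts the TE 3' end
        reads = [mk_split(1058, THREE, "-"), mk_split(1050, FIVE, "-")]
        [call] = call_insertions(cluster_junctions(reads, 3), _genome_with_octamer())
        assert (call.tsd_len, call.tsd_seq, call.insert_orientation) == (
            8, "ACGTAAAA", "-")

    def test_zero_tsd_boundary(self):
        reads = [mk_split(2000, FIVE), mk_split(2000, THREE)]
        [call] = call_insertions(cluster_junctions(reads, 3), _genome_with_octamer())
        assert (call.tsd_len, call.tsd_seq) == (0, "")

    def test_overlap_beyond_tsd_max_left_one_sided(self):
        reads = [mk_split(1100, FIVE), mk_split(1050, THREE)]
        calls = call_insertions(cluster_junctions(reads, 3),
                                _genome_with_octamer(), tsd_max=30)
        assert {c.status for c in calls} == {ONE_SIDED}

    def test_negative_overlap_stays_one_sided(self):
        # left junction *upstream* of right junction: no TSD-consistent pair
        reads = [mk_split(1050, FIVE), mk_split(1058, THREE)]
        calls = call_insertions(cluster_junctions(reads, 3), _genome_with_octamer())
        assert {c.status for c in calls} == {ONE_SIDED}
        assert all(c.tsd_seq == "" for c in calls)

    def test_min_support_monotonicity(self, study_calls, study, study_reads):
        from trapmap.split_align import find_split_alignments
        from trapmap.te_mapper import cluster_junctions as cj
        splits = find_split_alignments(study_reads, study.genome_pre,
                                       study.te_library)
        clusters = cj(splits, 3)
        previous = None
        for ms in (1, 2, 5, 10, 50):
            n = len(call_insertions(clusters, study.genome_pre, min_support=ms))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_zero_coverage_produces_zero_calls(self):
        assert call_insertions([], _genome_with_octamer()) == []


class TestTruthRecovery:
    def test_planted_insertions_recovered_exactly(self, study, study_calls):
        """Every planted insertion is recovered with exact position, TSD
        sequence and orientation; no extra two-sided calls."""
        two_sided = [c for c in study_calls if c.status != ONE_SIDED]
        got = {(c.contig, c.report_pos, c.tsd_seq, c.te_name,
                c.insert_orientation) for c in two_sided}
        want = {(t.contig, t.report_pos, t.tsd_seq, t.te_name, t.orientation)
                for t in study.truths}
        assert got == want

    def test_tsd_matches_independent_substring_oracle(self, study, study_calls):
        gseq = {g.name: g.seq for g in study.genome_pre}
        for c in study_calls:
            assert c.tsd_seq == gseq[c.contig][c.right_junction:c.left_junction]


class TestReferenceStatus:
    def _call(self, pos=5000):
        return InsertionCall("chr1", pos + 8, pos, 8, "ACGTACGT", "tx", "+",
                             3, 3, "non_reference")

    def test_same_family_instance_nearby_means_reference(self):
        feats = [FeatureRecord("chr1", 4990, 6000, "+", "TE_instance",
                               {"family": "tx"})]
        assert classify_reference_status(self._call(), feats).status == "reference"

    def test_no_instance_nearby_means_non_reference(self):
        assert classify_reference_status(self._call(), []).status == "non_reference"

    def test_different_family_does_not_match(self):
        feats = [FeatureRecord("chr1", 4990, 6000, "+", "TE_instance",
                               {"family": "other"})]
        assert classify_reference_status(self._call(), feats).status == "non_reference"

    def test_one_sided_status_preserved(self):
        call = InsertionCall("chr1", 5000, 5000, 0, "", "tx", "+", 1, 0,
                             ONE_SIDED)
        feats = [FeatureRecord("chr1", 4990, 6000, "+", "TE_instance",
                               {"family": "tx"})]
        assert classify_reference_status(call, feats).status == ONE_SIDED


class TestTerminusOffset:
    @pytest.mark.parametrize("trap,terminus,expected", [
        (12_004_982, 12_004_481, 501),
        (12_004_481, 12_004_481, 0),
        (12_004_531, 12_004_481, 50),
        (12_004_431, 12_004_481, -50),
    ])
    def test_signed_distance(self, trap, terminus, expected):
        assert terminus_offset("2L", trap, "2L", terminus) == expected

    def test_different_contigs_error(self):
        with pytest.raises(ValueError):
            terminus_offset("2L", 100, "2R", 100)
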