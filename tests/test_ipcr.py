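"""iPCR flank trimming, placement, trap-site calling and annotation."""

import pytest

from trapmap import synth
from trapmap.ipcr import (
    BOTH_ENDS,
    FIVE_ONLY,
    AmbiguousFlankError,
    FlankError,
    FlankMapper,
    FlankRead,
    InconsistentFlanksError,
    TrapCall,
    annotate_trap,
    call_trap_site,
    tally_catalogue,
    trim_element_tail,
)
from trapmap.seqio import FeatureRecord
from trapmap.seqio import reverse_complement as rc
from trapmap.split_align import FIVE, THREE

TAIL = "CATGATGAAATAACAT"  # P-element-like terminal stretch, 16 bp


class TestTrimElementTail:
    def test_three_prime_prefix_strip(self):
        genomic = "ACGT" * 8
        flank = FlankRead("f", THREE, TAIL + genomic, TAIL)
        assert trim_element_tail(flank) == genomic

    def test_reverse_complement_input_normalizes(self):
        genomic = "ACGT" * 8
        flank = FlankRead("f", THREE, rc(TAIL + genomic), TAIL)
        assert trim_element_tail(flank) == genomic

    def test_five_prime_remainder_reads_away_from_element(self):
        genomic = "AACCGGTTAACCGGTTAACCGGTT"
        flank = FlankRead("f", FIVE, genomic + TAIL, TAIL)
        assert trim_element_tail(flank) == rc(genomic)

    def test_missing_tail_is_a_no_hit_error(self):
        flank = FlankRead("f", THREE, "ACGT" * 20, TAIL)
        with pytest.raises(FlankError, match="f"):
            trim_element_tail(flank)

    def test_short_tail_rejected(self):
        flank = FlankRead("f", THREE, TAIL + "ACGT" * 8, TAIL[:8])
        with pytest.raises(FlankError, match="12"):
            trim_element_tail(flank)

    def test_short_remainder_rejected(self):
        flank = FlankRead("f", THREE, TAIL + "ACGTACGTAC", TAIL)
        with pytest.raises(FlankError, match="min_flank"):
            trim_element_tail(flank)


class TestMapFlank:
    def test_unique_placement(self, small_genome):
        g = small_genome[0].seq
        hit = FlankMapper(small_genome).map_flank(g[5000 - 40 : 5000])
        assert (hit.target_name, hit.target_start, hit.target_end,
                hit.target_strand) == ("chr1", 4960, 5000, "+")

    def test_minus_strand_placement(self, small_genome):
        g = small_genome[0].seq
        hit = FlankMapper(small_genome).map_flank(rc(g[1000:1040]))
        assert (hit.target_start, hit.target_end, hit.target_strand) == (
            1000, 1040, "-")

    def test_duplicated_segment_is_ambiguous_with_count(self, small_genome):
        g = small_genome[0].seq
        dup = {"chr1": g + g[2000:2060] + "ACGT" * 30}
        with pytest.raises(AmbiguousFlankError) as exc:
            FlankMapper(dup).map_flank(g[2005:2050])
        assert exc.value.n_placements == 2

    def test_short_remainder_precondition(self, small_genome):
        with pytest.raises(FlankError):
            FlankMapper(small_genome).map_flank("ACGTACGTAC")


@pytest.fixture(scope="module")
def octamer_site():
    """Genome with octamer ACGTAAAA at [1050, 1058) and a planted element."""
    genome = synth.make_genome(13, {"chr2L": 4000})
    seq = genome[0].seq[:1050] + "ACGTAAAA" + genome[0].seq[1058:]
    return [type(genome[0])(name="chr2L", seq=seq)]


@pytest.fixture(scope="module")
def element():
    return synth.make_te_consensus(17, "SXP", 500)


def _flank_hits(genome, truth, element):
    mapper = FlankMapper(genome)
    flanks = synth.simulate_ipcr_flanks(genome, [truth], [element])
    hits = {}
    for fl in flanks:
        hits[fl.end] = mapper.map_flank(trim_element_tail(fl), fl.read_id)
    return hits


class TestCallTrapSite:
    @pytest.mark.parametrize("orientation,expected_tsd", [
        ("+", "ACGTAAAA"),
        ("-", "TTTTACGT"),  # reverse complement per the strand convention
    ])
    def test_octamer_follows_codirectional_rule(self, octamer_site, element,
                                                orientation, expected_tsd):
        truth = synth.TruthInsertion("chr2L", 1050, 8, "SXP", orientation)
        hits = _flank_hits(octamer_site, truth, element)
        call = call_trap_site(hits[FIVE], hits[THREE], octamer_site)
        assert (call.contig, call.report_pos, call.insert_orientation,
                call.tsd_seq, call.evidence) == (
            "chr2L", 1051, orientation, expected_tsd, BOTH_ENDS)

    def test_single_five_prime_flank(self, octamer_site, element):
        truth = synth.TruthInsertion("chr2L", 1050, 8, "SXP", "+")
        hits = _flank_hits(octamer_site, truth, element)
        call = call_trap_site(hits[FIVE], None, octamer_site)
        assert (call.evidence, call.tsd_seq) == (FIVE_ONLY, "")
        assert call.report_pos == 1059  # the 5' junction sits past the TSD

    def test_wrong_overlap_raises_with_observed_value(self, octamer_site, element):
        truth = synth.TruthInsertion("chr2L", 1050, 5, "SXP", "+")
        hits = _flank_hits(octamer_site, truth, element)
        with pytest.raises(InconsistentFlanksError) as exc:
            call_trap_site(hits[FIVE], hits[THREE], octamer_site)
        assert exc.value.observed == 5

    def test_slack_admits_nonstandard_overlap(self, octamer_site, element):
        truth = synth.TruthInsertion("chr2L", 1050, 5, "SXP", "+")
        hits = _flank_hits(octamer_site, truth, element)
        call = call_trap_site(hits[FIVE], hits[THREE], octamer_site,
                              tsd_len=8, tsd_slack=3)
        assert call.report_pos == 1051


class TestAnnotateTrap:
    def _call(self, pos):
        return TrapCall("chr2L", pos, "+", "ACGTAAAA", BOTH_ENDS)

    GENES = [
        FeatureRecord("chr2L", 2000, 3000, "+", "gene", {"id": "esg"}),
        FeatureRecord("chr2L", 2000, 2200, "+", "exon", {"id": "esg_e1"}),
        FeatureRecord("chr2L", 2000, 2050, "+", "five_prime_UTR", {"id": "esg_u"}),
    ]

    def test_natural_te_has_precedence(self):
        tes = [FeatureRecord("chr2L", 2000, 2100, "+", "TE_instance",
                             {"family": "1360"})]
        call = annotate_trap(self._call(2010), self.GENES, tes)
        assert call.feature_context == "natural_TE"

    def test_utr_exon_intron_precedence(self):
        assert annotate_trap(self._call(2010), self.GENES).feature_context == \
            "five_prime_UTR"
        assert annotate_trap(self._call(2100), self.GENES).feature_context == "exon"
        assert annotate_trap(self._call(2500), self.GENES).feature_context == "intron"

    def test_promoter_window_upstream_of_plus_gene(self):
        call = annotate_trap(self._call(1901), self.GENES)  # 100 bp upstream
        assert call.feature_context == "promoter"
        assert call.nearest_gene == "esg"

    def test_intergenic_beyond_promoter_window(self):
        assert annotate_trap(self._call(501), self.GENES).feature_context == \
            "intergenic"

    def test_promoter_window_is_strand_aware(self):
        minus_gene = [FeatureRecord("chr2L", 2000, 3000, "-", "gene",
                                    {"id": "g"})]
        assert annotate_trap(self._call(3101), minus_gene).feature_context == \
            "promoter"
        assert annotate_trap(self._call(1901), minus_gene).feature_context == \
            "intergenic"

    @pytest.mark.parametrize("distance,listed", [(999, True), (1001, False)])
    def test_prior_insertions_within_one_kb(self, distance, listed):
        priors = [FeatureRecord("chr2L", 2000 + distance, 2001 + distance, ".",
                                "prior_insertion", {"id": "SE1-old"})]
        call = annotate_trap(self._call(2001), prior_catalogue=priors)
        assert (call.prior_within_1kb == ["SE1-old"]) is listed


class TestTally:
    ARMS = {"chr2L": "2L", "chr2R": "2R"}

    def _call(self, contig, pos, orientation="+", context=None, evidence=BOTH_ENDS):
        return TrapCall(contig, pos, orientation, "ACGTAAAA" if
                        evidence == BOTH_ENDS else "", evidence,
                        feature_context=context)

    def test_empty_catalogue(self):
        summary = tally_catalogue([], self.ARMS)
        assert summary["total"] == 0 and summary["unique_loci"] == 0

    def test_arm_counts_and_locus_merging(self):
        calls = [self._call("chr2L", 100), self._call("chr2L", 900),
                 self._call("chr2R", 100)]
        summary = tally_catalogue(calls, self.ARMS, merge_radius=1000)
        assert summary["per_arm"] == {"2L": 2, "2R": 1}
        assert summary["unique_loci"] == 2

    def test_orientation_and_natural_te_tallies(self):
        calls = [self._call("chr2L", 100, "+"),
                 self._call("chr2L", 5000, "-", context="natural_TE"),
                 self._call("chr2L", 9000, None, evidence=FIVE_ONLY)]
        summary = tally_catalogue(calls, self.ARMS)
        assert summary["per_orientation"] == {"+": 1, "-": 1, "undetermined": 1}
        assert summary["natural_te_count"] == 1
        assert summary["natural_te_fraction"] == pytest.approx(1 / 3)

    def test_unknown_contig_counts_as_unplaced(self):
        summary = tally_catalogue([self._call("chrU", 5)], self.ARMS)
        assert summary["per_arm"] == {"unplaced": 1}
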