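"""Enhancer-trap insertion-site calling from iPCR flank sequences.

Inverse PCR recovers, for each insertion, an amplicon containing a known
terminal stretch of the element plus the adjacent genomic sequence.  After
trimming the element tail, the genomic remainder is placed on the genome;
the 5′-end and 3′-end placements of one insertion overlap by exactly the
8-base target-site duplication created by P-element integration.

Orientation and TSD conventions
-------------------------------
An insertion whose element 5′→3′ axis is codirectional with the reference
strand is named ``+``, otherwise ``-``.  The 8 bp insertion-site sequence
is reported codirectional with the element: for ``+`` insertions it is the
reference-strand octamer, for ``-`` insertions its reverse complement.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .seqio import FeatureRecord, GenomeSequence, genome_dict, reverse_complement
from .split_align import FIVE, THREE, AlignParams, SeedIndex, SegmentHit

logger = logging.getLogger(__name__)

BOTH_ENDS = "both_ends"
FIVE_ONLY = "five_only"
THREE_ONLY = "three_only"

CONTEXT_PRECEDENCE = (
    "natural_TE", "five_prime_UTR", "exon", "intron", "promoter", "intergenic")


class FlankError(ValueError):
    """Raised when a flank read cannot be trimmed or placed."""


class AmbiguousFlankError(FlankError):
    """Remainder places equally well at multiple loci (repetitive DNA)."""

    def __init__(self, read_id: str, n_placements: int):
        super().__init__(
            f"flank {read_id!r}: {n_placements} equally good genome placements")
        self.n_placements = n_placements


class InconsistentFlanksError(FlankError):
    """Paired flank placements do not overlap by the expected TSD length."""

    def __init__(self, observed: int, expected: int = 8):
        super().__init__(
            f"flank placements overlap by {observed} bases, expected {expected}")
        self.observed = observed


@dataclass(frozen=True)
class FlankRead:
    """One iPCR amplicon sequence.

    ``end`` names the element terminus the amplicon derives from;
    ``element_tail`` is the expected element terminal sequence for that end
    (5′-end tails appear at the remainder-distal side, 3′-end tails at the
    proximal side, see :func:`trim_element_tail`).
    """

    read_id: str
    end: str  # five_prime | three_prime
    seq: str
    element_tail: str

    def __post_init__(self) -> None:
        if self.end not in (FIVE, THREE):
            raise ValueError(f"end must be {FIVE} or {THREE}, got {self.end!r}")


@dataclass
class TrapCall:
    """A called enhancer-trap insertion site.

    ``report_pos`` is the 1-based first base of the duplicated target site;
    ``tsd_seq`` is empty for single-ended evidence, otherwise the 8-mer in
    the element-codirectional frame described in the module docstring.
    """

    contig: str
    report_pos: int
    insert_orientation: str | None
    tsd_seq: str
    evidence: str
    nearest_gene: str | None = None
    feature_context: str | None = None
    prior_within_1kb: list[str] = field(default_factory=list)


def trim_element_tail(flank: FlankRead, min_flank: int = 20) -> str:
    """Strip one exact occurrence of the element tail; return the genomic
    remainder normalized to read *away from* the element.

    In the element frame, a 3′-end amplicon is ``tail + genomic`` (remainder
    already reads away) and a 5′-end amplicon is ``genomic + tail`` (the
    remainder is reverse-complemented so that it, too, reads away from the
    element).  The search is performed on the sequence and its reverse
    complement; absence of the tail in both orientations is an error.
    """
    if len(flank.element_tail) < 12:
        raise FlankError(
            f"element tail for {flank.read_id!r} is shorter than 12 bases")
    for seq in (flank.seq, reverse_complement(flank.seq)):
        if flank.end == THREE and seq.startswith(flank.element_tail):
            remainder = seq[len(flank.element_tail):]
            break
        if flank.end == FIVE and seq.endswith(flank.element_tail):
            remainder = reverse_complement(seq[: -len(flank.element_tail)])
            break
    else:
        raise FlankError(
            f"element tail not found in flank {flank.read_id!r} (either orientation)")
    if len(remainder) < min_flank:
        raise FlankError(
            f"flank {flank.read_id!r}: genomic remainder {len(remainder)} bp "
            f"< min_flank {min_flank}")
    return remainder


@dataclass(frozen=True)
class FlankHit:
    """A placed flank: the genome segment plus which element end it came from."""

    end: str
    hit: SegmentHit

    @property
    def contig(self) -> str:
        return self.hit.target_name

    @property
    def junction(self) -> int:
        """Genome coordinate of the element boundary.

        The remainder reads away from the element, so the junction sits at
        the start of a ``+`` placement and the end of a ``-`` placement for
        3′ flanks — and symmetrically for 5′ flanks, whose remainder runs
        against the element axis.
        """
        if self.end == THREE:
            return self.hit.target_start if self.hit.target_strand == "+" else self.hit.target_end
        return self.hit.target_end if self.hit.target_strand == "-" else self.hit.target_start

    @property
    def implied_orientation(self) -> str:
        """Element 5′→3′ axis direction implied by this placement."""
        if self.end == THREE:
            return self.hit.target_strand
        return "-" if self.hit.target_strand == "+" else "+"


class FlankMapper:
    """Places trimmed flank remainders on a genome by unique best seed match."""

    def __init__(self, genome: Iterable[GenomeSequence] | Mapping[str, str],
                 params: AlignParams | None = None):
        self.params = params or AlignParams()
        self.index = SeedIndex(genome_dict(genome), k=self.params.k)

    def map_flank(self, remainder: str, read_id: str = "?",
                  min_flank: int = 20) -> SegmentHit:
        """Unique best exact-seed placement of a remainder.

        Multiple equally good placements raise :class:`AmbiguousFlankError`
        (the repetitive-DNA case where an insertion cannot be assigned to a
        single natural-TE copy); no placement raises :class:`FlankError`.
        """
        if len(remainder) < min_flank:
            raise FlankError(
                f"flank {read_id!r}: remainder {len(remainder)} bp < {min_flank}")
        p = self.params
        hits = [h for h in self.index.hits(remainder, p.max_mismatch_rate, 1)]
        rc = reverse_complement(remainder)
        for h in self.index.hits(rc, p.max_mismatch_rate, 1):
            hits.append(SegmentHit(
                h.target_name, h.target_start, h.target_end, "-",
                len(remainder) - h.read_end, len(remainder) - h.read_start,
                h.mismatches))
        hits = [h for h in hits
                if (h.read_end - h.read_start) >= p.min_covered * len(remainder)]
        if not hits:
            raise FlankError(f"flank {read_id!r}: no genome placement")
        best = max(h.read_end - h.read_start - h.mismatches for h in hits)
        top = [h for h in hits
               if h.read_end - h.read_start - h.mismatches == best]
        placements = {(h.target_name, h.target_start, h.target_strand) for h in top}
        if len(placements) > 1:
            raise AmbiguousFlankError(read_id, len(placements))
        return top[0]


def map_flank(remainder: str,
              genome: Iterable[GenomeSequence] | Mapping[str, str],
              params: AlignParams | None = None,
              read_id: str = "?", min_flank: int = 20) -> SegmentHit:
    """Convenience wrapper around :meth:`FlankMapper.map_flank`."""
    return FlankMapper(genome, params).map_flank(remainder, read_id, min_flank)


def call_trap_site(five_hit: SegmentHit | None, three_hit: SegmentHit | None,
                   genome: Iterable[GenomeSequence] | Mapping[str, str],
                   tsd_len: int = 8, tsd_slack: int = 0) -> TrapCall:
    """Combine 5′- and 3′-flank placements into a trap call.

    Both-ends evidence requires the two junctions to bracket an overlap of
    exactly ``tsd_len`` bases (within ``tsd_slack``): the duplicated target
    site.  ``tsd_seq`` follows the element-codirectional convention (see
    module docstring).  Single-ended evidence yields a call at the junction
    with empty ``tsd_seq``; orientation is still implied by the one flank.
    """
    gdict = genome_dict(genome)
    fh = FlankHit(FIVE, five_hit) if five_hit is not None else None
    th = FlankHit(THREE, three_hit) if three_hit is not None else None
    if fh is None and th is None:
        raise ValueError("at least one flank placement is required")
    if fh is not None and th is not None:
        if fh.contig != th.contig:
            raise InconsistentFlanksError(-1, tsd_len)
        if fh.implied_orientation != th.implied_orientation:
            raise InconsistentFlanksError(-1, tsd_len)
        lo, hi = sorted((fh.junction, th.junction))
        overlap = hi - lo
        if abs(overlap - tsd_len) > tsd_slack:
            raise InconsistentFlanksError(overlap, tsd_len)
        orientation = fh.implied_orientation
        octamer = gdict[fh.contig][lo:hi]
        tsd = octamer if orientation == "+" else reverse_complement(octamer)
        return TrapCall(contig=fh.contig, report_pos=lo + 1,
                        insert_orientation=orientation, tsd_seq=tsd,
                        evidence=BOTH_ENDS)
    single = fh if fh is not None else th
    return TrapCall(contig=single.contig, report_pos=single.junction + 1,
                    insert_orientation=single.implied_orientation, tsd_seq="",
                    evidence=FIVE_ONLY if single.end == FIVE else THREE_ONLY)


def annotate_trap(call: TrapCall,
                  gff_features: Sequence[FeatureRecord] = (),
                  te_instances: Sequence[FeatureRecord] = (),
                  prior_catalogue: Sequence[FeatureRecord] = (),
                  promoter_window: int = 1000,
                  prior_radius: int = 1000) -> TrapCall:
    """Complete a call with gene context, feature class, and prior neighbours.

    ``feature_context`` follows the precedence natural_TE > five_prime_UTR >
    exon > intron > promoter > intergenic at the reported position; promoter
    means within ``promoter_window`` bases upstream (strand-aware) of an
    annotated gene start.  ``prior_within_1kb`` lists catalogued insertions
    within ``prior_radius`` of the reported position.
    """
    pos = call.report_pos - 1
    here = [f for f in gff_features if f.contig == call.contig]
    context = None
    if any(f.contains(pos) for f in te_instances if f.contig == call.contig):
        context = "natural_TE"
    elif any(f.kind == "five_prime_UTR" and f.contains(pos) for f in here):
        context = "five_prime_UTR"
    elif any(f.kind == "exon" and f.contains(pos) for f in here):
        context = "exon"
    elif any(f.kind == "intron" and f.contains(pos) for f in here) or any(
            f.kind == "gene" and f.contains(pos) for f in here):
        # position inside a gene body but not in an annotated exon/UTR
        context = "intron"
    elif any(_in_promoter(f, pos, promoter_window) for f in here if f.kind == "gene"):
        context = "promoter"
    elif gff_features:
        context = "intergenic"

    nearest = None
    genes = [f for f in here if f.kind == "gene"]
    if genes:
        nearest = min(genes, key=lambda f: _interval_distance(f, pos)).name

    priors = [f.name for f in prior_catalogue
              if f.contig == call.contig and abs(f.start - pos) <= prior_radius]
    return replace(call, feature_context=context, nearest_gene=nearest,
                   prior_within_1kb=priors)


def _in_promoter(gene: FeatureRecord, pos: int, window: int) -> bool:
    if gene.strand == "-":
        return gene.end <= pos < gene.end + window
    return gene.start - window <= pos < gene.start


def _interval_distance(feat: FeatureRecord, pos: int) -> int:
    if feat.contains(pos):
        return 0
    return min(abs(pos - feat.start), abs(pos - (feat.end - 1)))


def tally_catalogue(calls: Sequence[TrapCall],
                    arm_table: Mapping[str, str],
                    merge_radius: int = 1000) -> dict:
    """Summarize a trap-call catalogue.

    Returns counts per chromosome arm, per orientation (``+``/``-``/
    ``undetermined``), the natural-TE fraction, and the number of unique
    loci after merging calls within ``merge_radius`` of each other
    (single-linkage per contig).  Calls on contigs absent from
    ``arm_table`` are tallied under ``unplaced``.
    """
    arms: Counter = Counter()
    orientations: Counter = Counter()
    n_te = 0
    per_contig: dict[str, list[int]] = {}
    for call in calls:
        arms[arm_table.get(call.contig, "unplaced")] += 1
        if call.evidence == BOTH_ENDS and call.insert_orientation in ("+", "-"):
            orientations[call.insert_orientation] += 1
        else:
            orientations["undetermined"] += 1
        if call.feature_context == "natural_TE":
            n_te += 1
        per_contig.setdefault(call.contig, []).append(call.report_pos)
    unique_loci = 0
    for positions in per_contig.values():
        positions.sort()
        prev = None
        for pos in positions:
            if prev is None or pos - prev > merge_radius:
                unique_loci += 1
            prev = pos
    total = len(calls)
    return {
        "total": total,
        "per_arm": dict(arms),
        "per_orientation": {"+": orientations["+"], "-": orientations["-"],
                            "undetermined": orientations["undetermined"]},
        "natural_te_count": n_te,
        "natural_te_fraction": (n_te / total) if total else 0.0,
        "unique_loci": unique_loci,
    }
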