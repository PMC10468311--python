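"""Cluster split-read junction evidence and call TE insertions.

An insertion leaves two junctions in the reference frame.  Because the
target site is duplicated on insertion, the junction whose genome flank
*precedes* the element (the ``left_junction``, at reference position
``p + t`` for an insertion at position ``p`` with TSD length ``t``) lies
*downstream* of the junction whose genome flank follows the element (the
``right_junction``, at ``p``).  Their difference is the TSD length and the
reference slice between them is the TSD sequence — computed from junction
coordinate overlap, never from sequence self-comparison, so it is robust to
TSD octamers that happen to pre-exist elsewhere.

Which TE terminus abuts which junction depends on orientation: for a ``+``
insertion the left junction abuts the element 5′ end; for a ``-`` insertion
it abuts the 3′ end.  For P-element-style elements a both-sided call has
``tsd_len == 8``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .seqio import FeatureRecord, GenomeSequence, genome_dict
from .split_align import FIVE, THREE, SplitRead

logger = logging.getLogger(__name__)

NON_REFERENCE = "non_reference"
REFERENCE = "reference"
ONE_SIDED = "one_sided"


@dataclass(frozen=True)
class JunctionCluster:
    """Split reads sharing (contig, TE, side, orientation) at one locus."""

    contig: str
    breakpoint: int  # modal member junction position, 0-based
    te_name: str
    te_side: str
    insert_orientation: str
    support: int
    members: tuple[str, ...] = ()
    positions: tuple[int, ...] = ()


@dataclass
class InsertionCall:
    """A called TE insertion.

    ``left_junction >= right_junction``; ``tsd_len = left - right``;
    ``tsd_seq = genome[right_junction:left_junction]`` on the reference
    strand; ``report_pos`` is the 1-based position of the first TSD base.
    One-sided calls carry the single junction in both fields and an empty
    ``tsd_seq``.
    """

    contig: str
    left_junction: int
    right_junction: int
    tsd_len: int
    tsd_seq: str
    te_name: str
    insert_orientation: str
    support_left: int
    support_right: int
    status: str
    report_pos: int = field(default=0)

    def __post_init__(self) -> None:
        if self.report_pos == 0:
            self.report_pos = self.right_junction + 1

    @property
    def support(self) -> int:
        return self.support_left + self.support_right


def cluster_junctions(split_reads: Iterable[SplitRead],
                      cluster_tol: int = 3) -> list[JunctionCluster]:
    """Single-linkage clustering of junction positions within strata.

    Reads are stratified by (contig, TE, te_side, orientation); positions
    with successive gaps <= ``cluster_tol`` join one cluster.  The cluster
    breakpoint is the modal member position (ties broken toward the
    smallest coordinate).
    """
    if cluster_tol < 0:
        raise ValueError("cluster_tol must be >= 0")
    strata: dict[tuple, list[SplitRead]] = defaultdict(list)
    for sr in split_reads:
        strata[sr.stratum].append(sr)
    clusters: list[JunctionCluster] = []
    for (contig, te_name, side, orient), members in sorted(strata.items()):
        members.sort(key=lambda sr: sr.junction_pos)
        block: list[SplitRead] = []
        for sr in members:
            if block and sr.junction_pos - block[-1].junction_pos > cluster_tol:
                clusters.append(_finish_cluster(contig, te_name, side, orient, block))
                block = []
            block.append(sr)
        if block:
            clusters.append(_finish_cluster(contig, te_name, side, orient, block))
    return clusters


def _finish_cluster(contig: str, te_name: str, side: str, orient: str,
                    block: Sequence[SplitRead]) -> JunctionCluster:
    counts = Counter(sr.junction_pos for sr in block)
    top = max(counts.values())
    breakpoint = min(pos for pos, c in counts.items() if c == top)
    return JunctionCluster(
        contig=contig, breakpoint=breakpoint, te_name=te_name, te_side=side,
        insert_orientation=orient, support=len(block),
        members=tuple(sr.read_id for sr in block),
        positions=tuple(sr.junction_pos for sr in block),
    )


def _left_side_for(orientation: str) -> str:
    """TE side abutting the junction whose genome flank precedes the element."""
    return FIVE if orientation == "+" else THREE


def call_insertions(clusters: Iterable[JunctionCluster],
                    genome: Iterable[GenomeSequence] | Mapping[str, str],
                    tsd_max: int = 30,
                    min_support: int = 1) -> list[InsertionCall]:
    """Pair side clusters into insertion calls with TSD recovery.

    Within each (contig, TE, orientation) stratum, a left-flank cluster at
    ``bl`` pairs with the nearest right-flank cluster at ``br`` satisfying
    ``0 <= bl - br <= tsd_max``.  Pairing is greedy by combined support
    (ties toward the smaller coordinate) and each cluster is used at most
    once; leftover clusters with enough support become one-sided calls.
    """
    gdict = genome_dict(genome)
    strata: dict[tuple, dict[str, list[JunctionCluster]]] = defaultdict(
        lambda: {"left": [], "right": []})
    for cl in clusters:
        if cl.support < min_support:
            continue
        key = (cl.contig, cl.te_name, cl.insert_orientation)
        side = "left" if cl.te_side == _left_side_for(cl.insert_orientation) else "right"
        strata[key][side].append(cl)

    calls: list[InsertionCall] = []
    for (contig, te_name, orient), sides in sorted(strata.items()):
        pairs = []
        for li, lc in enumerate(sides["left"]):
            for ri, rc_ in enumerate(sides["right"]):
                t = lc.breakpoint - rc_.breakpoint
                if 0 <= t <= tsd_max:
                    pairs.append((-(lc.support + rc_.support), lc.breakpoint,
                                  rc_.breakpoint, li, ri))
        pairs.sort()
        used_l: set[int] = set()
        used_r: set[int] = set()
        for _, bl, br, li, ri in pairs:
            if li in used_l or ri in used_r:
                continue
            used_l.add(li)
            used_r.add(ri)
            seq = gdict.get(contig, "")
            calls.append(InsertionCall(
                contig=contig, left_junction=bl, right_junction=br,
                tsd_len=bl - br, tsd_seq=seq[br:bl], te_name=te_name,
                insert_orientation=orient,
                support_left=sides["left"][li].support,
                support_right=sides["right"][ri].support,
                status=NON_REFERENCE,
            ))
        for li, lc in enumerate(sides["left"]):
            if li not in used_l:
                calls.append(_one_sided(lc))
        for ri, rc_ in enumerate(sides["right"]):
            if ri not in used_r:
                calls.append(_one_sided(rc_))
    calls.sort(key=lambda c: (c.contig, c.report_pos))
    return calls


def _one_sided(cl: JunctionCluster) -> InsertionCall:
    left = cl.te_side == _left_side_for(cl.insert_orientation)
    return InsertionCall(
        contig=cl.contig, left_junction=cl.breakpoint,
        right_junction=cl.breakpoint, tsd_len=0, tsd_seq="",
        te_name=cl.te_name, insert_orientation=cl.insert_orientation,
        support_left=cl.support if left else 0,
        support_right=0 if left else cl.support,
        status=ONE_SIDED,
    )


def classify_reference_status(call: InsertionCall,
                              te_instance_features: Iterable[FeatureRecord],
                              window: int = 100) -> InsertionCall:
    """Mark a call reference/non-reference against annotated TE copies.

    A call is ``reference`` if an annotated instance of the same family lies
    within ``window`` bases of its reported position; otherwise
    ``non_reference``.  One-sided status is preserved.
    """
    if call.status == ONE_SIDED:
        return call
    pos = call.report_pos - 1
    status = NON_REFERENCE
    for feat in te_instance_features:
        if feat.contig != call.contig:
            continue
        family = feat.attributes.get("family") or feat.attributes.get("id")
        if not family:
            logger.warning("TE instance without family annotation at %s:%d",
                           feat.contig, feat.start)
            continue
        if family != call.te_name:
            continue
        if feat.start - window <= pos <= feat.end + window:
            status = REFERENCE
            break
    return replace(call, status=status)


def terminus_offset(trap_contig: str, trap_pos: int,
                    te_contig: str, terminus_pos: int) -> int:
    """Signed distance from a TE terminus to a second insertion's breakpoint.

    Both positions must be in the same coordinate frame (conventionally the
    1-based reported positions) and on one contig.  Positive means the trap
    lies downstream (3′) of the terminus on the reference strand.
    """
    if trap_contig != te_contig:
        raise ValueError(
            f"positions on different contigs: {trap_contig!r} vs {te_contig!r}")
    return trap_pos - terminus_pos
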