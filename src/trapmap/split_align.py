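"""Decompose junction-spanning reads into genome-aligned and TE-aligned parts.

A read crossing an insertion junction aligns partly to the host genome and
partly to a TE consensus ("split read").  Two pathways produce the same
:class:`SplitRead` evidence:

* an internal exact k-mer seed + ungapped extension aligner
  (:func:`find_split_alignments`) — sufficient because junction detection
  only needs locally exact anchors, and an indel-free model keeps the
  geometry auditable;
* ingestion of external soft-clipped alignments in SAM form
  (:func:`ingest_sam_splits`), the contract for reusing a general-purpose
  short-read aligner's output.

Junction frame (the case table)
-------------------------------
Everything is reduced to reference-strand coordinates.  ``junction_pos`` is
the genome coordinate of the genome/TE boundary: for a read whose genome
part precedes the TE part (genome flank on the left), it is the first
genome position not covered by the flank; for a genome flank on the right
it is the first genome position of the flank.  With the genome part of the
(possibly reverse-complemented) read fixed on the reference plus strand:

====================  =========  ===================  ========  ===========
genome flank          TE strand  TE terminus touched  te_side   orientation
====================  =========  ===================  ========  ===========
left  (read prefix)   ``+``      start (5′)           5′        ``+``
left  (read prefix)   ``-``      end   (3′)           3′        ``-``
right (read suffix)   ``+``      end   (3′)           3′        ``+``
right (read suffix)   ``-``      start (5′)           5′        ``-``
====================  =========  ===================  ========  ===========

``insert_orientation`` is ``+`` when the element's 5′→3′ axis is
codirectional with the reference strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .seqio import GenomeSequence, TEConsensus, genome_dict, reverse_complement

FIVE = "five_prime"
THREE = "three_prime"


@dataclass(frozen=True)
class AlignParams:
    """Tunables for the internal split aligner.

    k: exact seed length (bases).
    min_segment: minimum aligned length on each side of a junction.
    max_mismatch_rate: per-segment mismatch tolerance for ungapped extension.
    end_slack: maximum distance of the TE-aligned segment from a TE terminus.
    min_covered: minimum fraction of the read covered by the two segments.
    junction_gap: maximum unaligned gap tolerated between the two segments.
    seed_stride: query seed sampling stride (1 = every position).
    """

    k: int = 15
    min_segment: int = 20
    max_mismatch_rate: float = 0.05
    end_slack: int = 5
    min_covered: float = 0.9
    junction_gap: int = 3
    seed_stride: int = 4


@dataclass(frozen=True)
class SegmentHit:
    """An ungapped alignment of part of a read to one target sequence.

    ``read_start``/``read_end`` are on the read *as sequenced*;
    ``target_strand`` says which strand of the read matches the target's
    forward sequence.
    """

    target_name: str
    target_start: int
    target_end: int
    target_strand: str
    read_start: int
    read_end: int
    mismatches: int = 0

    def __len__(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class SplitRead:
    """One read decomposed at a genome/TE junction (reference-strand frame)."""

    read_id: str
    genome_hit: SegmentHit
    te_hit: SegmentHit
    junction_pos: int
    te_side: str  # five_prime | three_prime
    insert_orientation: str  # + | -

    @property
    def contig(self) -> str:
        return self.genome_hit.target_name

    @property
    def te_name(self) -> str:
        return self.te_hit.target_name

    @property
    def stratum(self) -> tuple[str, str, str, str]:
        return (self.contig, self.te_name, self.te_side, self.insert_orientation)


class SeedIndex:
    """Exact k-mer index over a set of target sequences (forward strand).

    Seeds containing N are skipped.  :meth:`hits` returns maximal ungapped
    extensions of query seeds, one per (target, diagonal).
    """

    def __init__(self, targets: Mapping[str, str], k: int = 15):
        if not targets:
            raise ValueError("empty target set")
        self.k = k
        self.targets = dict(targets)
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.targets.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" not in kmer:
                    self._index[kmer].append((name, pos))

    def hits(self, query: str, max_mismatch_rate: float = 0.05,
             stride: int = 1) -> list[SegmentHit]:
        """Maximal ungapped extensions of exact seed matches of ``query``.

        Returned hits are on the target forward strand (``target_strand='+'``)
        with read coordinates in the frame of ``query`` as passed.
        """
        k = self.k
        seen_diagonals: set[tuple[str, int]] = set()
        out: list[SegmentHit] = []
        qlen = len(query)
        positions = list(range(0, qlen - k + 1, stride))
        # always seed the last window so short trailing segments are anchored
        if positions and positions[-1] != qlen - k:
            positions.append(qlen - k)
        for qpos in positions:
            for name, tpos in self._index.get(query[qpos : qpos + k], ()):
                diag = (name, tpos - qpos)
                if diag in seen_diagonals:
                    continue
                seen_diagonals.add(diag)
                out.append(self._extend(query, name, qpos, tpos, max_mismatch_rate))
        return out

    def _extend(self, query: str, name: str, qpos: int, tpos: int,
                rate: float) -> SegmentHit:
        target = self.targets[name]
        k = self.k
        mm = 0
        # extend right
        qe, te = qpos + k, tpos + k
        while qe < len(query) and te < len(target):
            if query[qe] == target[te] and target[te] != "N":
                qe += 1
                te += 1
            elif (mm + 1) <= rate * (qe - qpos + 1):
                mm += 1
                qe += 1
                te += 1
            else:
                break
        # extend left
        qs, ts = qpos, tpos
        while qs > 0 and ts > 0:
            if query[qs - 1] == target[ts - 1] and target[ts - 1] != "N":
                qs -= 1
                ts -= 1
            elif (mm + 1) <= rate * (qe - qs + 1):
                mm += 1
                qs -= 1
                ts -= 1
            else:
                break
        # trim terminal mismatches so hits end on matches
        while qs < qe and query[qs] != target[ts]:
            qs += 1
            ts += 1
            mm -= 1
        while qe > qs and query[qe - 1] != target[te - 1]:
            qe -= 1
            te -= 1
            mm -= 1
        return SegmentHit(name, ts, te, "+", qs, qe, mm)


@dataclass(frozen=True)
class _Candidate:
    split: SplitRead
    score: int


class SplitReadAligner:
    """Seed-and-extend split-read finder over a genome and a TE library."""

    def __init__(self, genome: Iterable[GenomeSequence] | Mapping[str, str],
                 te_library: Sequence[TEConsensus] | Mapping[str, str],
                 params: AlignParams | None = None):
        self.params = params or AlignParams()
        gdict = genome_dict(genome)
        if isinstance(te_library, Mapping):
            tdict = dict(te_library)
        else:
            tdict = {t.name: t.seq for t in te_library}
        if not tdict:
            raise ValueError("empty TE library")
        self.genome_index = SeedIndex(gdict, k=self.params.k)
        self.te_index = SeedIndex(tdict, k=self.params.k)
        self.te_lengths = {n: len(s) for n, s in tdict.items()}

    # -- candidate construction ------------------------------------------

    def _pair_candidates(self, read_id: str, q: str, ghits: list[SegmentHit],
                         thits: list[SegmentHit], rc_frame: bool) -> list[_Candidate]:
        qlen = len(q)
        out: list[_Candidate] = []
        for g in ghits:
            for t in thits:
                cand = self._evaluate_pair(read_id, q, g, t, rc_frame, qlen)
                if cand is not None:
                    out.append(cand)
        return out

    def _evaluate_pair(self, read_id: str, q: str, g: SegmentHit, t: SegmentHit,
                       rc_frame: bool, qlen: int) -> _Candidate | None:
        p = self.params
        if g.read_start == t.read_start:
            return None
        genome_left = g.read_start < t.read_start
        # the TE hit is bounded by the element terminus, so its boundary
        # facing the genome flank anchors the junction exactly
        r_j = t.read_start if genome_left else t.read_end
        # effective genome segment stops at the junction (the genome hit may
        # overrun the junction by chance base matches)
        if genome_left:
            g_eff = r_j - g.read_start
            gap = max(0, t.read_start - g.read_end)
        else:
            g_eff = g.read_end - r_j
            gap = max(0, g.read_start - t.read_end)
        t_len = t.read_end - t.read_start
        if g_eff < p.min_segment or t_len < p.min_segment:
            return None
        if gap > p.junction_gap:
            return None
        covered = (max(g.read_end, t.read_end) - min(g.read_start, t.read_start)) - gap
        if covered < p.min_covered * qlen:
            return None
        case = _junction_case(genome_left, t, self.te_lengths[t.target_name],
                              p.end_slack)
        if case is None:
            return None
        te_side, orientation = case
        junction = g.target_start + (r_j - g.read_start)
        if not (0 <= junction <= len(self.genome_index.targets[g.target_name])):
            return None
        score = (g_eff - g.mismatches) + (t_len - t.mismatches)
        if rc_frame:  # report read intervals on the read as sequenced
            g = replace(g, target_strand="-",
                        read_start=qlen - g.read_end, read_end=qlen - g.read_start)
            t = replace(t, target_strand="-" if t.target_strand == "+" else "+",
                        read_start=qlen - t.read_end, read_end=qlen - t.read_start)
        split = SplitRead(read_id, g, t, junction, te_side, orientation)
        return _Candidate(split, score)

    # -- public API -------------------------------------------------------

    def find_read(self, read_id: str, seq: str,
                  counters: Counter | None = None) -> SplitRead | None:
        p = self.params
        if len(seq) < 2 * p.min_segment:
            if counters is not None:
                counters["too_short"] += 1
            return None
        qf, qr = seq, reverse_complement(seq)
        gh_f = self.genome_index.hits(qf, p.max_mismatch_rate, p.seed_stride)
        gh_r = self.genome_index.hits(qr, p.max_mismatch_rate, p.seed_stride)
        if not gh_f and not gh_r:
            return None
        th_f = self.te_index.hits(qf, p.max_mismatch_rate, p.seed_stride)
        th_r = self.te_index.hits(qr, p.max_mismatch_rate, p.seed_stride)
        if not th_f and not th_r:
            return None
        qlen = len(seq)
        # within each genome-forward frame, the TE part may match either TE
        # strand: fold hits found on the opposite frame back in as '-' hits
        te_in_f = th_f + [_flip_frame(h, qlen) for h in th_r]
        te_in_r = th_r + [_flip_frame(h, qlen) for h in th_f]
        cands = self._pair_candidates(read_id, qf, gh_f, te_in_f, rc_frame=False)
        cands += self._pair_candidates(read_id, qr, gh_r, te_in_r, rc_frame=True)
        if not cands:
            return None
        best = max(c.score for c in cands)
        top = {c.split for c in cands if c.score == best}
        if len(top) > 1:
            if counters is not None:
                counters["ambiguous"] += 1
            return None
        return next(iter(top))

    def find(self, reads: Iterable[tuple[str, str]],
             counters: Counter | None = None) -> list[SplitRead]:
        out = []
        for read_id, seq in reads:
            sr = self.find_read(read_id, seq, counters)
            if sr is not None:
                out.append(sr)
        return out


def _flip_frame(hit: SegmentHit, qlen: int) -> SegmentHit:
    """Re-express a hit found on the reverse-complement frame in the other
    frame's read coordinates (target interval unchanged, strand flipped)."""
    return replace(hit,
                   target_strand="-" if hit.target_strand == "+" else "+",
                   read_start=qlen - hit.read_end,
                   read_end=qlen - hit.read_start)


def _junction_case(genome_left: bool, te_hit: SegmentHit, te_len: int,
                   end_slack: int) -> tuple[str, str] | None:
    """Resolve (te_side, insert_orientation) from the case table, or None if
    the TE segment does not touch the required terminus."""
    touches_start = te_hit.target_start <= end_slack
    touches_end = te_len - te_hit.target_end <= end_slack
    if genome_left:
        if te_hit.target_strand == "+" and touches_start:
            return FIVE, "+"
        if te_hit.target_strand == "-" and touches_end:
            return THREE, "-"
    else:
        if te_hit.target_strand == "+" and touches_end:
            return THREE, "+"
        if te_hit.target_strand == "-" and touches_start:
            return FIVE, "-"
    return None


def find_split_alignments(reads: Iterable[tuple[str, str]],
                          genome: Iterable[GenomeSequence] | Mapping[str, str],
                          te_library: Sequence[TEConsensus] | Mapping[str, str],
                          params: AlignParams | None = None,
                          counters: Counter | None = None) -> list[SplitRead]:
    """Find at most one :class:`SplitRead` per read (best by matched bases).

    Reads matching only the genome or only the TE library yield nothing;
    score ties across distinct placements are rejected as ambiguous.  Both
    read orientations are searched and results are reported in
    reference-strand coordinates.
    """
    return SplitReadAligner(genome, te_library, params).find(reads, counters)


# ---------------------------------------------------------------------------
# SAM ingestion pathway
# ---------------------------------------------------------------------------


def _as_sequenced_interval(start: int, end: int, read_len: int,
                           is_reverse: bool) -> tuple[int, int]:
    """Convert a stored-SEQ interval to read-as-sequenced coordinates."""
    if is_reverse:
        return read_len - end, read_len - start
    return start, end


def ingest_sam_splits(sam_genome: str, sam_te: str,
                      params: AlignParams | None = None,
                      counters: Counter | None = None) -> list[SplitRead]:
    """Build split reads from two SAM files: reads vs genome and vs TE library.

    A split is emitted when a read's genome alignment soft-clips at least
    ``min_segment`` bases and the same read's TE alignment covers the clipped
    portion at a TE terminus.  ``junction_pos``, ``te_side`` and
    ``insert_orientation`` follow the same case table as the internal
    aligner, so the two pathways agree on identical evidence.
    """
    import pysam

    p = params or AlignParams()
    counters = counters if counters is not None else Counter()

    te_alns: dict[str, list] = defaultdict(list)
    with pysam.AlignmentFile(sam_te, "r", check_sq=False) as fh:
        te_lengths = dict(zip(fh.references, fh.lengths))
        for rec in fh:
            if not rec.is_unmapped:
                te_alns[rec.query_name].append(rec)

    out: list[SplitRead] = []
    with pysam.AlignmentFile(sam_genome, "r", check_sq=False) as fh:
        for g in fh:
            if g.is_unmapped or g.cigartuples is None:
                continue
            left_clip = g.cigartuples[0][1] if g.cigartuples[0][0] == 4 else 0
            right_clip = g.cigartuples[-1][1] if g.cigartuples[-1][0] == 4 else 0
            if max(left_clip, right_clip) < p.min_segment:
                counters["no_clip"] += 1
                continue
            # clip at the CIGAR end is always on the reference-right side
            genome_left = right_clip >= left_clip
            junction = g.reference_end if genome_left else g.reference_start
            read_len = g.infer_read_length() or len(g.query_sequence or "")
            if genome_left:
                clip_stored = (g.query_alignment_end, read_len)
            else:
                clip_stored = (0, g.query_alignment_start)
            clip_seq_iv = _as_sequenced_interval(*clip_stored, read_len, g.is_reverse)

            best: tuple[int, SplitRead] | None = None
            tie = False
            for t in te_alns.get(g.query_name, ()):
                rel_strand = "+" if (t.is_reverse == g.is_reverse) else "-"
                t_iv = _as_sequenced_interval(
                    t.query_alignment_start, t.query_alignment_end,
                    read_len, t.is_reverse)
                overlap = min(clip_seq_iv[1], t_iv[1]) - max(clip_seq_iv[0], t_iv[0])
                if overlap < p.min_segment:
                    continue
                te_hit = SegmentHit(t.reference_name, t.reference_start,
                                    t.reference_end, rel_strand, *t_iv)
                case = _junction_case(genome_left, te_hit,
                                      te_lengths[t.reference_name], p.end_slack)
                if case is None:
                    continue
                te_side, orientation = case
                g_iv = _as_sequenced_interval(
                    g.query_alignment_start, g.query_alignment_end,
                    read_len, g.is_reverse)
                genome_hit = SegmentHit(g.reference_name, g.reference_start,
                                        g.reference_end,
                                        "-" if g.is_reverse else "+", *g_iv)
                # report te strand on the as-sequenced read, as the internal
                # aligner does
                te_hit_rep = replace(
                    te_hit,
                    target_strand=rel_strand if not g.is_reverse
                    else ("-" if rel_strand == "+" else "+"))
                sr = SplitRead(g.query_name, genome_hit, te_hit_rep,
                               junction, te_side, orientation)
                if best is None or overlap > best[0]:
                    best = (overlap, sr)
                    tie = False
                elif overlap == best[0] and sr != best[1]:
                    tie = True
            if best is None:
                counters["clip_without_te_support"] += 1
            elif tie:
                counters["ambiguous"] += 1
            else:
                out.append(best[1])
    return out
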