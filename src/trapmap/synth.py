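"""Synthetic genomes, planted insertions, reads, iPCR flanks and placement
tables with machine-readable truth — every pipeline stage is testable
against known ground truth without any external download.

Insertion geometry: planting an element ``T`` at 0-based target position
``p`` with TSD length ``t`` produces ``G[0, p+t) + T_oriented + G[p, end)``
where ``T_oriented`` is ``T`` for ``+`` insertions and its reverse
complement for ``-`` insertions.  The octamer (or t-mer) ``G[p, p+t)`` is
thereby duplicated on both sides of the element, exactly the geometry a
cut-and-paste P-element integration leaves behind.

All generators draw from a single integer seed and are bit-reproducible;
the error model is substitution-only, matching the indel-free contract of
the split aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import GenomeSequence, TEConsensus, reverse_complement
from .split_align import FIVE, THREE
from .ipcr import FlankRead
from .te_counts import AlignmentRecord

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthInsertion:
    """Ground truth for one planted insertion.

    ``p`` is the 0-based first TSD base in the *pre-insertion* genome;
    reported calls should equal ``report_pos = p + 1``.  ``tsd_seq`` is
    filled in at planting time (reference-strand octamer).
    """

    contig: str
    p: int
    tsd_len: int
    te_name: str
    orientation: str
    tsd_seq: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")

    @property
    def report_pos(self) -> int:
        return self.p + 1


def make_genome(seed: int, lengths: Mapping[str, int],
                gc: float = 0.42) -> list[GenomeSequence]:
    """Reproducible random genome with the given contig lengths and GC.

    The default GC fraction of 0.42 approximates *Drosophila* euchromatin.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for name, length in lengths.items():
        seq = "".join(rng.choice(_BASES, size=length, p=probs))
        out.append(GenomeSequence(name=name, seq=seq))
    return out


def make_te_consensus(seed: int, name: str, length: int = 1500,
                      te_class: str = "II_DNA", family: str = "") -> TEConsensus:
    """Reproducible random TE consensus sequence."""
    rng = np.random.default_rng(seed)
    return TEConsensus(name=name, seq="".join(rng.choice(_BASES, size=length)),
                       te_class=te_class, family=family)


def splice_insertion(seq: str, p: int, tsd_len: int, te_seq: str,
                     orientation: str) -> str:
    """Insert an element at ``p`` with a ``tsd_len`` target-site duplication."""
    if p + tsd_len > len(seq):
        raise ValueError(f"insertion at {p} (+{tsd_len} TSD) exceeds contig length")
    te_oriented = te_seq if orientation == "+" else reverse_complement(te_seq)
    return seq[: p + tsd_len] + te_oriented + seq[p:]


def plant_insertions(genome: Sequence[GenomeSequence],
                     truths: Sequence[TruthInsertion],
                     te_library: Sequence[TEConsensus],
                     margin: int = 200) -> tuple[list[GenomeSequence], list[TruthInsertion]]:
    """Plant a disjoint truth set; returns the modified genome and the truth
    records completed with their TSD sequences.

    Truths on one contig must be separated by at least ``margin`` bases
    (overlapping or crowded truth sets are an error, so recovery tests have
    unambiguous expectations).
    """
    te_seqs = {t.name: t.seq for t in te_library}
    per_contig: dict[str, list[TruthInsertion]] = {}
    for tr in truths:
        if tr.te_name not in te_seqs:
            raise ValueError(f"unknown TE {tr.te_name!r} in truth set")
        per_contig.setdefault(tr.contig, []).append(tr)
    out_genome: list[GenomeSequence] = []
    completed: list[TruthInsertion] = []
    for g in genome:
        todo = sorted(per_contig.get(g.name, []), key=lambda t: t.p)
        for a, b in zip(todo, todo[1:]):
            if b.p - (a.p + a.tsd_len) < margin:
                raise ValueError(
                    f"planted insertions at {a.p} and {b.p} on {g.name} "
                    f"closer than margin {margin}")
        seq = g.seq
        for tr in reversed(todo):  # splice right-to-left so coordinates hold
            completed.append(replace(tr, tsd_seq=g.seq[tr.p : tr.p + tr.tsd_len]))
            seq = splice_insertion(seq, tr.p, tr.tsd_len, te_seqs[tr.te_name],
                                   tr.orientation)
        out_genome.append(GenomeSequence(name=g.name, seq=seq, arm=g.arm))
    completed.sort(key=lambda t: (t.contig, t.p))
    return out_genome, completed


def simulate_reads(genome: Sequence[GenomeSequence], read_len: int = 100,
                   coverage: float = 20.0, error_rate: float = 0.0,
                   seed: int = 0, fragment_len: int = 300,
                   fragment_sd: int = 30) -> list[tuple[str, str]]:
    """Paired-end reads with uniform fragment starts over each contig.

    Expected read count is ``coverage * L / read_len`` per contig (mates
    counted separately); substitution errors are applied per base at
    ``error_rate``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for g in genome:
        L = len(g.seq)
        if read_len > L:
            raise ValueError(f"read_len {read_len} exceeds contig {g.name} length")
        n_frags = int(round(coverage * L / (2 * read_len)))
        starts = rng.integers(0, max(1, L - read_len), size=n_frags)
        flens = np.clip(rng.normal(fragment_len, fragment_sd, size=n_frags)
                        .astype(int), read_len, None)
        for i, (s, fl) in enumerate(zip(starts, flens)):
            e = min(int(s) + int(fl), L)
            r1 = g.seq[s : s + read_len]
            r2 = reverse_complement(g.seq[max(0, e - read_len) : e])
            for mate, seq in ((1, r1), (2, r2)):
                if error_rate > 0:
                    seq = _mutate(seq, error_rate, rng)
                reads.append((f"{g.name}_frag{i}/{mate}", seq))
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_ipcr_flanks(genome_pre_insertion: Sequence[GenomeSequence],
                         truths: Sequence[TruthInsertion],
                         te_library: Sequence[TEConsensus],
                         flank_len: int = 60,
                         tail_len: int = 30) -> list[FlankRead]:
    """iPCR amplicons for each truth insertion: one 5′-end and one 3′-end
    flank carrying ``tail_len`` bases of element terminal sequence.

    In the element frame a 5′ amplicon is ``genomic + 5′-terminus`` and a 3′
    amplicon is ``3′-terminus + genomic``; for ``-`` insertions the genomic
    parts are drawn from the reference minus strand accordingly.  Flanks
    that would run off a contig are truncated with a warning.
    """
    gdict = {g.name: g.seq for g in genome_pre_insertion}
    te_seqs = {t.name: t.seq for t in te_library}
    out: list[FlankRead] = []
    for tr in truths:
        G = gdict[tr.contig]
        te = te_seqs[tr.te_name]
        tail5, tail3 = te[:tail_len], te[-tail_len:]
        p, t = tr.p, tr.tsd_len
        lo5 = p + t - flank_len
        if lo5 < 0:
            logger.warning("flank for %s at %s:%d truncated at contig start",
                           tr.te_name, tr.contig, tr.p)
            lo5 = 0
        hi3 = min(p + flank_len, len(G))
        if hi3 < p + flank_len:
            logger.warning("flank for %s at %s:%d truncated at contig end",
                           tr.te_name, tr.contig, tr.p)
        upstream = G[lo5 : p + t]   # genome flank preceding the element
        downstream = G[p:hi3]       # genome flank following the element
        if tr.orientation == "+":
            five_seq = upstream + tail5
            three_seq = tail3 + downstream
        else:
            five_seq = reverse_complement(downstream) + tail5
            three_seq = tail3 + reverse_complement(upstream)
        stem = f"{tr.contig}:{tr.p}:{tr.te_name}"
        out.append(FlankRead(f"{stem}:5p", FIVE, five_seq, tail5))
        out.append(FlankRead(f"{stem}:3p", THREE, three_seq, tail3))
    return out


def simulate_te_placements(n_reads: int,
                           te_instances: Sequence,
                           multimap_profile: Mapping[int, float],
                           seed: int = 0,
                           span: int = 50) -> list[AlignmentRecord]:
    """Placement tables with a known multimapping profile.

    ``multimap_profile`` maps x (number of placements) to its probability.
    Each read draws x, then x placements uniformly among the TE instances
    (``span`` bases inside the chosen instance), so expected per-class
    fractional counts follow directly from the profile.
    """
    xs = sorted(multimap_profile)
    probs = np.array([multimap_profile[x] for x in xs], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    for i in range(n_reads):
        x = xs[rng.choice(len(xs), p=probs)]
        placements = []
        for _ in range(x):
            feat = te_instances[rng.integers(0, len(te_instances))]
            width = min(span, feat.end - feat.start)
            offset = int(rng.integers(0, feat.end - feat.start - width + 1))
            placements.append((feat.contig, feat.start + offset,
                               feat.start + offset + width, "+"))
        records.append(AlignmentRecord(f"read{i}", tuple(placements)))
    return records


def write_truth(truths: Sequence[TruthInsertion], bed_path: str | Path,
                tsv_path: str | Path) -> None:
    """Emit a truth set as BED (TSD interval) and a TSV side table."""
    with open(bed_path, "w") as fh:
        for tr in truths:
            fh.write(f"{tr.contig}\t{tr.p}\t{tr.p + tr.tsd_len}\t{tr.te_name}"
                     f"\t0\t{tr.orientation}\n")
    with open(tsv_path, "w") as fh:
        fh.write("contig\treport_pos\ttsd_len\ttsd_seq\tte_name\torientation\n")
        for tr in truths:
            fh.write(f"{tr.contig}\t{tr.report_pos}\t{tr.tsd_len}\t{tr.tsd_seq}"
                     f"\t{tr.te_name}\t{tr.orientation}\n")


# ---------------------------------------------------------------------------
# Standard study: the conditions every recovery test and the acceptance
# measurements run under.
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """A complete planted-insertion study with its ground truth."""

    genome_pre: list[GenomeSequence]
    genome_post: list[GenomeSequence]
    te_library: list[TEConsensus]
    truths: list[TruthInsertion] = field(default_factory=list)


def insertion_study(seed: int, genome_len: int = 100_000) -> SimulatedStudy:
    """The standard planted-insertion scenario.

    One 100 kb contig; a 1.5 kb P-element-style class II element ("SXP"),
    a class II natural TE ("1360") and a class I retrotransposon ("Copia");
    five insertions with TSD lengths {8, 8, 8, 5, 0} in mixed orientations,
    pairwise separated by far more than two read lengths.
    """
    rng = np.random.default_rng(seed)
    genome = make_genome(int(rng.integers(2**31)), {"chr2L": genome_len})
    te_library = [
        make_te_consensus(int(rng.integers(2**31)), "SXP", 1500, "II_DNA",
                          family="P-element"),
        make_te_consensus(int(rng.integers(2**31)), "1360", 1200, "II_DNA"),
        make_te_consensus(int(rng.integers(2**31)), "Copia", 1300,
                          "I_retrotransposon"),
    ]
    # disjoint windows keep pairwise distances > 2 read lengths by construction
    spec = [(8, "SXP", "+"), (8, "SXP", "-"), (8, "SXP", "+"),
            (5, "Copia", "-"), (0, "1360", "+")]
    truths = []
    window = (genome_len - 20_000) // len(spec)
    for i, (t, te, orient) in enumerate(spec):
        p = 10_000 + i * window + int(rng.integers(0, window - 2000))
        truths.append(TruthInsertion("chr2L", p, t, te, orient))
    genome_post, truths = plant_insertions(genome, truths, te_library)
    return SimulatedStudy(genome_pre=genome, genome_post=genome_post,
                          te_library=te_library, truths=truths)
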