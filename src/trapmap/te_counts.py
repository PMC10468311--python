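"""Fractional counting of (multi-mapped) reads over TE instances and genes.

Reads from repetitive TE copies often align equally well at several loci
(``x`` placements).  Two assignment rules are implemented:

* **per-instance upper bound** — every placement overlapping an annotated
  TE instance contributes its full value (1.0) to that instance, giving a
  theoretical upper bound for how much transcript a single copy could have
  produced (:func:`count_instances`);
* **fractional 1/x** — each placement contributes ``1/x`` to the class of
  the TE instance it overlaps, estimating the total read mass attributable
  to a TE class or to TEs overall (:func:`count_classes`).

Gene counts use only uniquely aligned reads (``x == 1``), discarding reads
that span two genes as ambiguous.  A placement overlaps a feature when at
least ``min_overlap`` bases intersect (default 1).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .seqio import FeatureRecord


@dataclass(frozen=True)
class AlignmentRecord:
    """All placements of one read; ``x`` is the number of placements."""

    read_id: str
    placements: tuple[tuple[str, int, int, str], ...]  # (contig, start, end, strand)

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError(f"read {self.read_id!r} has no placements")

    @property
    def x(self) -> int:
        return len(self.placements)


class _FeatureIndex:
    """Per-contig interval index over features, reporting overlap lengths."""

    def __init__(self, features: Iterable[FeatureRecord]):
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for feat in features:
            self.trees[feat.contig].addi(feat.start, feat.end, feat)

    def overlaps(self, contig: str, start: int, end: int,
                 min_overlap: int = 1) -> list[tuple[FeatureRecord, int]]:
        out = []
        for iv in self.trees.get(contig, IntervalTree()).overlap(start, end):
            ol = min(end, iv.end) - max(start, iv.begin)
            if ol >= min_overlap:
                out.append((iv.data, ol))
        return out


def _instance_id(feat: FeatureRecord) -> str:
    return feat.attributes.get("id", f"{feat.contig}:{feat.start}-{feat.end}")


def count_instances(alignments: Iterable[AlignmentRecord],
                    te_instances: Sequence[FeatureRecord],
                    min_overlap: int = 1) -> dict[str, float]:
    """Upper-bound per-instance counts: full value to every overlapped copy.

    A read with x placements over x instances contributes x in total — by
    design an upper bound, not a partition of the read.
    """
    index = _FeatureIndex(te_instances)
    counts: dict[str, float] = defaultdict(float)
    for rec in alignments:
        for contig, start, end, _ in rec.placements:
            for feat, _ol in index.overlaps(contig, start, end, min_overlap):
                counts[_instance_id(feat)] += 1.0
    return dict(counts)


def count_classes(alignments: Iterable[AlignmentRecord],
                  te_instances: Sequence[FeatureRecord],
                  class_map: Mapping[str, str] | None = None,
                  min_overlap: int = 1) -> dict[str, float]:
    """Fractional per-class counts: each placement contributes 1/x.

    ``class_map`` maps instance id (or family) to a class label; instances
    without a class fall under ``unclassified``.  A placement overlapping
    several instances credits only the largest overlap (tie toward the
    smaller coordinate), so one read never contributes more than 1 in
    total, with equality exactly when all its placements overlap instances.
    """
    index = _FeatureIndex(te_instances)
    class_map = class_map or {}
    counts: dict[str, float] = defaultdict(float)
    for rec in alignments:
        share = 1.0 / rec.x
        for contig, start, end, _ in rec.placements:
            hits = index.overlaps(contig, start, end, min_overlap)
            if not hits:
                continue
            feat = min(hits, key=lambda fo: (-fo[1], fo[0].start))[0]
            key = _instance_id(feat)
            cls = (class_map.get(key)
                   or class_map.get(feat.attributes.get("family", ""))
                   or feat.attributes.get("te_class")
                   or "unclassified")
            counts[cls] += share
    return dict(counts)


def count_genes(alignments: Iterable[AlignmentRecord],
                gene_features: Sequence[FeatureRecord],
                min_overlap: int = 1,
                counters: Counter | None = None) -> dict[str, int]:
    """Unique-read gene counts over merged exon intervals per gene.

    Only reads with a single placement count; a unique read overlapping
    exactly one gene adds 1, one overlapping two or more genes is discarded
    as ambiguous (tallied in ``counters['ambiguous_gene']``).
    """
    by_gene: dict[str, list[FeatureRecord]] = defaultdict(list)
    for feat in gene_features:
        gene = feat.attributes.get("parent") or feat.attributes.get("id") or feat.name
        by_gene[gene].append(feat)
    flat = []
    for gene, feats in by_gene.items():
        for feat in feats:
            flat.append(FeatureRecord(feat.contig, feat.start, feat.end,
                                      feat.strand, "exon", {"id": gene}))
    index = _FeatureIndex(flat)
    counts: dict[str, int] = defaultdict(int)
    for rec in alignments:
        if rec.x != 1:
            continue
        contig, start, end, _ = rec.placements[0]
        genes = {feat.attributes["id"]
                 for feat, _ol in index.overlaps(contig, start, end, min_overlap)}
        if len(genes) == 1:
            counts[genes.pop()] += 1
        elif len(genes) > 1 and counters is not None:
            counters["ambiguous_gene"] += 1
    return dict(counts)


def te_fraction(class_counts: Mapping[str, float],
                total_assigned_reads: int) -> float:
    """Fraction of a library's reads attributable to TEs (1/x mass / total)."""
    if total_assigned_reads <= 0:
        raise ValueError("total_assigned_reads must be positive")
    frac = sum(class_counts.values()) / total_assigned_reads
    return frac


def per_read_class_mass(rec: AlignmentRecord,
                        te_instances: Sequence[FeatureRecord],
                        min_overlap: int = 1) -> float:
    """Total 1/x mass one read contributes to TE classes (for diagnostics)."""
    return sum(count_classes([rec], te_instances, min_overlap=min_overlap).values())
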