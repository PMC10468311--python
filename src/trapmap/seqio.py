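"""Sequence and annotation I/O plus the shared genomic data model.

All coordinates are held internally as 0-based half-open intervals.
User-facing report writers convert to 1-based inclusive positions, matching
the FlyBase-style coordinates conventional in *Drosophila* genomics
(e.g. ``2L:12,004,481``).

DNA alphabet is restricted to ``{A, C, G, T, N}``.  ``N`` is legal in genome
sequences but is never used as a seed position by the aligner; it is rejected
in target-site-duplication octamers downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
TE_CLASSES = frozenset({"I_retrotransposon", "II_DNA"})
FEATURE_KINDS = frozenset(
    {
        "gene",
        "exon",
        "intron",
        "five_prime_UTR",
        "TE_instance",
        "prior_insertion",
        "other",
    }
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqFormatError(ValueError):
    """Raised for malformed or out-of-alphabet sequence/annotation input."""


def _check_alphabet(seq: str, context: str = "") -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise SeqFormatError(
            f"non-DNA character(s) {sorted(bad)}{where}; alphabet is A/C/G/T/N"
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N).

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One named contig/scaffold; optionally tagged with a chromosome arm."""

    name: str
    seq: str
    arm: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise SeqFormatError(f"empty sequence for record {self.name!r}")
        _check_alphabet(self.seq, context=f"record {self.name!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TEConsensus:
    """A transposable-element consensus sequence with class/family metadata.

    ``te_class`` follows the two-way stratification used for expression
    counting: class I retrotransposons vs class II DNA cut-and-paste elements.
    """

    name: str
    seq: str
    te_class: str = "II_DNA"
    family: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) < 50:
            raise SeqFormatError(
                f"TE consensus {self.name!r} is {len(self.seq)} bp; minimum is 50"
            )
        _check_alphabet(self.seq, context=f"TE consensus {self.name!r}")
        if self.te_class not in TE_CLASSES:
            raise SeqFormatError(
                f"te_class {self.te_class!r} not in {sorted(TE_CLASSES)}"
            )
        if not self.family:
            object.__setattr__(self, "family", self.name)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FeatureRecord:
    """A genomic interval feature (gene, exon, TE instance, prior insertion...).

    ``start``/``end`` are 0-based half-open on ``contig``; ``strand`` is one of
    ``+ - .``; ``kind`` is a controlled vocabulary (see ``FEATURE_KINDS``).
    """

    contig: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqFormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in {"+", "-", "."}:
            # permissive dialects ('?' etc.) collapse to unknown
            self.strand = "."
        if self.kind not in FEATURE_KINDS:
            self.kind = "other"

    @property
    def name(self) -> str:
        return self.attributes.get("id", f"{self.contig}:{self.start}-{self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _find_bad_char_line(path: Path, header: str) -> str:
    """Locate the first offending character of a record for the error message."""
    in_record = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == header if line[1:].split() else False
            continue
        if in_record:
            bad = set(line.strip().upper()) - DNA_ALPHABET
            if bad:
                return f"character {sorted(bad)[0]!r} at line {lineno}"
    return "unknown position"


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a DNA FASTA into :class:`GenomeSequence` records.

    Sequences are upper-cased.  Duplicate headers, empty sequences, and
    non-DNA characters (including U; this is a DNA-only reader) are errors.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise SeqFormatError(f"empty sequence for header {rec.id!r} in {path}")
        if set(seq) - DNA_ALPHABET:
            raise SeqFormatError(
                f"record {rec.id!r} in {path}: {_find_bad_char_line(path, rec.id)}"
            )
        records.append(GenomeSequence(name=rec.id, seq=seq))
    return records


def read_te_fasta(path: str | Path) -> list[TEConsensus]:
    """Read a TE consensus library FASTA.

    Class/family metadata is taken from ``key=value`` tokens in the header
    description, e.g. ``>1360 te_class=II_DNA family=1360``.  Records without
    a ``te_class`` default to class II (DNA transposon).
    """
    out: list[TEConsensus] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"duplicate TE header {rec.id!r}")
        seen.add(rec.id)
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                meta[key] = value
        out.append(
            TEConsensus(
                name=rec.id,
                seq=str(rec.seq).upper(),
                te_class=meta.get("te_class", "II_DNA"),
                family=meta.get("family", ""),
            )
        )
    return out


def write_fasta(records: Iterable[GenomeSequence | TEConsensus], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into ``(read_id, sequence)`` pairs (qualities dropped)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_GFF_KIND_MAP = {
    "gene": "gene",
    "mRNA": "gene",
    "exon": "exon",
    "intron": "intron",
    "five_prime_UTR": "five_prime_UTR",
    "5'UTR": "five_prime_UTR",
    "transposable_element": "TE_instance",
}


def read_gff(path: str | Path) -> list[FeatureRecord]:
    """Read GFF3 features, converting 1-based inclusive to 0-based half-open.

    GFF feature types outside the internal vocabulary are stored as
    ``other`` with the original type kept under ``attributes['source_type']``.
    """
    import gffutils

    path = Path(path)
    # pre-scan for coordinate sanity so errors carry line numbers
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 5:
            start, end = int(cols[3]), int(cols[4])
            if end < start:
                raise SeqFormatError(f"{path}:{lineno}: end {end} < start {start}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[FeatureRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        attrs = {k: v[0] if isinstance(v, list) and v else v for k, v in feat.attributes.items()}
        attrs = {k.lower(): str(v) for k, v in attrs.items()}
        kind = _GFF_KIND_MAP.get(feat.featuretype, "other")
        if kind == "other":
            attrs["source_type"] = feat.featuretype
        out.append(
            FeatureRecord(
                contig=feat.seqid,
                start=feat.start - 1,  # GFF is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
                kind=kind,
                attributes=attrs,
            )
        )
    return out


def write_gff(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write features as GFF3 (internal 0-based half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            gff_type = {v: k for k, v in _GFF_KIND_MAP.items()}.get(f.kind, f.kind)
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.contig}\ttrapmap\t{gff_type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand if f.strand != '.' else '.'}\t.\t{attrs}\n"
            )


def read_bed(path: str | Path, kind: str = "other") -> list[FeatureRecord]:
    """Read a BED6 (or BED3+) file; BED is already 0-based half-open.

    Column 4 (name) is stored under ``attributes['id']`` and, for TE instance
    tracks, doubles as the family label; column 5 under ``score``.
    """
    out: list[FeatureRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise SeqFormatError(f"{path}:{lineno}: BED line with <3 columns")
        start, end = int(cols[1]), int(cols[2])
        if end < start:
            raise SeqFormatError(f"{path}:{lineno}: end {end} < start {start}")
        attrs: dict = {}
        if len(cols) > 3:
            attrs["id"] = cols[3]
            attrs.setdefault("family", cols[3])
        if len(cols) > 4:
            attrs["score"] = cols[4]
        strand = cols[5] if len(cols) > 5 else "."
        out.append(
            FeatureRecord(
                contig=cols[0], start=start, end=end,
                strand=strand, kind=kind, attributes=attrs,
            )
        )
    return out


def write_bed(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.contig}\t{f.start}\t{f.end}\t{f.attributes.get('id', '.')}\t"
                f"{f.attributes.get('score', '0')}\t{f.strand}\n"
            )


def genome_dict(genome: Iterable[GenomeSequence] | Mapping[str, str]) -> dict[str, str]:
    """Normalize a genome argument (records or name->seq mapping) to a dict."""
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.name: g.seq for g in genome}
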