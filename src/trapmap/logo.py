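"""Position frequency matrices and information-content sequence logos.

Built from target-site-duplication octamers (or any fixed-length ACGT
motif set).  Per column *i* over ``n`` sequences:

* counts ``c(b, i)`` and frequencies ``f(b, i) = c(b, i) / n``,
* Shannon entropy ``H_i = -sum_b f log2 f`` (bits, with 0*log0 = 0),
* small-sample correction ``e_n = 3 / (2 * ln2 * n)`` bits (the standard
  correction for a 4-letter alphabet),
* information content ``R_i = max(0, 2 - H_i - e_n)``,
* letter heights ``h(b, i) = f(b, i) * R_i``.

``R_i`` is clipped at zero so letter heights stay non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP_INDEX = [_BASE_INDEX[c] for c in "TGCA"]  # complement of A,C,G,T


@dataclass(frozen=True)
class PFM:
    """A 4xL base-count matrix with derived logo quantities."""

    counts: np.ndarray  # (4, L) ints, rows in A,C,G,T order
    n: int

    @property
    def L(self) -> int:
        return self.counts.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def entropy(self) -> np.ndarray:
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f), 0.0)
        return -terms.sum(axis=0)

    @property
    def small_sample_correction(self) -> float:
        return 3.0 / (2.0 * math.log(2) * self.n)

    @property
    def information(self) -> np.ndarray:
        return np.maximum(0.0, 2.0 - self.entropy - self.small_sample_correction)

    @property
    def letter_heights(self) -> np.ndarray:
        return self.freqs * self.information

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    @property
    def consensus_ties(self) -> list[int]:
        """Columns whose consensus base was a tie (resolved to the
        lexicographically smallest base by argmax order)."""
        top = self.counts.max(axis=0)
        return [i for i in range(self.L) if (self.counts[:, i] == top[i]).sum() > 1]


def collect_tsds(calls: Iterable, counters: dict | None = None) -> list[str]:
    """Extract strand-normalized TSD octamers from both-ends trap calls.

    Single-ended calls and octamers containing N are skipped (counted in
    ``counters`` when provided).
    """
    out: list[str] = []
    for call in calls:
        seq = getattr(call, "tsd_seq", "")
        if not seq:
            if counters is not None:
                counters["single_ended"] = counters.get("single_ended", 0) + 1
            continue
        if "N" in seq:
            if counters is not None:
                counters["contains_N"] = counters.get("contains_N", 0) + 1
            continue
        out.append(seq)
    return out


def build_pfm(seqs: Sequence[str]) -> PFM:
    """Count a set of same-length ACGT sequences into a :class:`PFM`."""
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if L < 1:
        raise ValueError("zero-length sequences")
    counts = np.zeros((4, L), dtype=int)
    for seq in seqs:
        if len(seq) != L:
            raise ValueError(
                f"sequence {seq!r} has length {len(seq)}, expected {L}")
        for i, base in enumerate(seq):
            if base not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {base!r} in {seq!r}")
            counts[_BASE_INDEX[base], i] += 1
    return PFM(counts=counts, n=len(seqs))


def pfm_from_counts(counts: np.ndarray) -> PFM:
    counts = np.asarray(counts, dtype=int)
    n = int(counts[:, 0].sum())
    if not (counts.sum(axis=0) == n).all():
        raise ValueError("count columns do not sum to a common n")
    return PFM(counts=counts, n=n)


def palindrome_score(pfm: PFM) -> float:
    """Reverse-complement palindromicity of a PFM, in (0, 1].

    ``score = (1/L) * sum_i sum_b f(b, i) * f(comp(b), L+1-i)`` — the mean
    probability that a random draw from column *i* is the complement of a
    random draw from the mirrored column.  1.0 for a deterministic
    reverse-complement palindrome; 0.25 for uniform columns.
    """
    if pfm.L % 2:
        raise ValueError("palindrome score requires even motif length")
    f = pfm.freqs
    mirrored = f[:, ::-1][_COMP_INDEX, :]
    return float((f * mirrored).sum() / pfm.L)


def write_pfm_tsv(pfm: PFM, path: str | Path) -> None:
    """Write counts, frequencies and per-column information as TSV."""
    with open(path, "w") as fh:
        cols = "\t".join(f"pos{i + 1}" for i in range(pfm.L))
        fh.write(f"# trapmap PFM, n={pfm.n}\nrow\t{cols}\n")
        for bi, base in enumerate(BASES):
            fh.write(f"count_{base}\t" + "\t".join(str(c) for c in pfm.counts[bi]) + "\n")
        for bi, base in enumerate(BASES):
            fh.write(f"freq_{base}\t" + "\t".join(f"{v:.6f}" for v in pfm.freqs[bi]) + "\n")
        fh.write("information\t" + "\t".join(f"{v:.6f}" for v in pfm.information) + "\n")


def read_pfm_tsv(path: str | Path) -> PFM:
    """Rebuild a PFM from the count rows of :func:`write_pfm_tsv` output."""
    counts = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("count_"):
            row, *values = line.split("\t")
            counts[row.removeprefix("count_")] = [int(v) for v in values]
    return pfm_from_counts(np.array([counts[b] for b in BASES]))


_LETTER_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def export_logo(pfm: PFM, path: str | Path, tsv_path: str | Path | None = None,
                title: str | None = None) -> None:
    """Render a stacked-letter information-content logo and its TSV matrix.

    Letters in each column are stacked in increasing height order; the
    column stack totals ``R_i`` bits.  ``tsv_path`` defaults to ``path``
    with a ``.tsv`` suffix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    path = Path(path)
    heights = pfm.letter_heights
    fig, ax = plt.subplots(figsize=(max(2.0, 0.6 * pfm.L), 2.6))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for col in range(pfm.L):
        y = 0.0
        order = np.argsort(heights[:, col])
        for bi in order:
            h = heights[bi, col]
            if h <= 0:
                continue
            base = BASES[bi]
            tp = TextPath((0, 0), base, size=1.0, prop=font)
            bbox = tp.get_extents()
            scale = Affine2D().translate(-bbox.x0, -bbox.y0).scale(
                0.9 / bbox.width, h / bbox.height).translate(col + 0.05, y)
            ax.add_patch(PathPatch(tp.transformed(scale),
                                   color=_LETTER_COLORS[base], lw=0))
            y += h
    ax.set_xlim(0, pfm.L)
    ax.set_ylim(0, 2.0)
    ax.set_xticks([i + 0.5 for i in range(pfm.L)])
    ax.set_xticklabels([str(i + 1) for i in range(pfm.L)])
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    for side in ("top", "right"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    write_pfm_tsv(pfm, tsv_path or path.with_suffix(".tsv"))
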