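# Methods

## Insertion geometry and coordinate conventions

All internal coordinates are 0-based half-open; reported positions are
1-based (FlyBase style).  An insertion of element `T` at target position
`p` with TSD length `t` turns the reference `G` into
`G[0, p+t) + T_oriented + G[p, …)`, where `T_oriented = T` for a `+`
insertion and the reverse complement for `−`.  The target site `G[p, p+t)`
therefore appears on both sides of the element.

Each insertion leaves two genome/TE junctions.  Projected into reference
coordinates, the junction whose genome flank *precedes* the element (the
"left-flank" junction) sits at `p + t`, and the junction whose genome
flank *follows* it at `p`; the left-flank coordinate is the larger of the
two precisely because the target site is duplicated.  An `InsertionCall`
stores these as `left_junction` and `right_junction`;
`tsd_len = left_junction − right_junction` and
`tsd_seq = G[right_junction, left_junction)`.  Computing the TSD from
junction overlap rather than sequence self-comparison keeps the call
correct even when the octamer happens to occur elsewhere.

Which element terminus abuts which junction depends on orientation: for
`+` the left-flank junction abuts the element 5′ end; for `−` it abuts the
3′ end.  The full case table (genome flank side × relative TE strand →
te_side, orientation) is documented in `split_align.py` and drives both
the internal aligner and SAM ingestion, so the two evidence pathways agree
by construction.

Orientation naming follows the enhancer-trap convention: `+` when the
element's 5′→3′ axis is codirectional with the reference strand.  TSD
octamers from the iPCR route are reported element-codirectionally — the
reference-strand octamer for `+` insertions, its reverse complement for
`−` — matching how insertion-site motif collections are assembled for
logo construction.

## Split-read detection

The internal aligner uses exact k-mer seeding (default `k = 15`) on the
genome and the TE library, one ungapped maximal extension per
(target, diagonal), and a substitution-only mismatch budget
(`max_mismatch_rate = 0.05`, terminal mismatches trimmed).  Gapped
alignment is deliberately out of scope: junction detection needs locally
exact anchors, and an indel-free model keeps every expectation computable
by string arithmetic.

A split read requires a genome segment and a TE segment that are adjacent
on the read (gap ≤ `junction_gap = 3`), each at least
`min_segment = 20` bases, together covering ≥ 90 % of the read, with the
TE segment touching an element terminus within `end_slack = 5` bases.
Because the TE segment is bounded by the terminus, its read-side boundary
anchors the junction exactly even when the genome segment chance-extends a
base or two past the junction (each ~¼ probability per base); the genome
coordinate of the junction is obtained by projecting that boundary through
the genome segment's diagonal.  Defaults were chosen so an 8 bp TSD is
always resolvable with two 20 nt anchors on 100 nt reads.  Reads with
equally scoring alternative placements are dropped as ambiguous rather
than placed arbitrarily — ambiguity in repetitive DNA is reported, not
guessed.

The SAM pathway accepts two alignment files (reads vs genome, reads vs TE
library).  A genome alignment soft-clipped by ≥ `min_segment` bases
defines the candidate junction (clips at the CIGAR end are always on the
reference-right side); the same read's TE alignment must cover the clipped
portion at a terminus, and the relative strand of the two alignments feeds
the shared case table.

## Junction clustering and pairing

Split reads are stratified by (contig, TE, te_side, orientation) and
clustered single-linkage with gap ≤ `cluster_tol = 3`; the cluster
breakpoint is the modal member position (ties toward the smaller
coordinate), which absorbs the chance-extension minority.  Within each
(contig, TE, orientation) stratum, left-flank clusters pair greedily with
the nearest right-flank cluster satisfying
`0 ≤ left − right ≤ tsd_max = 30` (greedy by combined support, ties toward
the smaller coordinate, each cluster used once).  The cap prevents chance
pairing of unrelated junctions; genuine TSDs here are ≤ 8 bp.  Unpaired
clusters with `support ≥ min_support` are emitted as one-sided calls.
Calls are labelled `reference` when an annotated TE copy of the same
family lies within `window = 100` bases, else `non_reference`.

## iPCR route

A flank read carries a known element tail (≥ 12 bp) at a mandated side;
trimming strips one exact occurrence (searching both orientations) and
normalizes the genomic remainder to read away from the element.
Remainders (≥ `min_flank = 20` bases) are placed by unique best seed
match; multiple equal placements raise an ambiguity error carrying the
placement count — the natural-TE case in which an insertion can be
assigned to a family but not to a single genomic copy.  A both-ends call
requires the two junctions to bracket exactly `tsd_len = 8` bases
(`tsd_slack = 0` by default; configurable because gene-specific-PCR
fallback evidence can be single-ended or imprecise).

Annotation precedence at the reported position is
natural_TE > five_prime_UTR > exon > intron > promoter > intergenic, with
promoter defined as `promoter_window = 1000` bases upstream of an
annotated gene start, strand-aware.  Catalogue tallies count calls per
chromosome arm and orientation and merge loci within
`merge_radius = 1000` bases (single linkage), mirroring the ±1 kb
proximity convention used for comparing insertion collections.

## Sequence-logo mathematics

For `n` aligned L-mers: `f(b,i) = c(b,i)/n`,
`H_i = −Σ_b f log2 f` (0·log 0 = 0),
`e_n = 3/(2·ln 2·n)` (the standard small-sample correction for a
four-letter alphabet), `R_i = max(0, 2 − H_i − e_n)` bits, letter height
`h(b,i) = f(b,i)·R_i`.  `R` is clipped at zero so heights are
non-negative; consensus ties are flagged rather than encoded as IUPAC
codes.  The palindromicity diagnostic is
`(1/L)·Σ_i Σ_b f(b,i)·f(comp b, L+1−i)`: 1 for a deterministic
reverse-complement palindrome, 0.25 for uniform columns.

## Fractional TE counting

`x` is the number of placements supplied for a read — taken from the
placement table itself, not from aligner-specific tags.  Per-instance
counts assign the full value to every overlapped instance (a deliberate
upper bound on single-copy expression); per-class counts assign `1/x` per
placement.  A placement overlapping two instances credits only the larger
overlap (tie toward the smaller coordinate), so one read's class
contributions never exceed 1, with equality exactly when every placement
overlaps an instance.  Overlap means ≥ 1 intersecting base by default
(configurable).  Gene counts conservatively use unique reads only and
discard reads spanning two genes; whether to admit multi-mapped reads to
gene counting is exposed as a choice rather than assumed.

## Synthetic data: what it emulates and what it does not

The generators emulate the features the calling logic consumes: planted
insertions with exact TSD geometry in both orientations, uniform-coverage
paired-end reads with substitution errors, iPCR amplicons with element
tails on the correct side (including contig-edge truncation), and
multi-mapped placement tables with a prescribed `x` distribution.  The
standard study (`insertion_study`) is one 100 kb contig, three TE
consensi (a 1.5 kb P-element-style element, a class II `1360`-like and a
class I `Copia`-like element), and five insertions with TSD lengths
{8, 8, 8, 5, 0} in mixed orientations, read at 20× with error-free
2×100 nt pairs — sizes at which the whole pipeline runs in seconds while
every junction has double-digit read support.

Not emulated: indels and quality-score structure, PCR duplicates,
restriction-fragment length realism beyond flank truncation, coverage
bias, heterozygous/pooled insertions, and near-identical TE subfamilies.
Passing recovery tests therefore demonstrates correctness of the junction
arithmetic, strand conventions and counting rules — not robustness to
alignment noise or repeat-family cross-talk in real libraries, where the
ambiguity counters are expected to absorb a nontrivial read fraction.

## Numerical and degenerate-input choices

Ties anywhere (cluster mode, pairing, consensus, best placement) break
toward the smaller coordinate or are reported as ambiguous — never
resolved randomly.  Empty inputs yield empty outputs except where a
precondition is structural (an empty TE library is an error; a zero-count
library is an error for `te_fraction`).  Zero-length TSDs are legal
(`tsd_seq = ""`).  All simulators thread a single integer seed;
outputs are bit-reproducible, and the CLI writes a config-hashed manifest
beside every result.

## Known limitations

* The aligner is ungapped; an indel near a junction shifts or destroys
  the anchor instead of being absorbed.
* One-sided calls carry no TSD and their reported position is the single
  junction, which for a left-flank-only call lies `t` bases downstream of
  the insertion's first TSD base.
* Nested insertions (a trap inside a natural TE absent from the
  reference) are handled by re-running the mapper with the TE library as
  the alignment target and anchoring the result with `terminus_offset`;
  this composite mode is manual, not automated.
* Reference/non-reference classification trusts the completeness of the
  supplied TE instance annotation.
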