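"""Core genomic data types and coordinate conventions.

All internal coordinates are 0-based, half-open (BED convention). The only
place 1-based closed coordinates appear is at the GTF I/O boundary
(:mod:`capture_atlas.io`). Strand is one of ``+``, ``-`` or ``.``
(unstranded); operations that require orientation reject ``.`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Tuple

Exon = Tuple[int, int]

STRANDS = ("+", "-", ".")

#: Canonical splice-site dinucleotide pairs (donor-acceptor, sense strand).
CANONICAL_MOTIFS = frozenset({"GT-AG", "GC-AG", "AT-AC"})

#: Values the ``motif`` field of a junction may take.
MOTIF_VALUES = frozenset({"GT-AG", "GC-AG", "AT-AC", "other", "unknown"})


class StructuralError(ValueError):
    """Raised when a genomic record violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise StructuralError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise StructuralError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise StructuralError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: donor = intron start, acceptor = intron end (half-open)."""

    chrom: str
    donor: int
    acceptor: int
    strand: str = "."
    motif: str = "unknown"
    short_read_count: int = 0
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise StructuralError(
                f"donor must precede acceptor, got {self.donor} >= {self.acceptor}"
            )
        if self.motif not in MOTIF_VALUES:
            raise StructuralError(f"invalid motif {self.motif!r}")
        if self.short_read_count < 0:
            raise StructuralError("short_read_count must be non-negative")
        if self.strand not in STRANDS:
            raise StructuralError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> Tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.donor, self.acceptor)


@dataclass(frozen=True)
class ExonChain:
    """An ordered, strand-aware chain of exons (a spliced read or a
    transcript skeleton).

    Exons are sorted by start and consecutive exons must be separated by a
    gap of >= 1 bp (an intron).
    """

    id: str
    chrom: str
    strand: str
    exons: Tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.chrom:
            raise StructuralError("chrom must be non-empty")
        if self.strand not in STRANDS:
            raise StructuralError(f"invalid strand {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise StructuralError("chain must have >= 1 exon")
        for s, e in exons:
            if not (0 <= s < e):
                raise StructuralError(f"invalid exon [{s}, {e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise StructuralError(
                    f"exons must be separated by >= 1 bp: [{s0},{e0}) then [{s1},{e1})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Total exonic length in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Exon, ...]:
        """Gaps between consecutive exons, as (donor, acceptor) pairs."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_key(self) -> Tuple[str, str, Tuple[Exon, ...]]:
        """Hashable identity of the intron chain (chrom, strand, introns)."""
        return (self.chrom, self.strand, self.introns)

    def with_id(self, new_id: str) -> "ExonChain":
        return replace(self, id=new_id)

    def boundaries(self) -> Tuple[int, ...]:
        """Flat tuple of all exon boundaries, alternating start/end."""
        out: list[int] = []
        for s, e in self.exons:
            out.extend((s, e))
        return tuple(out)


def introns_of(chain: ExonChain) -> list[SpliceJunction]:
    """Return the introns of a chain as :class:`SpliceJunction` records.

    Single-exon chains yield an empty list.
    """
    return [
        SpliceJunction(chain.chrom, donor, acceptor, chain.strand)
        for donor, acceptor in chain.introns
    ]


#: gffcompare-style class codes recognised by the classifier.
CLASS_CODES = frozenset({"=", "c", "j", "e", "o", "i", "p", "r", "s", "x", "u"})

NOVELTY_CLASSES = (
    "known",
    "novel-isoform",
    "novel-antisense",
    "novel-intergenic",
)


@dataclass
class TranscriptModel:
    """A transcript: an exon chain plus gene assignment and annotations.

    ``coding_probability`` is a pluggable per-transcript score in [0, 1]
    (e.g. from CPAT); ``None`` when not computed.
    """

    id: str
    gene_id: str
    chain: ExonChain
    class_code: Optional[str] = None
    coding_probability: Optional[float] = None

    def __post_init__(self) -> None:
        if self.class_code is not None and self.class_code not in CLASS_CODES:
            raise StructuralError(f"invalid class code {self.class_code!r}")
        if self.coding_probability is not None and not (
            0.0 <= self.coding_probability <= 1.0
        ):
            raise StructuralError("coding_probability must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.chain.length

    @property
    def chrom(self) -> str:
        return self.chain.chrom

    @property
    def strand(self) -> str:
        return self.chain.strand

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: start for '+', end - 1 for '-'."""
        if self.chain.strand == "+":
            return self.chain.start
        if self.chain.strand == "-":
            return self.chain.end - 1
        raise StructuralError(f"transcript {self.id} is unstranded")


def group_by_locus(
    spans: Sequence[GenomicInterval],
) -> list[list[int]]:
    """Group interval indices into loci of transitively-overlapping spans.

    Book-ended spans (touching, not overlapping) are *not* grouped.
    """
    order = sorted(range(len(spans)), key=lambda i: (spans[i].chrom, spans[i].start))
    loci: list[list[int]] = []
    cur: list[int] = []
    cur_chrom, cur_end = None, -1
    for i in order:
        iv = spans[i]
        if cur and iv.chrom == cur_chrom and iv.start < cur_end:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                loci.append(cur)
            cur = [i]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cur:
        loci.append(cur)
    return loci


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_of(genome, chrom: str, donor: int, acceptor: int, strand: str) -> str:
    """Read an intron's donor-acceptor dinucleotide pair on the transcript
    strand from a genome accessor; non-canonical pairs collapse to "other"."""
    left = genome.fetch(chrom, donor, donor + 2)
    right = genome.fetch(chrom, acceptor - 2, acceptor)
    if strand == "-":
        left, right = revcomp(right), revcomp(left)
    pair = f"{left}-{right}"
    return pair if pair in CANONICAL_MOTIFS else "other"


def lower_median(values: Iterable[int]) -> int:
    """Median taking the lower middle value for even counts.

    Keeps consensus coordinates on observed (integer) positions.
    """
    vs = sorted(values)
    if not vs:
        raise ValueError("median of empty sequence")
    return vs[(len(vs) - 1) // 2]
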