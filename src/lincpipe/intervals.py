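"""Core genomic primitives: stranded intervals, exon-structured transcripts, loci.

All coordinates are internally 0-based, half-open (``[start, end)``); GTF
readers/writers convert from/to the 1-based inclusive dialect at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")

BIOTYPES = ("coding", "noncoding", "unknown")


class StructuralValidationError(ValueError):
    """Raised for malformed exon structure or invalid coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval on a chromosome.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, strand one of
    ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise StructuralValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise StructuralValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Coordinate overlap by >= 1 bp, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Base pairs between the two intervals; 0 if they overlap or touch.

        Undefined across chromosomes (raises ValueError).
        """
        if self.chrom != other.chrom:
            raise ValueError("gap_to across different chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def strands_compatible(a: str, b: str) -> bool:
    """Same-strand test with ``.`` acting as a wildcard."""
    return a == "." or b == "." or a == b


def strands_opposite(a: str, b: str) -> bool:
    """Strictly opposite strands; ``.`` is never opposite to anything."""
    return {a, b} == {"+", "-"}


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript model.

    Exons are sorted by start, pairwise disjoint and all on the transcript's
    chromosome and strand. The spliced length is the sum of exon lengths;
    introns are the gaps between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise StructuralValidationError(f"invalid strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise StructuralValidationError(f"invalid biotype {self.biotype!r}")
        if not self.exons:
            raise StructuralValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise StructuralValidationError(
                    f"exon chromosome {ex.chrom} != transcript {self.chrom}"
                )
            if ex.start < prev_end:
                raise StructuralValidationError(
                    f"exons of {self.transcript_id} unsorted or overlapping"
                )
            prev_end = ex.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced transcript length in nt."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns)

    def shifted(self, offset: int) -> "TranscriptModel":
        return TranscriptModel(
            self.transcript_id,
            self.gene_id,
            self.chrom,
            self.strand,
            [e.shifted(offset) for e in self.exons],
            self.biotype,
        )


@dataclass
class Locus:
    """A cluster of transcripts sharing exonic overlap on one strand."""

    locus_id: str
    member_transcript_ids: frozenset[str]
    span: GenomicInterval

    def __post_init__(self) -> None:
        if not self.member_transcript_ids:
            raise StructuralValidationError(f"locus {self.locus_id} has no members")
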