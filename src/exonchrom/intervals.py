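"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)`` on a
named chromosome, with strand ``+`` or ``-``.  GTF input (1-based inclusive)
is converted on load; BED output is written as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def five_prime(self) -> int:
        """Genomic position of the first transcribed nucleotide."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap; abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Genomic distance from this interval to a point (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap between two intervals on the same chromosome (0 if overlapping)."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end + 1
        return self.start - other.end + 1


@dataclass(frozen=True)
class ExonRecord:
    """A candidate internal exon with its flanking-intron junctions.

    Junctions are ``(donor, acceptor)`` genomic coordinates of the intron,
    stored as the intron's half-open genomic span ``(intron_start, intron_end)``
    regardless of strand; ``upstream``/``downstream`` are in transcription
    direction.
    """

    interval: GenomicInterval
    gene_id: str
    transcript_ids: frozenset = field(default_factory=frozenset)
    upstream_junction: tuple = None
    downstream_junction: tuple = None

    @property
    def exon_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def skip_junction(self) -> tuple:
        """Genomic span of the intron joining the two flanking exons."""
        if self.upstream_junction is None or self.downstream_junction is None:
            return None
        spans = (*self.upstream_junction, *self.downstream_junction)
        return (min(spans), max(spans))
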