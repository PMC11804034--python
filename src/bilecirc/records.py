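"""Core record types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; BED on disk keeps
that convention, and only VCF/descriptor output switches to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class Segment:
    """One genomic interval of a circle (or of an alignment)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"degenerate segment {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


def reciprocal_overlap(a: Segment, b: Segment) -> float:
    """Overlap length divided by the longer of the two intervals.

    0 for different chromosomes; 1 only for identical intervals.
    """
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / max(a.length, b.length)


@dataclass
class EccDNARecord:
    """One called (or simulated truth) eccDNA molecule.

    ``segments`` is the ordered chain of genomic intervals traversed once
    around the circle, stored in canonical rotation: the cycle is rotated so
    that it starts at the segment with the lexicographically smallest
    (chrom, start, end, strand).
    """

    id: str
    segments: list[Segment]
    n_passes: int = 2
    n_supporting_reads: int = 1
    consensus: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a circle needs at least one segment")
        self.segments = canonical_rotation(self.segments)

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def chroms(self) -> set[str]:
        return {s.chrom for s in self.segments}

    @property
    def junctions(self) -> list[tuple[Segment, Segment]]:
        """Breakpoint pairs (outgoing segment, incoming segment), cyclic."""
        n = len(self.segments)
        return [(self.segments[i], self.segments[(i + 1) % n]) for i in range(n)]

    def same_structure(self, other: "EccDNARecord", min_reciprocal: float = 0.9,
                       tol: int | None = None) -> bool:
        """True when both circles have the same segment count and every
        canonical segment pair overlaps reciprocally by ``min_reciprocal``.

        With ``tol`` set, segment pairs whose endpoints all agree within
        ``tol`` bp also match - this absorbs aligner endpoint jitter on
        circles shorter than ~2 x tol / (1 - min_reciprocal).
        """
        if len(self.segments) != len(other.segments):
            return False

        def pair_ok(a: Segment, b: Segment) -> bool:
            if reciprocal_overlap(a, b) >= min_reciprocal:
                return True
            return (tol is not None and a.chrom == b.chrom
                    and a.strand == b.strand
                    and abs(a.start - b.start) <= tol
                    and abs(a.end - b.end) <= tol)

        return all(pair_ok(a, b) for a, b in zip(self.segments, other.segments))


def canonical_rotation(segments: list[Segment]) -> list[Segment]:
    """Rotate a cyclic segment chain to start at the smallest sort key."""
    pivot = min(range(len(segments)), key=lambda i: segments[i].sort_key())
    return segments[pivot:] + segments[:pivot]


@dataclass
class SampleProfile:
    """One bile sample: its called eccDNA set plus clinical metadata."""

    sample_id: str
    group: str  # cancer | noncancer | unknown
    mapped_read_count: int = 0
    downsampled_read_count: int = 0
    eccdna: list[EccDNARecord] = field(default_factory=list)
    serum_cea: float | None = None  # ng/mL
    serum_ca199: float | None = None  # U/mL

    def __post_init__(self) -> None:
        if self.group not in ("cancer", "noncancer", "unknown"):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.downsampled_read_count > self.mapped_read_count:
            raise ValueError("downsampled count exceeds mapped count")

    def with_eccdna(self, records: list[EccDNARecord]) -> "SampleProfile":
        return replace(self, eccdna=records)
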