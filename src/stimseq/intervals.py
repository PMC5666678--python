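"""Interval algebra on 0-based half-open genomic coordinates.

All in-memory coordinates follow the BED convention: ``start`` is 0-based
inclusive, ``end`` exclusive, ``start < end``. GTF's 1-based inclusive
coordinates are converted at the I/O boundary (:mod:`stimseq.io`).

These primitives carry the windows the analysis is built from: the ±2 kb
gene-exclusion zone, the ±500 bp TSS/peak window, the 500-nt divergent
pairing window, the −30/+300 bp promoter-proximal window, and the 300-kb
enhancer–gene linkage radius.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")


class IntervalError(ValueError):
    """Raised for ill-formed intervals or invalid interval arguments."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open.

    ``strand`` is ``'+'``, ``'-'``, or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise IntervalError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def expand(self, slack: int) -> "GenomicInterval":
        """Symmetric, strand-ignorant expansion by ``slack`` bp, clipped at 0."""
        if slack < 0:
            raise IntervalError("slack must be >= 0")
        return GenomicInterval(self.chrom, max(0, self.start - slack), self.end + slack, self.strand)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlaps(a: GenomicInterval, b: GenomicInterval, slack: int = 0) -> bool:
    """True iff ``[a.start - slack, a.end + slack)`` intersects ``b``.

    Strand is ignored. Half-open adjacency ([0,10) vs [10,20), slack 0) does
    not overlap. Intervals on different chromosomes never overlap.
    """
    if slack < 0:
        raise IntervalError("slack must be >= 0")
    if a.chrom != b.chrom:
        return False
    return a.start - slack < b.end and b.start < a.end + slack


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on the same chromosome; 0 if they touch."""
    if a.chrom != b.chrom:
        raise IntervalError("intervals on different chromosomes have no defined gap")
    return max(0, a.start - b.end, b.start - a.end)


def point_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance in bp from a point to the nearest base covered by ``iv`` (0 if inside)."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def directional_window(
    chrom: str, anchor: int, strand: str, upstream: int, downstream: int
) -> tuple[GenomicInterval, bool]:
    """Window around an anchor base, oriented by transcription direction.

    Covers ``upstream`` bp 5' of the anchor through ``downstream`` bp 3' of
    it, both inclusive of the anchor, so the full length is
    ``upstream + downstream + 1``. On the minus strand the window is
    mirrored. Returns ``(interval, clipped)`` where ``clipped`` is True when
    the window ran off the chromosome start and was truncated at 0.
    """
    if upstream < 0 or downstream < 0:
        raise IntervalError("upstream/downstream must be >= 0")
    if strand not in STRANDS:
        raise IntervalError(f"unknown strand symbol {strand!r}")
    if strand == ".":
        if upstream != downstream:
            raise IntervalError("unstranded anchor cannot take an asymmetric window")
        strand_eff = "+"
    else:
        strand_eff = strand
    if strand_eff == "+":
        start, end = anchor - upstream, anchor + downstream + 1
    else:
        start, end = anchor - downstream, anchor + upstream + 1
    clipped = start < 0
    return GenomicInterval(chrom, max(0, start), end, strand), clipped
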