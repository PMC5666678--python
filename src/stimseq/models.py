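"""Transcript and peak models shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval, IntervalError


@dataclass
class TranscriptModel:
    """A stranded transcript: a span plus its ordered exon structure.

    Invariants enforced on construction: the transcript is stranded; exons
    are disjoint, sorted, on the same chromosome/strand, contained in the
    span; and the exon union touches both span boundaries. ``tss()`` is the
    biological 5' end — the last base of the span for a minus-strand model.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise IntervalError(f"transcript {self.id} must be stranded (+ or -)")
        if not self.exons:
            # single implicit exon spanning the whole model
            self.exons = [self.interval]
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise IntervalError(f"exon of {self.id} on wrong chrom/strand")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise IntervalError(f"exon of {self.id} outside transcript span")
            if prev_end is not None and ex.start < prev_end:
                raise IntervalError(f"exons of {self.id} unsorted or overlapping")
            prev_end = ex.end
        if self.exons[0].start != self.interval.start or self.exons[-1].end != self.interval.end:
            raise IntervalError(f"exon union of {self.id} does not touch span boundaries")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def tss(self) -> int:
        """Position of the transcription start site (5' end)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def tes(self) -> int:
        """Position of the transcription end site (3' end)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def is_spliced(self) -> bool:
        return len(self.exons) > 1

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class Peak:
    """An unstranded signal peak (e.g. H3K27ac or enrichment-caller output)."""

    interval: GenomicInterval
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak {self.name} has negative score {self.score}")
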