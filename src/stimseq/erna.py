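"""Enhancer-RNA locus identification from assembled transcripts.

The cascade mirrors the standard bidirectional-eRNA definition: starting
from a transcriptome assembly it (1) keeps only unspliced transcripts,
(2) removes anything overlapping or within ±2 kb of annotated genes,
(3) pairs the survivors head-to-head (divergent, TSSs within 500 nt), and
(4) requires an H3K27ac peak within ±500 bp of a member TSS. Induced loci
can then be linked to the nearest stimulus-responsive gene within 300 kb.

Each stage is non-increasing in set size and exposed separately so the
elimination stage of any candidate can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .intervals import GenomicInterval, overlaps, point_distance
from .models import Peak, TranscriptModel

STAGES = ("input", "unspliced", "intergenic", "paired", "peak_supported")


@dataclass
class ErnaLocus:
    """A retained divergent transcript pair with its supporting peak."""

    plus_id: str
    minus_id: str
    interval: GenomicInterval  # union span of the pair, unstranded
    inter_tss_distance: int
    peak_name: str | None = None
    peak_score: float = 0.0
    linked_gene: str | None = None
    linked_distance: int | None = None

    @property
    def name(self) -> str:
        return f"{self.plus_id}|{self.minus_id}"


@dataclass
class ErnaParams:
    gene_margin: int = 2000      # bp exclusion zone around genes
    pair_window: int = 500       # nt max TSS-to-TSS distance
    peak_window: int = 500       # bp TSS window that must touch a peak
    peak_rule: str = "or"        # 'or': either member TSS; 'and': both
    link_distance: int = 300_000


@dataclass
class ErnaAnnotation:
    """Result of the full cascade, with per-stage survivor bookkeeping."""

    loci: list[ErnaLocus]
    stage_survivors: dict[str, set[str]] = field(default_factory=dict)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {stage: len(ids) for stage, ids in self.stage_survivors.items()}


def filter_unspliced(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Keep exactly the single-exon (unspliced) transcripts."""
    return [t for t in transcripts if not t.is_spliced()]


def exclude_near_genes(
    transcripts: Sequence[TranscriptModel],
    gene_spans: Sequence[GenomicInterval],
    margin: int = 2000,
) -> list[TranscriptModel]:
    """Drop transcripts overlapping any gene span expanded by ±margin (strand-ignorant)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in gene_spans:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept = []
    for t in transcripts:
        near = any(overlaps(t.interval, g, slack=margin) for g in by_chrom.get(t.chrom, []))
        if not near:
            kept.append(t)
    return kept


def _divergent(plus: TranscriptModel, minus: TranscriptModel) -> bool:
    # bodies extend away from the shared TSS midpoint: minus body leftward
    # of its TSS, plus body rightward of its TSS, with the plus TSS not 5'
    # of the minus TSS
    return plus.tss() >= minus.tss()


def pair_head_to_head(
    transcripts: Sequence[TranscriptModel], window: int = 500
) -> list[tuple[TranscriptModel, TranscriptModel]]:
    """Greedy closest-TSS pairing of divergent (+,-) transcripts within ``window`` nt.

    A transcript joins at most one pair; candidate pairs are consumed in
    order of increasing TSS distance (ties broken by ids) so the pairing is
    deterministic.
    """
    plus = [t for t in transcripts if t.strand == "+"]
    minus = [t for t in transcripts if t.strand == "-"]
    candidates = []
    for p in plus:
        for m in minus:
            if p.chrom != m.chrom:
                continue
            d = abs(p.tss() - m.tss())
            if d <= window and _divergent(p, m):
                candidates.append((d, p.id, m.id, p, m))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[str] = set()
    pairs = []
    for d, pid, mid, p, m in candidates:
        if pid in used or mid in used:
            continue
        used.update((pid, mid))
        pairs.append((p, m))
    return pairs


def _tss_window(t: TranscriptModel, window: int) -> GenomicInterval:
    tss = t.tss()
    return GenomicInterval(t.chrom, max(0, tss - window), tss + window + 1)


def require_h3k27ac(
    pairs: Sequence[tuple[TranscriptModel, TranscriptModel]],
    peaks: Sequence[Peak],
    tss_window: int = 500,
    rule: str = "or",
) -> list[ErnaLocus]:
    """Keep pairs whose member TSS (±tss_window) intersects an H3K27ac peak.

    ``rule='or'`` accepts support at either member TSS (the default,
    permissive reading); ``'and'`` requires both. The supporting peak is
    the highest-scoring intersecting peak (ties broken by name).
    """
    if rule not in ("or", "and"):
        raise ValueError("peak rule must be 'or' or 'and'")
    by_chrom: dict[str, list[Peak]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.interval.chrom, []).append(pk)
    loci = []
    for p, m in pairs:
        hits_per_member = []
        for member in (p, m):
            win = _tss_window(member, tss_window)
            hits_per_member.append(
                [pk for pk in by_chrom.get(member.chrom, []) if overlaps(win, pk.interval)]
            )
        supported = (
            all(hits_per_member) if rule == "and" else any(hits_per_member)
        )
        if not supported:
            continue
        best = max(
            (pk for hits in hits_per_member for pk in hits),
            key=lambda pk: (pk.score, pk.name),
        )
        span = GenomicInterval(
            p.chrom,
            min(p.interval.start, m.interval.start),
            max(p.interval.end, m.interval.end),
        )
        loci.append(
            ErnaLocus(
                plus_id=p.id,
                minus_id=m.id,
                interval=span,
                inter_tss_distance=abs(p.tss() - m.tss()),
                peak_name=best.name,
                peak_score=best.score,
            )
        )
    return loci


def link_to_responsive_genes(
    loci: Sequence[ErnaLocus],
    responsive_genes: Sequence[TranscriptModel],
    max_distance: int = 300_000,
) -> list[ErnaLocus]:
    """Retain loci whose midpoint lies within ``max_distance`` of a responsive gene.

    Each retained locus is annotated with the nearest responsive gene id
    and its distance in bp (0 when the midpoint falls inside the gene).
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in responsive_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    linked = []
    for locus in loci:
        mid = locus.interval.midpoint
        best: tuple[int, str] | None = None
        for g in by_chrom.get(locus.interval.chrom, []):
            d = point_distance(mid, g.interval)
            key = (d, g.gene_id or g.id)
            if best is None or key < best:
                best = key
        if best is not None and best[0] <= max_distance:
            linked.append(replace(locus, linked_gene=best[1], linked_distance=best[0]))
    return linked


def annotate_ernas(
    assembly: Sequence[TranscriptModel],
    gene_spans: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    params: ErnaParams | None = None,
    exclusion_mask: Sequence[GenomicInterval] | None = None,
) -> ErnaAnnotation:
    """Run the full cascade: unspliced → intergenic → head-to-head → peak-supported.

    ``exclusion_mask`` optionally drops transcripts overlapping masked
    regions (e.g. rRNA/tRNA/7SK loci) before the cascade. Returns the
    retained loci plus the surviving transcript ids after every stage.
    """
    params = params or ErnaParams()
    work = list(assembly)
    if exclusion_mask:
        work = [
            t for t in work
            if not any(overlaps(t.interval, m) for m in exclusion_mask if m.chrom == t.chrom)
        ]
    survivors = {"input": {t.id for t in work}}
    work = filter_unspliced(work)
    survivors["unspliced"] = {t.id for t in work}
    work = exclude_near_genes(work, gene_spans, margin=params.gene_margin)
    survivors["intergenic"] = {t.id for t in work}
    pairs = pair_head_to_head(work, window=params.pair_window)
    survivors["paired"] = {t.id for pair in pairs for t in pair}
    loci = require_h3k27ac(pairs, peaks, tss_window=params.peak_window, rule=params.peak_rule)
    survivors["peak_supported"] = {
        tid for locus in loci for tid in (locus.plus_id, locus.minus_id)
    }
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start, l.name))
    return ErnaAnnotation(loci=loci, stage_survivors=survivors)


def loci_to_peaks(loci: Sequence[ErnaLocus]) -> list[Peak]:
    """BED6 representation: name = pair ids, score = inter-TSS distance."""
    return [
        Peak(locus.interval, score=float(locus.inter_tss_distance), name=locus.name)
        for locus in loci
    ]


def loci_to_transcripts(loci: Sequence[ErnaLocus]) -> list[TranscriptModel]:
    """Unstranded-agnostic transcript models for merging loci into a GTF."""
    out = []
    for locus in loci:
        iv = GenomicInterval(
            locus.interval.chrom, locus.interval.start, locus.interval.end, "+"
        )
        out.append(TranscriptModel(locus.name, iv, [iv], gene_id=locus.name))
    return out
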