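"""Enhancer peak detection, superenhancer stitching/ranking, and SE scoring.

Peak detection is a transparent fold-enrichment caller over a treatment
vs. control coverage pair. Superenhancers are called ROSE-style: peaks
within a stitching distance are merged, stitched regions are ranked by
total signal, both axes of the rank-signal curve are scaled to [0, 1], and
the superenhancer boundary sits where the curve's slope first exceeds 1.
The SE score normalizes each region's total signal by the highest total
signal in the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack
from .intervals import GenomicInterval, overlaps
from .models import Peak


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    member_names: list[str] = field(default_factory=list)
    total_signal: float = 0.0
    rank: int | None = None            # ascending by total signal
    is_superenhancer: bool = False
    se_score: float | None = None      # total signal / max total signal

    @property
    def name(self) -> str:
        return ",".join(self.member_names) or "."


def detect_enrichment_peaks(
    treatment: CoverageTrack,
    control: CoverageTrack,
    window: int = 100,
    min_fold: float = 4.0,
    merge_gap: int = 500,
    eps: float = 0.5,
) -> list[Peak]:
    """Fold-enrichment peak caller over a treatment/control track pair.

    Regions where ``(treatment + eps) / (control + eps) >= min_fold`` are
    collected and merged when separated by <= ``merge_gap`` bp. With
    ``window <= 1`` the ratio is evaluated on the exact per-base step
    decomposition of the two tracks; with larger windows it is evaluated on
    non-overlapping tiles of that width. Peak score = summed treatment
    signal over the merged region. Output is independent of chromosome
    processing order (chromosomes are handled sorted).
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    peaks: list[Peak] = []
    for chrom in sorted(set(treatment.chroms()) | set(control.chroms())):
        extent = max(treatment.extent(chrom), control.extent(chrom))
        if extent == 0:
            continue
        enriched: list[tuple[int, int]] = []
        if window <= 1:
            bounds = sorted(
                {0, extent}
                | {b for s, e, _ in treatment.steps(chrom) for b in (s, e)}
                | {b for s, e, _ in control.steps(chrom) for b in (s, e)}
            )
            segments = zip(bounds[:-1], bounds[1:])
        else:
            edges = list(range(0, extent, window)) + [extent]
            segments = zip(edges[:-1], edges[1:])
        for s, e in segments:
            region = GenomicInterval(chrom, s, e)
            ratio = (treatment.mean(region) + eps) / (control.mean(region) + eps)
            if ratio >= min_fold:
                enriched.append((s, e))
        for s, e in enriched:
            if peaks and peaks[-1].interval.chrom == chrom and s - peaks[-1].interval.end <= merge_gap:
                merged = GenomicInterval(chrom, peaks[-1].interval.start, e)
                peaks[-1] = Peak(merged, name=peaks[-1].name)
            else:
                peaks.append(Peak(GenomicInterval(chrom, s, e), name=f"peak_{len(peaks) + 1:05d}"))
    return [
        Peak(p.interval, score=treatment.sum(p.interval), name=p.name) for p in peaks
    ]


def stitch(peaks: Sequence[Peak], stitch_distance: int = 12_500) -> list[StitchedEnhancer]:
    """Merge peaks separated by <= stitch_distance into candidate enhancer regions."""
    regions: list[StitchedEnhancer] = []
    for peak in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.name)):
        if (
            regions
            and regions[-1].interval.chrom == peak.interval.chrom
            and peak.interval.start - regions[-1].interval.end <= stitch_distance
        ):
            last = regions[-1]
            last.interval = GenomicInterval(
                last.interval.chrom,
                last.interval.start,
                max(last.interval.end, peak.interval.end),
            )
            last.member_names.append(peak.name)
            last.total_signal += peak.score
        else:
            regions.append(
                StitchedEnhancer(
                    interval=peak.interval,
                    member_names=[peak.name],
                    total_signal=peak.score,
                )
            )
    return regions


def flag_superenhancers(regions: list[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Rank regions ascending by total signal and flag the superenhancers.

    With both axes of the rank-signal curve scaled to [0, 1], regions past
    the first point where the curve's slope exceeds 1 are superenhancers.
    A flat curve has no superenhancers; with fewer than 3 regions the
    boundary is undefined and everything is flagged non-SE with a warning.
    """
    regions = sorted(regions, key=lambda r: (r.total_signal, r.name))
    for i, r in enumerate(regions):
        r.rank = i + 1
        r.is_superenhancer = False
    n = len(regions)
    if n < 3:
        if n:
            warnings.warn("fewer than 3 stitched regions: superenhancer boundary undefined")
        return regions
    signals = np.array([r.total_signal for r in regions], dtype=float)
    lo, hi = signals[0], signals[-1]
    if hi == lo:
        return regions  # flat curve: slope never exceeds 1
    xs = np.arange(n) / (n - 1)
    ys = (signals - lo) / (hi - lo)
    slopes = np.diff(ys) / np.diff(xs)
    above = np.nonzero(slopes > 1)[0]
    if len(above):
        for r in regions[above[0] + 1:]:
            r.is_superenhancer = True
    return regions


def stitch_and_rank(peaks: Sequence[Peak], stitch_distance: int = 12_500) -> list[StitchedEnhancer]:
    """Stitch peaks and flag superenhancers in one step."""
    return flag_superenhancers(stitch(peaks, stitch_distance))


def se_score(
    regions: Sequence[StitchedEnhancer],
) -> tuple[list[StitchedEnhancer], dict[str, int]]:
    """Normalize each region's total signal by the set maximum.

    Returns the scored regions plus metadata recording the peak universe
    size (total member peaks) the normalization was computed over. Scores
    are invariant under uniform rescaling of all signals.
    """
    if not regions:
        raise ValueError("no regions to score")
    top = max(r.total_signal for r in regions)
    if top <= 0:
        raise ValueError("cannot score regions: all total signals are zero")
    scored = list(regions)
    for r in scored:
        r.se_score = r.total_signal / top
    meta = {"n_peaks": sum(len(r.member_names) for r in scored)}
    return scored, meta


def assemble_top_enhancers(
    superenhancers: Sequence[StitchedEnhancer],
    traditional: Sequence[Peak],
    gene_spans: Sequence[GenomicInterval],
    k: int = 500,
) -> list[StitchedEnhancer]:
    """Top-k stimulus-induced enhancer set: SEs first, then best traditional peaks.

    Superenhancers overlapping gene spans are removed (the bona fide SE
    set); the remaining slots are filled with the highest-scoring
    traditional peaks that do not overlap genes. The combined set is
    rescored (signal / max signal) and ranked descending.
    """
    def clear_of_genes(iv: GenomicInterval) -> bool:
        return not any(overlaps(iv, g) for g in gene_spans if g.chrom == iv.chrom)

    ses = [r for r in superenhancers if clear_of_genes(r.interval)]
    if k < len(ses):
        raise ValueError(f"k={k} smaller than the {len(ses)} gene-free superenhancers")
    se_names = {name for r in ses for name in r.member_names}
    pool = [
        p for p in traditional
        if clear_of_genes(p.interval) and p.name not in se_names
    ]
    pool.sort(key=lambda p: (-p.score, p.name))
    n_fill = k - len(ses)
    if len(pool) < n_fill:
        raise ValueError(
            f"insufficient enhancer candidates: {len(ses)} superenhancers + "
            f"{len(pool)} traditional peaks < k={k}"
        )
    combined = list(ses) + [
        StitchedEnhancer(
            interval=p.interval,
            member_names=[p.name],
            total_signal=p.score,
        )
        for p in pool[:n_fill]
    ]
    top = max(r.total_signal for r in combined)
    if top <= 0:
        raise ValueError("cannot score enhancer set: all signals are zero")
    combined.sort(key=lambda r: (-r.total_signal, r.name))
    for i, r in enumerate(combined):
        r.se_score = r.total_signal / top
        r.rank = i + 1
    return combined
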