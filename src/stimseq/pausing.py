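"""RNAPII traveling-ratio (pausing) metrics, KS comparison, metaprofiles.

The traveling ratio of an isoform is the read density over its
promoter-proximal window (TSS −30 to +300 bp, inclusive, in transcription
direction) divided by the density over the rest of the gene body plus 1 kb
beyond the TES. High values indicate promoter-proximal pausing; the
statistic is reported as log10 and is invariant under uniform scaling of
the track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import distributions

from .coverage import CoverageTrack
from .intervals import GenomicInterval, directional_window
from .models import TranscriptModel


@dataclass
class TravelingRatioRecord:
    transcript_id: str
    tss_density: float
    body_density: float
    ratio: float | None        # None when the record is excluded
    log10_ratio: float | None
    excluded: bool = False
    reason: str = ""


@dataclass
class MetaProfile:
    offsets: np.ndarray        # bin start offsets relative to the anchor, bp
    means: np.ndarray          # mean density per bin across anchors
    n_anchors: int


def traveling_ratio(
    track: CoverageTrack,
    transcript: TranscriptModel,
    tss_up: int = 30,
    tss_down: int = 300,
    tes_extension: int = 1000,
) -> TravelingRatioRecord:
    """Traveling ratio of one isoform; degenerate cases are flagged, not raised.

    The body window starts immediately 3' of the promoter-proximal window
    and runs through TES + ``tes_extension``. Records with an empty body
    window (transcript shorter than the TSS window) or zero density in
    either window are flagged excluded.
    """
    tss, tes = transcript.tss(), transcript.tes()
    if transcript.length <= tss_down:
        return TravelingRatioRecord(transcript.id, 0.0, 0.0, None, None, True, "body window empty")
    tss_win, _ = directional_window(transcript.chrom, tss, transcript.strand, tss_up, tss_down)
    if transcript.strand == "+":
        body = GenomicInterval(transcript.chrom, tss + tss_down + 1, tes + tes_extension + 1)
    else:
        body = GenomicInterval(transcript.chrom, max(0, tes - tes_extension), tss - tss_down)
    tss_density = track.mean(tss_win)
    body_density = track.mean(body)
    if tss_density <= 0 or body_density <= 0:
        return TravelingRatioRecord(
            transcript.id, tss_density, body_density, None, None, True, "zero density"
        )
    ratio = tss_density / body_density
    return TravelingRatioRecord(
        transcript.id, tss_density, body_density, ratio, math.log10(ratio)
    )


def traveling_ratio_distribution(
    track: CoverageTrack,
    transcripts: Sequence[TranscriptModel],
    expression: pd.DataFrame,
    fpkm_col: str,
    min_fpkm: float = 1.0,
    **tr_kwargs,
) -> tuple[list[TravelingRatioRecord], list[TravelingRatioRecord]]:
    """Traveling ratios over every expressed isoform (parent FPKM > min_fpkm).

    Returns ``(records, excluded)``; record order is by transcript id, so
    the output is invariant to input order.
    """
    expressed = set(
        expression.loc[expression[fpkm_col] > min_fpkm, "feature_id"]
    )
    records, excluded = [], []
    for t in sorted(transcripts, key=lambda t: t.id):
        if (t.gene_id or t.id) not in expressed:
            continue
        rec = traveling_ratio(track, t, **tr_kwargs)
        (excluded if rec.excluded else records).append(rec)
    return records, excluded


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of the absolute difference between the two empirical
    CDFs; the p-value uses the asymptotic Kolmogorov distribution with the
    standard small-sample correction on the effective sample size.
    """
    xa, ya = np.sort(np.asarray(x, dtype=float)), np.sort(np.asarray(y, dtype=float))
    if xa.size == 0 or ya.size == 0:
        raise ValueError("KS test requires non-empty samples")
    grid = np.concatenate([xa, ya])
    cdf_x = np.searchsorted(xa, grid, side="right") / xa.size
    cdf_y = np.searchsorted(ya, grid, side="right") / ya.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = math.sqrt(xa.size * ya.size / (xa.size + ya.size))
    p = float(distributions.kstwobign.sf(d * (en + 0.12 + 0.11 / en)))
    return d, min(1.0, max(0.0, p))


def metaprofile(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    flank: int = 2000,
    bin_width: int = 50,
) -> MetaProfile:
    """Average coverage profile around anchors, oriented 5'→3'.

    Each anchor is ``(chrom, position, strand)``; densities over
    [−flank, +flank) relative to the anchor are binned at ``bin_width`` in
    transcription direction (minus-strand anchors mirrored) and averaged
    across anchors. ``flank`` must be a multiple of ``bin_width``.
    """
    if not anchors:
        raise ValueError("metaprofile requires at least one anchor")
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin width")
    n_bins = 2 * flank // bin_width
    offsets = np.arange(-flank, flank, bin_width)
    acc = np.zeros(n_bins, dtype=float)
    for chrom, pos, strand in anchors:
        if strand not in ("+", "-"):
            raise ValueError(f"anchor strand must be + or -, got {strand!r}")
        for i, off in enumerate(offsets):
            if strand == "+":
                s = pos + off
            else:
                # mirrored: bin at offset `off` covers the same distance 5'->3'
                s = pos - off - bin_width + 1
            e = s + bin_width
            if e <= 0:
                continue
            region = GenomicInterval(chrom, max(0, s), e)
            acc[i] += track.sum(region) / bin_width
    return MetaProfile(offsets=offsets, means=acc / len(anchors), n_anchors=len(anchors))


def records_to_frame(records: Sequence[TravelingRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "tss_density": r.tss_density,
                "body_density": r.body_density,
                "ratio": r.ratio,
                "log10_ratio": r.log10_ratio,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in records
        ]
    )
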