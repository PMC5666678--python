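"""Readers and writers for GTF, BED, bedGraph, and expression tables.

Conventions at the boundary:

* GTF is 1-based inclusive on disk, converted to internal 0-based half-open
  on read and back on write.
* BED and bedGraph are already 0-based half-open and pass through.
* Expression tables are TSV with header
  ``feature_id  fpkm_<cond>...  fold_change  q_value``.

Malformed lines raise :class:`ParseError` naming the file and line number.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .coverage import CoverageTrack
from .intervals import GenomicInterval, IntervalError
from .models import Peak, TranscriptModel


class ParseError(ValueError):
    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (``transcript`` + ``exon`` features) from a GTF.

    ``gene`` feature lines are ignored; a transcript without an explicit
    ``transcript`` line gets the union span of its exons.
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    gene_ids: dict[str, str | None] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(path, lineno, f"expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature not in ("transcript", "exon"):
            continue
        try:
            start, end = int(start_s) - 1, int(end_s)  # 1-based inclusive -> half-open
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"unknown strand symbol {strand!r}")
        attr = dict(_ATTR_RE.findall(attrs))
        tid = attr.get("transcript_id")
        if tid is None:
            raise ParseError(path, lineno, "missing transcript_id attribute")
        try:
            iv = GenomicInterval(chrom, start, end, strand)
        except IntervalError as exc:
            raise ParseError(path, lineno, str(exc))
        if tid not in gene_ids:
            order.append(tid)
            gene_ids[tid] = attr.get("gene_id")
        if feature == "transcript":
            spans[tid] = iv
        else:
            exons.setdefault(tid, []).append(iv)
    out = []
    for tid in order:
        ex = sorted(exons.get(tid, []), key=lambda e: e.start)
        span = spans.get(tid)
        if span is None:
            if not ex:
                continue
            span = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        out.append(TranscriptModel(tid, span, ex or [span], gene_id=gene_ids[tid]))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "stimseq", feature_class: dict[str, str] | None = None) -> None:
    """Write transcript+exon GTF lines (1-based inclusive coordinates).

    ``feature_class`` optionally maps transcript id -> a ``feature_class``
    attribute value (used to distinguish eRNA loci from genes in the merged
    annotation).
    """
    lines = []
    for t in transcripts:
        cls = (feature_class or {}).get(t.id)
        attrs = f'gene_id "{t.gene_id or t.id}"; transcript_id "{t.id}";'
        if cls:
            attrs += f' feature_class "{cls}";'
        iv = t.interval
        lines.append(
            f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
        )
        for ex in t.exons:
            lines.append(
                f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED6 into peaks (score 0 and name '.' where absent)."""
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "expected at least 3 BED fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer BED coordinates")
        name = fields[3] if len(fields) > 3 else "."
        try:
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric BED score {fields[4]!r}")
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in ("+", "-", "."):
            raise ParseError(path, lineno, f"unknown strand symbol {strand!r}")
        try:
            iv = GenomicInterval(fields[0], start, end, strand)
        except IntervalError as exc:
            raise ParseError(path, lineno, str(exc))
        peaks.append(Peak(iv, score=score, name=name))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    lines = [
        f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}\t{p.score:g}\t{p.interval.strand}"
        for p in peaks
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(path: str | Path) -> CoverageTrack:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(path, lineno, "expected 4 bedGraph fields")
        try:
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise ParseError(path, lineno, "malformed bedGraph values")
    return CoverageTrack.from_steps(records)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    lines = []
    for chrom in track.chroms():
        for start, end, value in track.steps(chrom):
            lines.append(f"{chrom}\t{start}\t{end}\t{value:.6g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


REQUIRED_EXPRESSION_COLUMNS = ("feature_id", "fold_change", "q_value")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a per-feature expression table (TSV).

    Requires ``feature_id``, ``fold_change``, ``q_value`` and at least one
    ``fpkm_<condition>`` column.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"expression table missing columns {missing}")
    if not any(c.startswith("fpkm_") for c in df.columns):
        raise ParseError(path, 1, "expression table has no fpkm_<condition> column")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def gene_spans(transcripts: Sequence[TranscriptModel]) -> list[GenomicInterval]:
    """Union span per gene_id (falls back to transcript id)."""
    by_gene: dict[str, GenomicInterval] = {}
    for t in transcripts:
        gid = t.gene_id or t.id
        iv = t.interval
        if gid in by_gene:
            old = by_gene[gid]
            by_gene[gid] = GenomicInterval(
                old.chrom, min(old.start, iv.start), max(old.end, iv.end), old.strand
            )
        else:
            by_gene[gid] = iv
    return [by_gene[g] for g in sorted(by_gene)]
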