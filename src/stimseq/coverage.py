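"""Run-length encoded per-base coverage tracks.

A :class:`CoverageTrack` stores, per chromosome, sorted non-overlapping
steps ``(start, end, value)`` with value = read density in reads/bp.
Queries outside any step return 0. Tracks are strand-agnostic.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .intervals import GenomicInterval


class CoverageTrack:
    def __init__(self) -> None:
        # chrom -> (starts, ends, values) as float/int arrays; sorted, disjoint
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_steps(cls, records: Iterable[tuple[str, int, int, float]]) -> "CoverageTrack":
        """Build a track from (chrom, start, end, value) blocks.

        Overlapping blocks are summed, which lets callers compose a
        background level with localised signal blocks.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start:
                raise ValueError(f"empty coverage step [{start}, {end}) on {chrom}")
            if value < 0:
                raise ValueError("coverage density must be >= 0")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, blocks in by_chrom.items():
            bounds = np.unique(
                np.concatenate([[s for s, _, _ in blocks], [e for _, e, _ in blocks]])
            )
            starts, ends = bounds[:-1], bounds[1:]
            values = np.zeros(len(starts), dtype=float)
            for s, e, v in blocks:
                i, j = np.searchsorted(starts, s), np.searchsorted(ends, e, side="left") + 1
                values[i:j] += v
            keep = values > 0
            track._steps[chrom] = (starts[keep], ends[keep], values[keep])
        return track

    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def steps(self, chrom: str) -> Iterator[tuple[int, int, float]]:
        """Yield nonzero (start, end, value) steps for one chromosome, sorted."""
        if chrom not in self._steps:
            return
        starts, ends, values = self._steps[chrom]
        for s, e, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
            yield int(s), int(e), float(v)

    def extent(self, chrom: str) -> int:
        """End of the last covered step (0 for an uncovered chromosome)."""
        if chrom not in self._steps or len(self._steps[chrom][1]) == 0:
            return 0
        return int(self._steps[chrom][1][-1])

    def sum(self, region: GenomicInterval) -> float:
        """Total signal (density × bp) over ``region``; 0 if uncovered."""
        if region.chrom not in self._steps:
            return 0.0
        starts, ends, values = self._steps[region.chrom]
        lo = np.minimum(ends, region.end)
        hi = np.maximum(starts, region.start)
        span = np.clip(lo - hi, 0, None)
        return float(np.dot(span, values))

    def mean(self, region: GenomicInterval) -> float:
        """Mean per-base density over ``region`` (0 for fully uncovered)."""
        return self.sum(region) / region.length

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._steps:
            return 0.0
        starts, ends, values = self._steps[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if set(self._steps) != set(other._steps):
            return False
        return all(
            list(self.steps(c)) == list(other.steps(c)) for c in self._steps
        )
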