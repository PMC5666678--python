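"""Peak calling, superenhancer stitching/ranking, and SE-score properties."""

import numpy as np
import pytest

from stimseq import enhancers
from stimseq.coverage import CoverageTrack
from stimseq.intervals import GenomicInterval
from stimseq.models import Peak


def flag_oracle(signals):
    """Scaled-tangent oracle, written from the definition with plain loops."""
    order = sorted(range(len(signals)), key=lambda i: (signals[i], i))
    s = [signals[i] for i in order]
    n = len(s)
    flags = [False] * n
    if n >= 3 and s[-1] > s[0]:
        cut = None
        for i in range(n - 1):
            dy = (s[i + 1] - s[0]) / (s[-1] - s[0]) - (s[i] - s[0]) / (s[-1] - s[0])
            dx = 1.0 / (n - 1)
            if dy / dx > 1:
                cut = i
                break
        if cut is not None:
            for j in range(cut + 1, n):
                flags[j] = True
    out = [False] * len(signals)
    for pos, orig in enumerate(order):
        out[orig] = flags[pos]
    return out


class TestPeakDetection:
    def track(self, blocks):
        return CoverageTrack.from_steps([("chr1", s, e, v) for s, e, v in blocks])

    def test_equal_tracks_yield_no_peaks(self):
        t = self.track([(0, 10_000, 2.0)])
        assert enhancers.detect_enrichment_peaks(t, t, window=1) == []

    def test_single_enriched_block_yields_one_spanning_peak(self):
        ctrl = self.track([(0, 10_000, 1.0)])
        treat = self.track([(0, 10_000, 1.0), (4_000, 5_000, 9.0)])
        (peak,) = enhancers.detect_enrichment_peaks(treat, ctrl, window=1, min_fold=4.0)
        assert (peak.interval.start, peak.interval.end) == (4_000, 5_000)
        assert peak.score == pytest.approx(10.0 * 1_000)

    def test_matches_per_base_threshold_merge_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(100):
            size = 400
            treat_steps, ctrl_steps = [], []
            for _ in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, size - 20))
                treat_steps.append((s, s + int(rng.integers(5, 60)), float(rng.uniform(0, 8))))
            for _ in range(int(rng.integers(1, 4))):
                s = int(rng.integers(0, size - 20))
                ctrl_steps.append((s, s + int(rng.integers(5, 60)), float(rng.uniform(0, 3))))
            treat, ctrl = self.track(treat_steps), self.track(ctrl_steps)
            merge_gap = int(rng.integers(0, 30))
            got = [
                (p.interval.start, p.interval.end)
                for p in enhancers.detect_enrichment_peaks(
                    treat, ctrl, window=1, min_fold=3.0, merge_gap=merge_gap
                )
            ]
            # per-base oracle
            extent = max(treat.extent("chr1"), ctrl.extent("chr1"))
            hot = [
                b for b in range(extent)
                if (treat.value_at("chr1", b) + 0.5) / (ctrl.value_at("chr1", b) + 0.5) >= 3.0
            ]
            merged = []
            for b in hot:
                if merged and b - merged[-1][1] <= merge_gap:
                    merged[-1][1] = b + 1
                else:
                    merged.append([b, b + 1])
            assert got == [tuple(m) for m in merged]

    def test_output_insensitive_to_chromosome_order(self):
        steps = [("chr2", 0, 1_000, 1.0), ("chr2", 100, 200, 9.0),
                 ("chr1", 0, 1_000, 1.0), ("chr1", 500, 600, 9.0)]
        ctrl = CoverageTrack.from_steps([("chr1", 0, 1_000, 1.0), ("chr2", 0, 1_000, 1.0)])
        a = enhancers.detect_enrichment_peaks(CoverageTrack.from_steps(steps), ctrl, window=1)
        b = enhancers.detect_enrichment_peaks(CoverageTrack.from_steps(steps[::-1]), ctrl, window=1)
        assert [(p.interval.chrom, p.interval.start) for p in a] == \
               [(p.interval.chrom, p.interval.start) for p in b]

    def test_min_fold_must_exceed_one(self):
        t = self.track([(0, 100, 1.0)])
        with pytest.raises(ValueError):
            enhancers.detect_enrichment_peaks(t, t, min_fold=1.0)


def make_peaks(signals, spacing=50_000, width=1_000):
    return [
        Peak(GenomicInterval("chr1", i * spacing, i * spacing + width),
             score=float(s), name=f"p{i}")
        for i, s in enumerate(signals)
    ]


class TestStitching:
    def test_nearby_peaks_merge(self):
        peaks = [
            Peak(GenomicInterval("chr1", 0, 1_000), 5.0, "a"),
            Peak(GenomicInterval("chr1", 5_000, 6_000), 7.0, "b"),
            Peak(GenomicInterval("chr1", 100_000, 101_000), 1.0, "c"),
        ]
        regions = enhancers.stitch(peaks)
        assert [r.member_names for r in regions] == [["a", "b"], ["c"]]
        assert regions[0].total_signal == pytest.approx(12.0)
        assert regions[0].total_signal >= max(5.0, 7.0)

    def test_stitching_is_idempotent_on_random_peak_sets(self):
        rng = np.random.default_rng(71)
        for _ in range(200):
            n = int(rng.integers(1, 15))
            peaks = []
            for i, s in enumerate(sorted(rng.integers(0, 300_000, size=n))):
                peaks.append(Peak(GenomicInterval("chr1", int(s), int(s) + int(rng.integers(200, 2_000))),
                                  score=float(rng.uniform(0, 50)), name=f"p{i}"))
            once = enhancers.stitch(peaks)
            again = enhancers.stitch(
                [Peak(r.interval, r.total_signal, r.name) for r in once]
            )
            assert [(r.interval, r.total_signal) for r in again] == \
                   [(r.interval, r.total_signal) for r in once]


class TestSuperenhancerFlags:
    def test_single_outlier_is_the_only_superenhancer(self):
        regions = enhancers.stitch_and_rank(make_peaks([1, 1, 1, 1, 100]))
        flags = {r.name: r.is_superenhancer for r in regions}
        assert flags == {"p0": False, "p1": False, "p2": False, "p3": False, "p4": True}

    def test_flat_curve_has_no_superenhancers(self):
        regions = enhancers.stitch_and_rank(make_peaks([5, 5, 5, 5]))
        assert not any(r.is_superenhancer for r in regions)

    def test_fewer_than_three_regions_warns_and_flags_none(self):
        with pytest.warns(UserWarning):
            regions = enhancers.stitch_and_rank(make_peaks([1, 100]))
        assert not any(r.is_superenhancer for r in regions)

    def test_matches_scaled_tangent_oracle_on_random_signal_sets(self):
        rng = np.random.default_rng(81)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            signals = [float(x) for x in rng.uniform(0, 100, size=n)]
            regions = enhancers.stitch_and_rank(make_peaks(signals))
            got = {r.name: r.is_superenhancer for r in regions}
            expected = dict(zip([f"p{i}" for i in range(n)], flag_oracle(signals)))
            assert got == expected

    def test_flags_invariant_under_uniform_rescaling(self):
        rng = np.random.default_rng(91)
        signals = [float(x) for x in rng.uniform(0, 100, size=12)]
        base = {r.name: r.is_superenhancer
                for r in enhancers.stitch_and_rank(make_peaks(signals))}
        scaled = {r.name: r.is_superenhancer
                  for r in enhancers.stitch_and_rank(make_peaks([s * 37.5 for s in signals]))}
        assert base == scaled

    def test_dominant_outlier_stays_flagged_when_background_grows(self):
        # the boundary is scale-dependent at the low end, but a dominant
        # outlier remains a superenhancer when weak background regions are
        # appended below the minimum
        rng = np.random.default_rng(101)
        for _ in range(50):
            signals = [float(x) for x in rng.uniform(1, 10, size=8)] + [500.0]
            grown = signals + [min(signals) / 2]
            flags = {r.name: r.is_superenhancer
                     for r in enhancers.stitch_and_rank(make_peaks(grown))}
            assert flags["p8"]


class TestSeScore:
    def test_normalization(self):
        regions = enhancers.stitch(make_peaks([10, 5, 1]))
        scored, meta = enhancers.se_score(regions)
        assert sorted(r.se_score for r in scored) == pytest.approx([0.1, 0.5, 1.0])
        assert meta["n_peaks"] == 3

    def test_single_region_scores_one(self):
        (r,), _ = enhancers.se_score(enhancers.stitch(make_peaks([42])))
        assert r.se_score == 1.0

    def test_scale_invariance(self):
        a, _ = enhancers.se_score(enhancers.stitch(make_peaks([10, 5, 1])))
        b, _ = enhancers.se_score(enhancers.stitch(make_peaks([1000, 500, 100])))
        assert [r.se_score for r in a] == pytest.approx([r.se_score for r in b])

    def test_all_zero_signals_rejected(self):
        with pytest.raises(ValueError):
            enhancers.se_score(enhancers.stitch(make_peaks([0, 0, 0])))


class TestTopEnhancerAssembly:
    def gene(self, start, end):
        return GenomicInterval("chr1", start, end)

    def ses(self, signals, base=1_000_000):
        return [
            enhancers.StitchedEnhancer(
                interval=GenomicInterval("chr1", base + i * 30_000, base + i * 30_000 + 2_000),
                member_names=[f"se{i}"], total_signal=float(s), is_superenhancer=True,
            )
            for i, s in enumerate(signals)
        ]

    def test_fill_arithmetic(self):
        top = enhancers.assemble_top_enhancers(
            self.ses([100, 90, 80]), make_peaks(range(10, 20)), [], k=5
        )
        assert len(top) == 5
        assert [r.name for r in top[:3]] == ["se0", "se1", "se2"]
        # highest-scoring traditional peaks fill the remaining slots
        assert {r.name for r in top[3:]} == {"p9", "p8"}
        assert [r.rank for r in top] == [1, 2, 3, 4, 5]

    def test_gene_overlapping_se_excluded(self):
        ses = self.ses([100, 90])
        gene = self.gene(ses[0].interval.start - 500, ses[0].interval.start + 500)
        top = enhancers.assemble_top_enhancers(ses, make_peaks([50]), [gene], k=2)
        assert [r.name for r in top] == ["se1", "p0"]

    def test_insufficient_candidates_error_reports_counts(self):
        with pytest.raises(ValueError, match="2 superenhancers"):
            enhancers.assemble_top_enhancers(self.ses([10, 9]), [], [], k=5)

    def test_matches_sort_filter_concat_oracle(self):
        rng = np.random.default_rng(111)
        for _ in range(50):
            ses = self.ses(rng.uniform(50, 100, size=3))
            trad = make_peaks([float(x) for x in rng.uniform(0, 60, size=8)])
            genes = [self.gene(int(s), int(s) + 2_000) for s in rng.integers(0, 500_000, size=2)]
            k = 6
            try:
                got = enhancers.assemble_top_enhancers(ses, trad, genes, k=k)
            except ValueError:
                continue
            ses_ok = [r for r in ses if not any(
                genes[j].start < r.interval.end and r.interval.start < genes[j].end
                for j in range(len(genes)))]
            trad_ok = sorted(
                (p for p in trad if not any(
                    g.start < p.interval.end and p.interval.start < g.end for g in genes)),
                key=lambda p: (-p.score, p.name),
            )
            expected = [r.name for r in ses_ok] + [p.name for p in trad_ok[: k - len(ses_ok)]]
            assert sorted(r.name for r in got) == sorted(expected)
            assert [r.se_score for r in got] == sorted(
                (r.se_score for r in got), reverse=True
            )
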