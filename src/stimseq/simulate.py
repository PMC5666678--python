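"""Synthetic cohort generator with planted ground truth.

Generates the full set of inputs the analysis consumes — gene annotation,
transcriptome assembly, H3K27ac peaks, coverage tracks, and per-condition
differential-expression tables — with a :class:`TruthSet` recording what
was planted, so every downstream stage can be tested for exact recovery.

Design of the genome layout: genes are placed left to right with a fixed
inter-gene spacing; each inter-gene gap can host exactly one "item" — a
planted divergent eRNA pair or one decoy pair. Planted pairs satisfy all
four eRNA filters by construction (unspliced, > 2 kb from genes, TSSs
within the pairing window, supporting peak at the TSS). Each decoy class
violates exactly one named filter:

* ``spliced``    — divergent intergenic pair, but both members have 2 exons
* ``neargene``   — divergent unspliced pair placed 0.5–1.5 kb from a gene
* ``farpair``    — divergent pair with TSS separation in (500, 5000] nt
* ``convergent`` — TSS-proximal pair with the wrong orientation
                   (convergent, or tandem on one strand)
* ``nopeak``     — a perfect divergent pair with no supporting peak

Everything is deterministic under the config seed: independent generator
streams are derived from ``(seed, stream_id)`` so adding conditions or
antibodies never perturbs unrelated draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack
from .intervals import GenomicInterval, point_distance
from .models import Peak, TranscriptModel

DECOY_CLASSES = ("spliced", "neargene", "farpair", "convergent", "nopeak")

# stream ids for seed derivation
_S_LAYOUT, _S_ASSEMBLY, _S_PEAKS = 1, 2, 3
_S_BASELINE, _S_NOISE, _S_TRUEFOLD, _S_AFFECTED = 40, 41, 42, 43
_S_COVERAGE = 50


class CohortConfigError(ValueError):
    """The requested cohort cannot be packed into the configured genome."""


@dataclass
class Perturbation:
    """A condition that suppresses the stimulus response of some genes.

    ``affected_fraction`` of the responsive features have their induced
    excess scaled: fold' = 1 + suppression_factor * (fold - 1), so factor 1
    is the identity and factor 0 returns a feature exactly to baseline.
    """

    affected_fraction: float = 0.75
    suppression_factor: float = 0.2


@dataclass
class CohortConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 3_000_000
    # genes
    n_genes: int = 50
    fraction_responsive: float = 0.4
    gene_length_range: tuple[int, int] = (3000, 6000)
    n_exons_range: tuple[int, int] = (2, 4)
    gene_spacing: int = 20_000           # inter-gene distance, >= 5 kb
    intergenic_pad: int = 2500           # item clearance from flanking genes
    # eRNA items
    n_planted_ernas: int = 20
    n_decoys_per_class: int = 5
    erna_length_range: tuple[int, int] = (300, 1200)
    pair_distance_range: tuple[int, int] = (50, 400)
    far_pair_distance_range: tuple[int, int] = (501, 5000)
    # peaks
    peak_coverage_fraction: float = 1.0
    peak_halfwidth: int = 400
    n_background_peaks: int = 10
    # expression
    baseline_fpkm_log_mean: float = math.log(10.0)
    baseline_fpkm_log_sd: float = 0.8
    erna_fpkm_log_mean: float = math.log(1.5)
    erna_fpkm_log_sd: float = 0.5
    fold_lognorm_mean: float = 1.0       # log-scale mean of the induced excess
    fold_lognorm_sd: float = 0.5
    noise_sd: float = 0.15               # sd of log fold-change noise (0 = noise-free)
    baseline_condition: str = "vehicle"
    conditions: tuple[str, ...] = ("egf", "egf_erki", "egf_meki", "shints11")
    perturbations: dict[str, Perturbation] = field(
        default_factory=lambda: {
            "egf_erki": Perturbation(0.75, 0.2),
            "egf_meki": Perturbation(0.75, 0.2),
            "shints11": Perturbation(0.70, 0.25),
        }
    )
    # coverage
    pausing_ratio_range: tuple[float, float] = (2.0, 50.0)
    body_density: float = 1.0
    background_density: float = 0.0
    condition_pausing_multiplier: dict[str, float] = field(
        default_factory=lambda: {"egf_erki": 3.0}
    )
    enhancer_enrichment: float = 10.0

    def validate(self) -> None:
        for frac in (self.fraction_responsive, self.peak_coverage_fraction):
            if not 0 <= frac <= 1:
                raise CohortConfigError(f"fraction {frac} outside [0, 1]")
        for count in (self.n_genes, self.n_planted_ernas, self.n_decoys_per_class,
                      self.n_background_peaks, self.n_chromosomes):
            if count < 0:
                raise CohortConfigError("counts must be >= 0")
        if self.gene_spacing < 5000:
            raise CohortConfigError("gene_spacing must keep genes >= 5 kb apart")
        if self.intergenic_pad <= 2000:
            raise CohortConfigError("intergenic_pad must exceed the 2 kb exclusion zone")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        if "perturbations" in data:
            data["perturbations"] = {
                k: Perturbation(**v) if isinstance(v, dict) else v
                for k, v in data["perturbations"].items()
            }
        for key in ("gene_length_range", "n_exons_range", "erna_length_range",
                    "pair_distance_range", "far_pair_distance_range",
                    "pausing_ratio_range", "conditions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _rng(config: CohortConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


@dataclass
class PlantedErna:
    plus_id: str
    minus_id: str
    peak_name: str | None
    supported: bool
    linked_gene: str | None
    linked_distance: int | None

    @property
    def name(self) -> str:
        return f"{self.plus_id}|{self.minus_id}"


@dataclass
class TruthSet:
    """Ground truth planted by the generator."""

    responsive_gene_ids: set[str] = field(default_factory=set)
    planted_ernas: list[PlantedErna] = field(default_factory=list)
    decoys: dict[str, list[str]] = field(default_factory=dict)  # class -> pair names
    true_fold: dict[str, float] = field(default_factory=dict)
    affected: dict[str, set[str]] = field(default_factory=dict)  # condition -> features
    pausing_ratio: dict[str, float] = field(default_factory=dict)

    @property
    def planted_locus_names(self) -> set[str]:
        return {p.name for p in self.planted_ernas}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "responsive_gene_ids": sorted(self.responsive_gene_ids),
            "planted_ernas": [asdict(p) for p in self.planted_ernas],
            "decoys": {k: sorted(v) for k, v in self.decoys.items()},
            "true_fold": self.true_fold,
            "affected": {k: sorted(v) for k, v in self.affected.items()},
            "pausing_ratio": self.pausing_ratio,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        data = json.loads(Path(path).read_text())
        return cls(
            responsive_gene_ids=set(data["responsive_gene_ids"]),
            planted_ernas=[PlantedErna(**p) for p in data["planted_ernas"]],
            decoys={k: list(v) for k, v in data["decoys"].items()},
            true_fold=data["true_fold"],
            affected={k: set(v) for k, v in data["affected"].items()},
            pausing_ratio=data["pausing_ratio"],
        )


# ---------------------------------------------------------------------------
# expression truth (independent of the genome layout, so very large feature
# universes can be simulated without packing them into chromosomes)

def _feature_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    ernas = [f"ERNA{i:04d}.plus|ERNA{i:04d}.minus" for i in range(config.n_planted_ernas)]
    return genes, ernas


def _expression_truth(config: CohortConfig) -> tuple[set[str], dict[str, float], dict[str, set[str]]]:
    """Responsive ids, per-feature true fold induction, affected set per condition."""
    genes, ernas = _feature_ids(config)
    rng = _rng(config, _S_TRUEFOLD)
    n_resp = round(config.fraction_responsive * config.n_genes)
    resp_idx = sorted(rng.choice(config.n_genes, size=n_resp, replace=False)) if n_resp else []
    responsive = {genes[i] for i in resp_idx}
    true_fold = {g: 1.0 for g in genes}
    excess = rng.lognormal(config.fold_lognorm_mean, config.fold_lognorm_sd, size=n_resp)
    for i, idx in enumerate(resp_idx):
        true_fold[genes[idx]] = 2.0 + excess[i]  # support guarantees fold > 2
    erna_excess = rng.lognormal(config.fold_lognorm_mean, config.fold_lognorm_sd,
                                size=len(ernas))
    for name, ex in zip(ernas, erna_excess):
        true_fold[name] = 1.6 + ex  # all planted loci are induced (fold > 1.6)

    rng_aff = _rng(config, _S_AFFECTED)
    affected: dict[str, set[str]] = {}
    for cond in sorted(config.perturbations):
        pert = config.perturbations[cond]
        aff: set[str] = set()
        for pool in (sorted(responsive), list(ernas)):
            k = round(pert.affected_fraction * len(pool))
            if k:
                aff.update(rng_aff.choice(pool, size=k, replace=False))
        affected[cond] = aff
    return responsive, true_fold, affected


def simulate_expression(
    config: CohortConfig, condition: str, features: str = "all"
) -> pd.DataFrame:
    """Per-feature expression table for one condition arm vs. the baseline.

    Columns: ``feature_id, fpkm_<baseline>, fpkm_<condition>, fold_change,
    q_value``. Responsive features are induced by their planted fold
    (suppressed under perturbed conditions); all features get multiplicative
    log-normal noise shared across conditions, so a suppression factor of 1
    reproduces the control arm exactly. p-values come from a two-sided
    z-score on the log fold change under the noise null and are BH-adjusted
    across the table.

    ``features`` restricts the table to ``'genes'``, ``'ernas'``, or ``'all'``.
    """
    config.validate()
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; configured: {config.conditions}")
    genes, ernas = _feature_ids(config)
    responsive, true_fold, affected = _expression_truth(config)

    rng_base = _rng(config, _S_BASELINE)
    base_genes = rng_base.lognormal(config.baseline_fpkm_log_mean,
                                    config.baseline_fpkm_log_sd, size=len(genes))
    base_ernas = rng_base.lognormal(config.erna_fpkm_log_mean,
                                    config.erna_fpkm_log_sd, size=len(ernas))
    all_ids = genes + ernas
    baseline = np.concatenate([base_genes, base_ernas]) if all_ids else np.empty(0)
    # noise is drawn per feature only, so arms differ solely through the
    # perturbation (a suppression factor of 1 gives a byte-identical table)
    noise = _rng(config, _S_NOISE).normal(0.0, config.noise_sd, size=len(all_ids)) \
        if config.noise_sd > 0 else np.zeros(len(all_ids))

    pert = config.perturbations.get(condition)
    fold_true = np.empty(len(all_ids))
    for i, fid in enumerate(all_ids):
        f = true_fold[fid]
        if pert is not None and fid in affected.get(condition, set()):
            f = 1.0 + pert.suppression_factor * (f - 1.0)
        fold_true[i] = f
    observed = fold_true * np.exp(noise)
    fpkm_after = baseline * observed
    signed = np.where(observed >= 1.0, observed, -1.0 / observed)
    if config.noise_sd > 0:
        z = np.abs(np.log(observed)) / config.noise_sd
        p = 2.0 * norm.sf(z)
    else:
        p = np.where(np.isclose(observed, 1.0), 1.0, 0.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else p

    df = pd.DataFrame(
        {
            "feature_id": all_ids,
            f"fpkm_{config.baseline_condition}": baseline,
            f"fpkm_{condition}": fpkm_after,
            "fold_change": signed,
            "q_value": q,
        }
    )
    if features == "genes":
        df = df[df["feature_id"].isin(genes)].reset_index(drop=True)
    elif features == "ernas":
        df = df[df["feature_id"].isin(ernas)].reset_index(drop=True)
    elif features != "all":
        raise ValueError("features must be 'genes', 'ernas', or 'all'")
    return df


# ---------------------------------------------------------------------------
# genome layout

@dataclass
class Cohort:
    config: CohortConfig
    genes: list[TranscriptModel]
    assembly: list[TranscriptModel]
    peaks: list[Peak]
    truth: TruthSet

    def expression(self, condition: str, features: str = "all") -> pd.DataFrame:
        return simulate_expression(self.config, condition, features=features)

    def coverage(self, antibody: str = "rnapii", condition: str = "egf") -> CoverageTrack:
        track, _ = simulate_coverage(self.config, self.genes, antibody=antibody,
                                     condition=condition)
        return track

    def enhancer_tracks(self) -> tuple[CoverageTrack, CoverageTrack]:
        return simulate_enhancer_tracks(self.config, self.truth, self.assembly)


def _make_gene(gid: str, chrom: str, start: int, length: int, strand: str,
               n_exons: int, rng: np.random.Generator) -> TranscriptModel:
    n_seg = 2 * n_exons - 1
    min_seg = 100
    extra = rng.multinomial(length - min_seg * n_seg, np.full(n_seg, 1.0 / n_seg))
    seg_lens = extra + min_seg
    exons = []
    pos = start
    for i, seg in enumerate(seg_lens):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + int(seg), strand))
        pos += int(seg)
    iv = GenomicInterval(chrom, start, start + length, strand)
    return TranscriptModel(f"{gid}.t1", iv, exons, gene_id=gid)


def _unspliced(tid: str, chrom: str, start: int, length: int, strand: str,
               gene_id: str | None = None) -> TranscriptModel:
    iv = GenomicInterval(chrom, start, start + length, strand)
    return TranscriptModel(tid, iv, [iv], gene_id=gene_id or tid)


def _spliced_pair_member(tid: str, chrom: str, start: int, length: int,
                         strand: str) -> TranscriptModel:
    iv = GenomicInterval(chrom, start, start + length, strand)
    cut = length // 3
    exons = [
        GenomicInterval(chrom, start, start + cut, strand),
        GenomicInterval(chrom, start + 2 * cut, start + length, strand),
    ]
    return TranscriptModel(tid, iv, exons, gene_id=tid)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Lay out genes and eRNA items on the synthetic genome and plant truth."""
    config.validate()
    gene_ids, _ = _feature_ids(config)
    responsive, true_fold, affected = _expression_truth(config)

    rng_lay = _rng(config, _S_LAYOUT)
    rng_asm = _rng(config, _S_ASSEMBLY)
    rng_pk = _rng(config, _S_PEAKS)

    reserve = 60_000  # background-peak zone at each chromosome end
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.n_genes and not config.n_chromosomes:
        raise CohortConfigError("need at least one chromosome")

    # items: which gap after gene i hosts which (kind, index)
    items: list[tuple[str, int]] = [("planted", i) for i in range(config.n_planted_ernas)]
    for cls in DECOY_CLASSES:
        items += [(cls, i) for i in range(config.n_decoys_per_class)]
    if len(items) > config.n_genes:
        raise CohortConfigError(
            f"{len(items)} eRNA items need {len(items)} inter-gene gaps "
            f"but only {config.n_genes} genes are configured"
        )
    gap_width = config.gene_spacing - 2 * config.intergenic_pad
    max_item = 2 * config.erna_length_range[1] + config.far_pair_distance_range[1] + 100
    if gap_width < max_item:
        raise CohortConfigError(
            f"gene_spacing too small: gap {gap_width} bp cannot host items up to {max_item} bp"
        )
    gap_order = rng_lay.permutation(config.n_genes)
    item_of_gap: dict[int, tuple[str, int]] = {
        int(gap_order[j]): items[j] for j in range(len(items))
    }

    genes: list[TranscriptModel] = []
    assembly: list[TranscriptModel] = []
    peaks: list[Peak] = []
    truth = TruthSet(responsive_gene_ids=responsive, true_fold=true_fold,
                     affected=affected, decoys={cls: [] for cls in DECOY_CLASSES})

    n_supported = round(config.peak_coverage_fraction * config.n_planted_ernas)
    supported_idx = set(
        int(i) for i in rng_pk.choice(config.n_planted_ernas, size=n_supported, replace=False)
    ) if config.n_planted_ernas else set()
    planted_geom: dict[int, tuple[TranscriptModel, TranscriptModel]] = {}

    cursors = {c: 10_000 for c in chrom_names}
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chromosomes]
        length = int(rng_lay.integers(*config.gene_length_range, endpoint=True))
        strand = str(rng_lay.choice(["+", "-"]))
        n_exons = int(rng_lay.integers(*config.n_exons_range, endpoint=True))
        start = cursors[chrom]
        gene = _make_gene(gene_ids[gi], chrom, start, length, strand, n_exons, rng_lay)
        genes.append(gene)
        gene_end = start + length
        cursors[chrom] = gene_end + config.gene_spacing
        if cursors[chrom] > config.chrom_length - reserve:
            raise CohortConfigError(
                f"chromosome {chrom} too short for the configured gene count/spacing"
            )

        item = item_of_gap.get(gi)
        if item is None:
            continue
        kind, idx = item
        gap_start = gene_end + config.intergenic_pad
        lm = int(rng_asm.integers(*config.erna_length_range, endpoint=True))
        lp = int(rng_asm.integers(*config.erna_length_range, endpoint=True))
        if kind == "farpair":
            d = int(rng_asm.integers(*config.far_pair_distance_range, endpoint=True))
        else:
            d = int(rng_asm.integers(*config.pair_distance_range, endpoint=True))

        if kind in ("planted", "nopeak", "spliced", "neargene"):
            # divergent geometry: minus body leftward of its TSS `a`, plus
            # body rightward of its TSS `a + d`
            if kind == "neargene":
                # both members must start inside the 2 kb exclusion zone so
                # the whole pair is eliminated at the gene-proximity stage
                ms = gene_end + int(rng_asm.integers(500, 700, endpoint=True))
                lm = min(lm, 500)
                lp = min(lp, 500)
                d = min(d, 300)
            else:
                ms = gap_start
            a = ms + lm - 1
            prefix = {"planted": f"ERNA{idx:04d}", "nopeak": f"DECOY_nopeak_{idx:02d}",
                      "spliced": f"DECOY_spliced_{idx:02d}",
                      "neargene": f"DECOY_neargene_{idx:02d}"}[kind]
            maker = _spliced_pair_member if kind == "spliced" else _unspliced
            minus = maker(f"{prefix}.minus", chrom, ms, lm, "-")
            plus = maker(f"{prefix}.plus", chrom, a + d, lp, "+")
            assembly += [plus, minus]
            pair_name = f"{prefix}.plus|{prefix}.minus"
            if kind == "planted":
                planted_geom[idx] = (plus, minus)
                supported = idx in supported_idx
                peak_name = None
                if supported:
                    mid = (a + a + d) // 2
                    peak_name = f"h3k27ac_{len(peaks) + 1:05d}"
                    peaks.append(Peak(
                        GenomicInterval(chrom, mid - config.peak_halfwidth,
                                        mid + config.peak_halfwidth + 1),
                        score=float(rng_pk.uniform(20, 100)), name=peak_name,
                    ))
                # nearest responsive gene filled in after layout completes
                truth.planted_ernas.append(PlantedErna(
                    plus_id=plus.id, minus_id=minus.id, peak_name=peak_name,
                    supported=supported, linked_gene=None, linked_distance=None,
                ))
            else:
                truth.decoys[kind].append(pair_name)
                if kind != "nopeak":
                    mid = (a + a + d) // 2
                    peaks.append(Peak(
                        GenomicInterval(chrom, mid - config.peak_halfwidth,
                                        mid + config.peak_halfwidth + 1),
                        score=float(rng_pk.uniform(20, 100)),
                        name=f"h3k27ac_{len(peaks) + 1:05d}",
                    ))
        elif kind == "farpair":
            ms = gap_start
            a = ms + lm - 1
            prefix = f"DECOY_farpair_{idx:02d}"
            minus = _unspliced(f"{prefix}.minus", chrom, ms, lm, "-")
            plus = _unspliced(f"{prefix}.plus", chrom, a + d, lp, "+")
            assembly += [plus, minus]
            truth.decoys[kind].append(f"{prefix}.plus|{prefix}.minus")
            peaks.append(Peak(  # support at the minus TSS only
                GenomicInterval(chrom, max(0, a - config.peak_halfwidth),
                                a + config.peak_halfwidth + 1),
                score=float(rng_pk.uniform(20, 100)),
                name=f"h3k27ac_{len(peaks) + 1:05d}",
            ))
        else:  # convergent / tandem orientation decoys
            prefix = f"DECOY_convergent_{idx:02d}"
            if idx % 2 == 0:
                # convergent: plus TSS 5' of minus TSS, bodies pointing inward
                plus = _unspliced(f"{prefix}.plus", chrom, gap_start + lm, lp, "+")
                m_tss = plus.tss() + d
                minus = _unspliced(f"{prefix}.minus", chrom, m_tss + 1 - lm, lm, "-")
                assembly += [plus, minus]
                mid = (plus.tss() + m_tss) // 2
            else:
                # tandem: two same-strand transcripts with proximal TSSs
                t1 = _unspliced(f"{prefix}.a", chrom, gap_start, lp, "+")
                t2 = _unspliced(f"{prefix}.b", chrom, gap_start + d, lm, "+")
                plus, minus = t1, t2
                assembly += [t1, t2]
                mid = (t1.tss() + t2.tss()) // 2
            truth.decoys[kind].append(f"{plus.id}|{minus.id}")
            peaks.append(Peak(
                GenomicInterval(chrom, mid - config.peak_halfwidth,
                                mid + config.peak_halfwidth + 1),
                score=float(rng_pk.uniform(20, 100)),
                name=f"h3k27ac_{len(peaks) + 1:05d}",
            ))

    # background peaks in the reserved zone at each chromosome end
    for bi in range(config.n_background_peaks):
        chrom = chrom_names[bi % config.n_chromosomes]
        slot = bi // config.n_chromosomes
        base = config.chrom_length - reserve + 5_000 + slot * 3_000
        start = base + int(rng_pk.integers(0, 1000))
        peaks.append(Peak(
            GenomicInterval(chrom, start, start + int(rng_pk.integers(500, 1500))),
            score=float(rng_pk.uniform(5, 40)),
            name=f"h3k27ac_{len(peaks) + 1:05d}",
        ))

    # link each planted locus to the nearest responsive gene within 300 kb
    resp_genes = [g for g in genes if g.gene_id in responsive]
    for planted in truth.planted_ernas:
        plus, minus = planted_geom[int(planted.plus_id[4:8])]
        mid = (min(plus.interval.start, minus.interval.start)
               + max(plus.interval.end, minus.interval.end)) // 2
        best: tuple[int, str] | None = None
        for g in resp_genes:
            if g.chrom != plus.chrom:
                continue
            dist = point_distance(mid, g.interval)
            key = (dist, g.gene_id)
            if best is None or key < best:
                best = key
        if best is not None and best[0] <= 300_000:
            planted.linked_gene, planted.linked_distance = best[1], best[0]

    # pausing ratios used for the default coverage track, recorded as truth
    _, ratios = simulate_coverage(config, genes, antibody="rnapii", condition="egf")
    truth.pausing_ratio = ratios

    for cls in truth.decoys:
        truth.decoys[cls].sort()
    truth.planted_ernas.sort(key=lambda p: p.name)
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.name))
    assembly.sort(key=lambda t: (t.chrom, t.interval.start, t.id))
    return Cohort(config=config, genes=genes, assembly=assembly, peaks=peaks, truth=truth)


def simulate_annotation(config: CohortConfig) -> tuple[list[TranscriptModel], TruthSet]:
    cohort = generate_cohort(config)
    return cohort.genes, cohort.truth


def simulate_assembly(config: CohortConfig) -> list[TranscriptModel]:
    return generate_cohort(config).assembly


def simulate_peaks(config: CohortConfig) -> list[Peak]:
    return generate_cohort(config).peaks


_ANTIBODY_STREAM = {"rnapii": 0, "ints11": 1}


def simulate_coverage(
    config: CohortConfig,
    transcripts: Sequence[TranscriptModel],
    antibody: str = "rnapii",
    condition: str = "egf",
    pausing_ratios: dict[str, float] | None = None,
) -> tuple[CoverageTrack, dict[str, float]]:
    """Coverage track with a planted promoter-proximal pausing ratio.

    Per transcript the TSS window (−30/+300) carries ``ratio × body``
    density and the body (through TES + 1 kb) carries the base body
    density; elsewhere the track sits at the configured background.
    Ratios are drawn log-uniformly from ``pausing_ratio_range`` per
    antibody (or passed explicitly) and scaled by the per-condition
    multiplier.
    """
    if antibody not in _ANTIBODY_STREAM:
        raise ValueError(f"unknown antibody {antibody!r}")
    ordered = sorted(transcripts, key=lambda t: t.id)
    if pausing_ratios is None:
        rng = _rng(config, _S_COVERAGE, _ANTIBODY_STREAM[antibody])
        lo, hi = config.pausing_ratio_range
        draws = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(ordered)))
        pausing_ratios = {t.id: float(r) for t, r in zip(ordered, draws)}
    mult = config.condition_pausing_multiplier.get(condition, 1.0)

    blocks: list[tuple[str, int, int, float]] = []
    if config.background_density > 0:
        for c in sorted({t.chrom for t in ordered}):
            blocks.append((c, 0, config.chrom_length, config.background_density))
    ratios_used: dict[str, float] = {}
    for t in ordered:
        r = pausing_ratios[t.id] * mult
        ratios_used[t.id] = r
        tss, tes = t.tss(), t.tes()
        if t.strand == "+":
            tss_win = (tss - 30, tss + 301)
            body = (tss + 301, tes + 1001)
        else:
            tss_win = (tss - 300, tss + 31)
            body = (max(0, tes - 1000), tss - 300)
        blocks.append((t.chrom, max(0, tss_win[0]), tss_win[1], r * config.body_density))
        if body[1] > body[0]:
            blocks.append((t.chrom, body[0], body[1], config.body_density))
    return CoverageTrack.from_steps(blocks), ratios_used


def simulate_enhancer_tracks(
    config: CohortConfig, truth: TruthSet, assembly: Sequence[TranscriptModel]
) -> tuple[CoverageTrack, CoverageTrack]:
    """Treatment/control RNA-seq-style pair for the enrichment peak caller.

    Control is flat background; treatment adds ``enhancer_enrichment`` ×
    background over every peak-supported planted locus (±500 bp).
    """
    by_id = {t.id: t for t in assembly}
    chroms = sorted({t.chrom for t in assembly}) or ["chr1"]
    base = max(config.background_density, 1.0)
    control_blocks = [(c, 0, config.chrom_length, base) for c in chroms]
    treat_blocks = list(control_blocks)
    for planted in truth.planted_ernas:
        if not planted.supported:
            continue
        plus, minus = by_id[planted.plus_id], by_id[planted.minus_id]
        start = min(plus.interval.start, minus.interval.start) - 500
        end = max(plus.interval.end, minus.interval.end) + 500
        treat_blocks.append((plus.chrom, max(0, start), end,
                             config.enhancer_enrichment * base))
    return CoverageTrack.from_steps(treat_blocks), CoverageTrack.from_steps(control_blocks)
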