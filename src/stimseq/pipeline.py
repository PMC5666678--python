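"""End-to-end pipeline: generate → annotate → classify → score → metrics.

A run is driven by one config (YAML or in-memory), writes every stage's
outputs as plain-text genomics formats into an output directory, and emits
a manifest recording the config hash, seed, per-stage output digests and
feature counts. Re-running with the same config and seed reproduces
byte-identical outputs; a ``state.json`` marker makes interrupted runs
resumable (completed stages with intact outputs are skipped).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, erna, enhancers, io, pausing, responsiveness, simulate

log = logging.getLogger("stimseq.pipeline")

STAGE_ORDER = ("generate", "annotate", "classify", "score", "metrics")


@dataclass
class EnhancerStageParams:
    window: int = 100
    min_fold: float = 4.0
    merge_gap: int = 1000
    eps: float = 0.5
    stitch_distance: int = 12_500
    top_k: int = 10


@dataclass
class MetricsStageParams:
    control_condition: str = "egf"
    treatment_condition: str = "egf_erki"
    min_fpkm: float = 1.0
    flank: int = 2000
    bin_width: int = 50


@dataclass
class PipelineConfig:
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    erna: erna.ErnaParams = field(default_factory=erna.ErnaParams)
    enhancer: EnhancerStageParams = field(default_factory=EnhancerStageParams)
    metrics: MetricsStageParams = field(default_factory=MetricsStageParams)
    n_control_genes: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        seed = data.pop("seed", None)
        cfg = cls(
            cohort=simulate.CohortConfig.from_dict(data.get("cohort", {})),
            erna=erna.ErnaParams(**data.get("erna", {})),
            enhancer=EnhancerStageParams(**data.get("enhancer", {})),
            metrics=MetricsStageParams(**data.get("metrics", {})),
            n_control_genes=data.get("n_control_genes", 10),
        )
        if seed is not None:
            cfg.cohort.seed = seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


class PipelineRun:
    """One pipeline execution rooted at ``outdir``."""

    def __init__(self, config: PipelineConfig, outdir: str | Path) -> None:
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._state_path = self.outdir / "state.json"
        self._state: dict[str, dict] = {}
        if self._state_path.exists():
            self._state = json.loads(self._state_path.read_text())
            if self._state.get("__config_hash__") != _config_hash(config):
                log.info("config changed; discarding previous state")
                self._state = {}

    # -- helpers ----------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _stage_done(self, stage: str, outputs: list[str]) -> bool:
        return stage in self._state and all(self.path(o).exists() for o in outputs)

    def _mark_done(self, stage: str, outputs: list[str], counts: dict) -> None:
        self._state[stage] = {"outputs": outputs, "counts": counts}
        self._state["__config_hash__"] = _config_hash(self.config)
        self._state_path.write_text(json.dumps(self._state, indent=1, sort_keys=True))

    # -- stages -----------------------------------------------------------
    def stage_generate(self) -> None:
        cfg = self.config.cohort
        outputs = (
            ["genes.gtf", "assembly.gtf", "peaks.bed", "truth.json",
             "rnaseq_treatment.bedgraph", "rnaseq_control.bedgraph"]
            + [f"expression_{c}.tsv" for c in cfg.conditions]
            + [f"coverage_rnapii_{c}.bedgraph"
               for c in (self.config.metrics.control_condition,
                         self.config.metrics.treatment_condition)]
        )
        if self._stage_done("generate", outputs):
            log.info("generate: reusing completed outputs")
            return
        cohort = simulate.generate_cohort(cfg)
        io.write_gtf(cohort.genes, self.path("genes.gtf"))
        io.write_gtf(cohort.assembly, self.path("assembly.gtf"))
        io.write_bed(cohort.peaks, self.path("peaks.bed"))
        cohort.truth.to_json(self.path("truth.json"))
        for cond in cfg.conditions:
            io.write_expression_table(
                cohort.expression(cond), self.path(f"expression_{cond}.tsv")
            )
        for cond in {self.config.metrics.control_condition,
                     self.config.metrics.treatment_condition}:
            io.write_bedgraph(
                cohort.coverage("rnapii", cond), self.path(f"coverage_rnapii_{cond}.bedgraph")
            )
        treat, ctrl = cohort.enhancer_tracks()
        io.write_bedgraph(treat, self.path("rnaseq_treatment.bedgraph"))
        io.write_bedgraph(ctrl, self.path("rnaseq_control.bedgraph"))
        counts = {
            "n_genes": len(cohort.genes),
            "n_assembly_transcripts": len(cohort.assembly),
            "n_peaks": len(cohort.peaks),
            "n_planted_ernas": len(cohort.truth.planted_ernas),
        }
        log.info("generate: %s", counts)
        self._mark_done("generate", outputs, counts)

    def stage_annotate(self) -> None:
        outputs = ["ernas.bed", "merged.gtf", "erna_stages.json"]
        if self._stage_done("annotate", outputs):
            log.info("annotate: reusing completed outputs")
            return
        assembly = io.read_gtf(self.path("assembly.gtf"))
        genes = io.read_gtf(self.path("genes.gtf"))
        peaks = io.read_bed(self.path("peaks.bed"))
        result = erna.annotate_ernas(
            assembly, io.gene_spans(genes), peaks, params=self.config.erna
        )
        io.write_bed(erna.loci_to_peaks(result.loci), self.path("ernas.bed"))
        merged = genes + erna.loci_to_transcripts(result.loci)
        io.write_gtf(
            merged, self.path("merged.gtf"),
            feature_class={l.name: "erna" for l in result.loci},
        )
        self.path("erna_stages.json").write_text(
            json.dumps(result.stage_counts, indent=1, sort_keys=True)
        )
        counts = {"n_erna_loci": len(result.loci), **{
            f"stage_{k}": v for k, v in result.stage_counts.items()
        }}
        log.info("annotate: %s", counts)
        self._mark_done("annotate", outputs, counts)

    def stage_classify(self) -> None:
        cfg = self.config.cohort
        perturbed = sorted(cfg.perturbations)
        outputs = (
            ["responsive_genes.tsv", "responsive_ernas.tsv", "controls.txt", "linkage.tsv"]
            + [f"affected_{c}.tsv" for c in perturbed]
        )
        if self._stage_done("classify", outputs):
            log.info("classify: reusing completed outputs")
            return
        genes = io.read_gtf(self.path("genes.gtf"))
        gene_ids = {t.gene_id or t.id for t in genes}
        erna_names = {p.name for p in io.read_bed(self.path("ernas.bed"))}
        before = cfg.baseline_condition
        control_cond = self.config.metrics.control_condition
        tables = {
            c: io.read_expression_table(self.path(f"expression_{c}.tsv"))
            for c in cfg.conditions
        }
        control = tables[control_cond]
        gene_table = control[control["feature_id"].isin(gene_ids)]
        erna_table = control[control["feature_id"].isin(erna_names)]
        resp_genes = responsiveness.call_responsive_genes(gene_table, before, control_cond) \
            if not gene_table.empty else pd.DataFrame(columns=["feature_id", "fold_induction", "rank"])
        if not erna_table.empty:
            resp_ernas = responsiveness.call_responsive_ernas(erna_table, before, control_cond)
        else:
            resp_ernas = pd.DataFrame(columns=["feature_id", "fold_induction", "rank"])
        io.write_expression_table(resp_genes, self.path("responsive_genes.tsv"))
        io.write_expression_table(resp_ernas, self.path("responsive_ernas.tsv"))

        counts = {
            "n_responsive_genes": len(resp_genes),
            "n_responsive_ernas": len(resp_ernas),
        }
        for cond in perturbed:
            table = tables[cond]
            affected = responsiveness.classify_affected(
                resp_genes, control, table, before, control_cond, perturbed_after=cond,
            ) if len(resp_genes) else pd.DataFrame(columns=["feature_id", "rank", "affected", "rule"])
            io.write_expression_table(affected, self.path(f"affected_{cond}.tsv"))
            counts[f"n_affected_{cond}"] = int(affected["affected"].sum()) if len(affected) else 0

        try:
            controls = responsiveness.select_control_genes(
                {c: t[t["feature_id"].isin(gene_ids)] for c, t in tables.items()},
                n=self.config.n_control_genes, seed=cfg.seed,
                fpkm_col=f"fpkm_{before}",
            )
        except ValueError as exc:
            log.warning("control-gene selection skipped: %s", exc)
            controls = set()
        self.path("controls.txt").write_text("\n".join(sorted(controls)) + "\n")
        counts["n_control_genes"] = len(controls)

        # link induced eRNA loci to responsive genes within 300 kb
        loci_peaks = io.read_bed(self.path("ernas.bed"))
        induced = set(resp_ernas["feature_id"]) if len(resp_ernas) else set()
        induced_loci = [
            erna.ErnaLocus(
                plus_id=p.name.split("|")[0], minus_id=p.name.split("|")[1],
                interval=p.interval, inter_tss_distance=int(p.score),
            )
            for p in loci_peaks if p.name in induced
        ]
        resp_gene_models = [t for t in genes if (t.gene_id or t.id) in set(resp_genes["feature_id"])]
        linked = erna.link_to_responsive_genes(
            induced_loci, resp_gene_models, max_distance=self.config.erna.link_distance
        )
        pd.DataFrame(
            [
                {"locus": l.name, "linked_gene": l.linked_gene, "distance_bp": l.linked_distance}
                for l in linked
            ]
        ).to_csv(self.path("linkage.tsv"), sep="\t", index=False)
        counts["n_linked_ernas"] = len(linked)
        log.info("classify: %s", counts)
        self._mark_done("classify", outputs, counts)

    def stage_score(self) -> None:
        outputs = ["enhancer_peaks.bed", "stitched_enhancers.tsv", "top_enhancers.tsv"]
        if self._stage_done("score", outputs):
            log.info("score: reusing completed outputs")
            return
        p = self.config.enhancer
        treat = io.read_bedgraph(self.path("rnaseq_treatment.bedgraph"))
        ctrl = io.read_bedgraph(self.path("rnaseq_control.bedgraph"))
        peaks = enhancers.detect_enrichment_peaks(
            treat, ctrl, window=p.window, min_fold=p.min_fold,
            merge_gap=p.merge_gap, eps=p.eps,
        )
        io.write_bed(peaks, self.path("enhancer_peaks.bed"))
        regions = enhancers.stitch_and_rank(peaks, stitch_distance=p.stitch_distance)
        if regions:
            regions, meta = enhancers.se_score(regions)
        else:
            meta = {"n_peaks": 0}
        pd.DataFrame(
            [
                {
                    "chrom": r.interval.chrom, "start": r.interval.start,
                    "end": r.interval.end, "members": r.name,
                    "total_signal": r.total_signal, "se_score": r.se_score,
                    "rank": r.rank, "is_superenhancer": r.is_superenhancer,
                }
                for r in regions
            ]
        ).to_csv(self.path("stitched_enhancers.tsv"), sep="\t", index=False)
        ses = [r for r in regions if r.is_superenhancer]
        se_members = {m for r in ses for m in r.member_names}
        traditional = [pk for pk in peaks if pk.name not in se_members]
        gene_spans = io.gene_spans(io.read_gtf(self.path("genes.gtf")))
        n_available = len(ses) + len(traditional)
        k = min(p.top_k, n_available)
        k = max(k, len(ses))
        if n_available:
            top = enhancers.assemble_top_enhancers(ses, traditional, gene_spans, k=k)
        else:
            top = []
        pd.DataFrame(
            [
                {
                    "chrom": r.interval.chrom, "start": r.interval.start,
                    "end": r.interval.end, "members": r.name,
                    "total_signal": r.total_signal, "se_score": r.se_score,
                    "rank": r.rank, "is_superenhancer": r.is_superenhancer,
                }
                for r in top
            ]
        ).to_csv(self.path("top_enhancers.tsv"), sep="\t", index=False)
        counts = {
            "n_enhancer_peaks": len(peaks),
            "n_stitched_regions": len(regions),
            "n_superenhancers": len(ses),
            "n_top_enhancers": len(top),
            "peak_universe": meta["n_peaks"],
        }
        log.info("score: %s", counts)
        self._mark_done("score", outputs, counts)

    def stage_metrics(self) -> None:
        m = self.config.metrics
        outputs = [
            f"traveling_ratio_{m.control_condition}.tsv",
            f"traveling_ratio_{m.treatment_condition}.tsv",
            "ks.json", "metaprofile.tsv",
        ]
        if self._stage_done("metrics", outputs):
            log.info("metrics: reusing completed outputs")
            return
        genes = io.read_gtf(self.path("genes.gtf"))
        expr = io.read_expression_table(
            self.path(f"expression_{m.control_condition}.tsv")
        )
        fpkm_col = f"fpkm_{m.control_condition}"
        samples = {}
        for cond in (m.control_condition, m.treatment_condition):
            track = io.read_bedgraph(self.path(f"coverage_rnapii_{cond}.bedgraph"))
            records, excluded = pausing.traveling_ratio_distribution(
                track, genes, expr, fpkm_col, min_fpkm=m.min_fpkm
            )
            pausing.records_to_frame(records + excluded).to_csv(
                self.path(f"traveling_ratio_{cond}.tsv"), sep="\t", index=False
            )
            samples[cond] = [r.log10_ratio for r in records]
        if samples[m.control_condition] and samples[m.treatment_condition]:
            d, pval = pausing.ks_two_sample(
                samples[m.control_condition], samples[m.treatment_condition]
            )
        else:
            d, pval = float("nan"), float("nan")
        self.path("ks.json").write_text(json.dumps(
            {"D": d, "p_value": pval,
             "n_control": len(samples[m.control_condition]),
             "n_treatment": len(samples[m.treatment_condition])},
            indent=1, sort_keys=True,
        ))
        track = io.read_bedgraph(
            self.path(f"coverage_rnapii_{m.control_condition}.bedgraph")
        )
        anchors = [(t.chrom, t.tss(), t.strand) for t in genes]
        profile = pausing.metaprofile(track, anchors, flank=m.flank, bin_width=m.bin_width)
        pd.DataFrame({"offset_bp": profile.offsets, "mean_density": profile.means}).to_csv(
            self.path("metaprofile.tsv"), sep="\t", index=False
        )
        counts = {
            "n_tr_records": len(samples[m.control_condition]),
            "ks_D": round(d, 6) if d == d else None,
            "n_profile_anchors": profile.n_anchors,
        }
        log.info("metrics: %s", counts)
        self._mark_done("metrics", outputs, counts)

    # -- driver -----------------------------------------------------------
    def run(self) -> dict:
        for stage in STAGE_ORDER:
            getattr(self, f"stage_{stage}")()
        manifest = self.build_manifest()
        self.path("manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        return manifest

    def build_manifest(self) -> dict:
        stages = {}
        for stage in STAGE_ORDER:
            info = self._state.get(stage)
            if info is None:
                continue
            stages[stage] = {
                "outputs": {o: _digest(self.path(o)) for o in info["outputs"]},
                "counts": info["counts"],
            }
        return {
            "tool": "stimseq",
            "version": __version__,
            "seed": self.config.cohort.seed,
            "config_hash": _config_hash(self.config),
            "stages": stages,
        }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    return PipelineRun(config, outdir).run()


def report(manifest: dict) -> str:
    """Deterministic human-readable run summary from a manifest."""
    lines = [
        f"stimseq {manifest['version']} run (seed {manifest['seed']}, "
        f"config {manifest['config_hash'][:12]})"
    ]
    for stage in STAGE_ORDER:
        info = manifest["stages"].get(stage)
        if info is None:
            lines.append(f"  {stage}: NOT RUN")
            continue
        counts = ", ".join(f"{k}={v}" for k, v in sorted(info["counts"].items()))
        lines.append(f"  {stage}: {counts}")
    return "\n".join(lines)
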