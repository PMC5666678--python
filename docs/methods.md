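# Methods

This note documents the models and procedures stimseq implements, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic-data validation does and does not establish.

## Coordinate conventions and interval algebra

All in-memory coordinates are 0-based half-open (BED convention); GTF files
are converted from/to 1-based inclusive at the I/O boundary, and all
conversions compose to identity (round-trip tested). The TSS of a
minus-strand transcript is the **last** base of its span (the biological 5′
end); the TES is symmetric. Overlap queries take a symmetric,
strand-ignorant slack — this is how the ±2 kb gene-exclusion zone and
±500 bp peak windows are implemented, since neither filter is
strand-qualified. Directional windows (e.g. the promoter-proximal −30/+300
window) cover `upstream + downstream + 1` bases inclusive of the anchor,
mirrored on the minus strand, and clip at position 0 with a flag.

Coverage tracks are run-length encoded per chromosome and strand-agnostic
(ChIP-seq-style input); queries outside covered steps return 0. Chromatin
RNA-seq coverage used for eRNA work is likewise treated as unstranded —
strand-resolved quantification is a possible refinement the present track
model does not attempt.

## Responsiveness classification

All printed thresholds are applied as **strict** inequalities (q < 0.05
excludes q = 0.05; fold > 2 excludes 2.0). Fold induction uses a
pseudocount (default 0.1 FPKM, configurable) so zero-FPKM features stay
finite; responsive genes must have FPKM > 1, so the default is inert on
them. The signed fold-change convention reports an x-fold reduction as −x,
which makes "fold < 2 or fold > −2" the non-differential band |fold| < 2
used for control-gene eligibility — the only reading under which both
clauses bind.

The tiered affected-gene rule ranks responsive genes by control-arm fold
induction (ties broken by feature id for determinism; tier cut at
⌈0.30·n⌉). Tier 1 compares **fold inductions** (the quantity the ranking is
built from): affected when perturbed induction ≤ 0.5 × control induction.
Tier 2 declares a gene affected when it loses differential status in the
perturbed arm (q > 0.05 and fold < 2 after stimulation). The knockdown
reduction rule compares post-stimulation expression levels and is
**inclusive** at the boundary (exactly 40 % down counts); both the 0.40
threshold and the inclusivity are parameters, since "40 % in gene
expression" admits more than one reading.

## eRNA identification

The cascade is: keep unspliced (single-exon) transcripts → remove anything
overlapping or within ±2 kb of gene spans → pair head-to-head → require
H3K27ac support. "Head-to-head" means **divergent**: opposite strands,
TSS-to-TSS distance ≤ 500 nt, and bodies extending away from the shared
midpoint (plus-strand TSS not 5′ of the minus-strand TSS) — the standard
bidirectional-eRNA geometry; convergent and tandem configurations are
rejected. Each transcript joins at most one pair, assigned greedily by
increasing TSS distance with lexicographic tie-breaks, so pairing is
deterministic. H3K27ac support means a peak intersecting the ±500 bp window
around **either** member TSS (the permissive reading of "the pair … whose
TSS overlapped"; an AND mode is available). The supporting peak recorded is
the highest-scoring hit. Induced loci are linked to the nearest responsive
gene when the locus midpoint lies within 300 kb of the gene span.

Every stage is non-increasing and the surviving transcript ids after each
stage are reported, so the elimination stage of any candidate is auditable.

## Superenhancer scoring

Peak calling is a transparent fold-enrichment caller (treatment vs control
coverage, ratio `(t+ε)/(c+ε)` with ε = 0.5 reads/bp by default, threshold
4×, evaluated on the exact step decomposition or on fixed-width tiles, then
gap-merged). Stitching merges peaks ≤ 12,500 bp apart (the ROSE
convention). Regions are ranked ascending by total signal; with both axes
scaled to [0, 1], the superenhancer boundary is the first point where the
curve's slope exceeds 1, and everything past it is flagged. A flat curve
yields no superenhancers; fewer than three regions leaves the boundary
undefined (all flagged non-SE, with a warning). The SE score is each
region's total signal divided by the maximum total signal, so scores are
invariant under uniform signal rescaling; the size of the peak universe the
normalization was computed over is carried as metadata rather than used as
a second divisor. Known limitation: any scaled-axes inflection rule is
sensitive at the low end of the curve — appending regions below the current
minimum rescales both axes and can shift the boundary, so SE flags are
meaningful for heavy-tailed signal distributions (a clear outlier
structure), not for near-uniform signals.

The top-k induced enhancer set removes superenhancers overlapping gene
spans, fills the remaining slots with the highest-scoring gene-free
traditional peaks, and rescores the combined set.

## RNAPII traveling ratio and profiles

The promoter-proximal window is TSS −30 to +300 **inclusive** (331 bp, in
transcription direction); the body is the rest of the gene body plus 1 kb
beyond the TES, starting immediately after the promoter window. The
statistic is log10(TSS density / body density), a scale-free quantity.
Isoforms shorter than the promoter window, or with zero density in either
window, are flagged excluded rather than raising or being imputed — this
mirrors the restriction to expressed isoforms (parent FPKM > 1) rather than
pseudocounting; a pseudocount mode is deliberately not the default.
Distribution comparisons use the two-sample KS statistic (exact empirical
CDF sweep) with the asymptotic Kolmogorov p-value on the effective sample
size. Metaprofiles average per-bin densities over TSS anchors (default
flank 2 kb, bin 50 bp), mirroring minus-strand anchors so profiles read
5′ → 3′.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
desk scale: by default 50 multi-exon genes on 2 × 3 Mb chromosomes with a
fixed 20 kb inter-gene spacing (so all gene pairs are ≥ 5 kb apart and the
±2 kb exclusion filter is decidable by construction), 20 planted divergent
eRNA pairs, and 5 decoys per class, each decoy violating exactly one eRNA
filter: spliced intergenic pairs; unspliced pairs 0.5–0.7 kb from a gene;
divergent pairs 501–5,000 nt apart; convergent/tandem pairs; and perfect
pairs with no H3K27ac peak. Decoy classes that must fail only their own
filter receive supporting peaks. Background peaks occupy a reserved zone at
each chromosome end. Each inter-gene gap hosts at most one planted item
with ≥ 2.5 kb clearance from flanking genes.

Expression: baseline FPKM is log-normal (genes: median 10; eRNA loci:
median 1.5). Responsive genes are induced by `2 + LogNormal(1.0, 0.5)` (so
fold > 2 by construction of the support) and planted eRNA loci by
`1.6 + LogNormal(1.0, 0.5)`; non-responsive features sit at fold 1. All
features receive multiplicative log-normal noise (σ = 0.15 by default;
0 gives the noise-free limit), drawn once per feature so perturbed arms
differ from control only through the perturbation itself. q-values are
Benjamini–Hochberg-adjusted p-values from a two-sided z-score on the log
fold change under the noise null — a stand-in for a DE estimator, which is
out of scope; under a null configuration the simulated tables are
calibrated (q < 0.05 fraction ≤ 0.05, tested over 100,000 features). A
perturbation scales the induced excess: fold′ = 1 + s·(fold − 1), so the
suppression factor s = 1 is the identity and s = 0 returns an affected gene
exactly to baseline (the setting at which the tiered rule's exact recovery
is well-defined — with partial suppression a noise-free q can never exceed
0.05 for a still-induced gene). Default perturbed arms: ERK/MEK-inhibitor
conditions suppressing 75 % of responsive genes to s = 0.2, and a knockdown
arm suppressing 70 % to s = 0.25, in line with the ~76–95 % affected
fractions this kind of experiment reports.

Coverage tracks plant a per-transcript pausing ratio r (log-uniform in
[2, 50] by default): the promoter window carries r × body density and the
body a constant density through TES + 1 kb, so the traveling-ratio
estimator should return log10 r exactly at zero background — the parameter
recovery the tests assert to ±0.05 (and 1e−9 for the uniform-track closed
form). An inhibitor-arm multiplier (default 3×) raises pausing genome-wide,
driving the KS separation between arms.

What the synthetic validation does **not** show: the generator has no read
sampling, sequence content, mappability structure, overlapping gene
architecture, or dispersion-driven DE uncertainty, so passing tests
establish the correctness of the decision rules and estimators, not their
robustness to alignment artefacts or count noise in real libraries.

## Determinism and problem sizes

Every random draw flows from `numpy` generators seeded by
`(seed, stream_id)`, so outputs are byte-identical under a fixed config and
seed — the pipeline manifest records per-stage SHA-256 digests and the
tests assert two independent runs agree file by file. Interrupted runs
resume from the per-stage state marker and produce outputs identical to an
uninterrupted run. The validation suite uses cohorts of 30–100 genes,
oracle sweeps of 1,000 random cases per primitive, 200-set property checks
for the superenhancer machinery, and 20 × 5,000-feature null tables —
sizes chosen so the full suite and the acceptance script each complete in
well under a minute on a laptop while keeping Monte-Carlo error far below
the asserted tolerances.
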