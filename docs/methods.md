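# Methods

This note records the models, conventions and numerical choices behind
epiweave, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Coordinates and window rules

All coordinates are 0-based half-open (BED convention) internally; the
per-cytosine report parser converts its 1-based positions at the boundary.
Overlap means ≥ 1 shared base on the same chromosome — there is no
minimum-fraction rule anywhere.

A gene's TSS is its first transcribed base (`span.start` on +, `span.end−1`
on −). The promoter is the 2 kb upstream of the TSS by default
(`promoter_upstream_bp = 2000`, `promoter_downstream_bp = 0`); the
symmetric ±2 kb reading is available by setting the downstream length. On
the − strand the promoter is the reflection of the + strand interval about
the TSS coordinate. TSS windows `[tss − w, tss + w + 1)` are symmetric and
strand-independent; "within N kb" is therefore inclusive at exactly N kb.
Gene annotation windows default to w = 100 kb; enhancer→gene links in the
hypo-methylated-enhancer analysis use w = 50 kb. Both widths share one code
path (`tss_window` / `link_enhancers_to_genes`).

Location classification is a strict precedence: gene_body (overlaps any
gene span) > promoter (overlaps any promoter interval) > intergenic
(linked to every gene whose ±100 kb TSS window it overlaps, possibly
none). Every feature receives exactly one label; results are invariant to
the ordering of genes and features (interval trees index the gene set;
per-base brute-force oracles in the test suite check the same queries).

## DMR calling

Candidate regions are maximal runs of CpGs covered (total reads > 0) in
both groups with inter-CpG distance ≤ `max_gap_bp` (default 300 bp, a
common segmentation default); runs of fewer than `min_cpg = 5` sites are
dropped. Replicates within a group are pooled by summing counts per site
before segmentation — per-replicate dispersion modelling is out of scope.
Only the CpG context is analysed; the parser accepts CHG/CHH rows and
filters them by a context flag.

Per candidate, methylated/unmethylated read counts are pooled across sites
into one 2×2 table per group and tested with a two-sided Fisher exact test
(scipy). The criteria name a Fisher test per region without fixing its
table; pooling raw counts is the simplest faithful construction and is the
documented choice. Mean methylation levels are means of per-site levels
(zero-coverage sites excluded); fold change is the larger mean over the
smaller, two-sided, so hypo- and hyper-methylation are called
symmetrically. If one group's mean level is 0 and the other's positive the
fold is infinite and passes the ≥ 2-fold gate; if both are 0 there is no
call. A region is a DMR when fold ≥ `min_fold = 2` and P ≤ `alpha = 0.05`;
Benjamini–Hochberg q-values are computed over all *tested* candidates
(before the fold/alpha filter), and q ≤ `q_threshold = 0.05` defines the
significant set used downstream.

Merging: consecutive same-direction DMRs on one chromosome are joined into
one continuous region when every tested candidate lying between them was
itself called — i.e. the whole stretch is differentially methylated. The
merged statistics are recomputed from the pooled counts (levels are
n_CpG-weighted means; the merged q is the members' minimum, a deliberate
convenience since BH is not re-run post hoc). The operation is idempotent.
The precise meaning of "adjacent" is not fixed by the criteria; this rule
is our documented reading.

## Active enhancers and differential features

An enhancer is each OCR overlapping ≥ 1 H3K27ac peak of the same condition
and no promoter interval. The reported interval is the whole OCR (the
OCR∩K27ac intersection hull is available via `interval_mode`). Conditions
are processed independently; the union of two conditions' peak sets is
never formed. Differential OCR/histone calling is not reimplemented —
differential-feature tables (region, assay, gain/loss, FDR, genes) are
inputs, filtered at FDR ≤ 0.01 when marks are assembled.

## Differential expression

Upregulated: linear FC ≥ 4 and FDR ≤ 0.01. Downregulated: log₂FC < 0 and
FDR ≤ 0.01 by default. The asymmetry (a 4-fold gain required up, any
significant negative change down) matches the operational usage of the
162-up/76-down gene sets in the downstream contingency analyses; a
symmetric option (FC ≤ 1/4) exists. The stated down-rule "FC ≤ 0" is only
meaningful on the log scale, which is how it is implemented. The curated
46-gene panel is user-supplied (`read_panel`); no panel ships with the
package because the exact list is not reproducible from the available
material — substitute the real list as one gene id per line.

## Contingency statistics

`chi_square_2x2` is Pearson's χ², df = 1, **without** Yates continuity
correction by default. The one-sided P is two-sided/2 when the top-left
cell exceeds its expectation (enrichment of the mark among upregulated
genes), else 1 − two-sided/2. This convention, applied to the six
verifiable published tables, reproduces the printed values (0.0135,
0.0327, 0.0976, 0.0008, 0.0034, 0.0002) to printed precision, which
two-sided and Yates-corrected variants do not; both sidednesses are always
reported, and the correction is available as a flag. A zero margin is an
error (statistic undefined) and surfaces as NA in association reports.

The one-sided χ² P is an asymptotic approximation to the fixed-margins
randomization mid-P (P(A > a) + ½P(A = a) under the hypergeometric null).
The agreement is within Monte-Carlo noise when expected cell counts are
moderate (≳ 15); for small sparse tables the discrete exact null deviates
from the asymptotic value by up to ~0.01 — in that regime `fisher_2x2`
(exact, minimum-likelihood two-sided rule) is the robust alternative and
is verified against an exhaustive enumeration oracle. Odds ratios are
reported plain (∞ on a zero cell) together with the Haldane–Anscombe
(+0.5) estimate.

Group rules (hypo = any compartment hypo-methylation, ocr = differential
OCR gain, k27 = H3K27ac gain): Group 1 = hypo∧ocr∧k27, Group 2 =
hypo∧k27∧¬ocr, Group 3 = hypo∧ocr∧¬k27, Group 4 = hypo only, ungrouped =
¬hypo. The rules are exhaustive and mutually exclusive, so labels
partition the gene set. The modification burden collapses the mark columns
to four types (methylation, accessibility, H3K27ac, H3K4me3) and counts
0–4 per gene.

Two published contingency P values (0.0004 and 0.0187, from the
H3K4me3-vs-expression donut analysis) could not be reverse-engineered from
the printed counts under any of the one/two-sided χ²/Fisher constructions
tried; they are excluded from verification.

## Clonotypes

Clonotype identity is exact equality of (αV, αJ, αCDR3, βV, βJ, βCDR3)
with CDR3 compared at the nucleotide level by default (strictest); an
amino-acid mode collapses synonymous rearrangements. Cells with more than
one productive chain at a locus are excluded with a reported count — the
repertoire model is one αβ pair per cell. Cross-cluster "twins" are
reported both within a treatment arm (default) and across arms, since
either reading is defensible; singletons are never shared.

## Synthetic data

The generators are pure functions of (config, seed) — repeated runs are
byte-identical — and emit exactly the dialects the pipeline parses, plus a
JSON truth manifest sufficient to score every caller.

*Genome*: non-overlapping gene spans (2–8 kb) on both strands, gaps
2–12 kb, 600 genes over 4 × 2 Mb chromosomes by default.

*Methylome*: coverage is Poisson (mean 100 reads), methylated counts
Binomial(coverage, level), baseline levels Beta(8, 2) clipped to
[0.05, 0.98] — the simplest generative family matching bisulfite count
structure. CpGs sit in discrete islands (8 sites 50 bp apart) separated by
more than the segmentation gap, so each island is one candidate region; a
uniformly spaced CpG lattice would merge whole chromosomes into single
candidates and is not how CpG islands occur. Each gene carries a
same-level background island; planted effect islands divide the treated
(hypo) or control (hyper) level by `effect_fold = 4`.

*Association*: an upregulated gene carries a gene-body hypo island with
probability p₁ and a down/unchanged gene with p₀ = 0.08, where the odds
ratio (p₁/(1−p₁))/(p₀/(1−p₀)) = θ = 6. Both values come from the studied
comparison's own margins (6/76 ≈ 8% baseline; 55/162 vs 6/76 is an odds
ratio of ≈ 6), with 162 up and 76 down genes. θ acts on gene-body
hypo-methylation only; promoter (2%) and intergenic (5%) hypo rates and
the hyper rate (5%) are class-independent (odds ratio 1), serving as
negative controls in the association report.

*Peaks/DE*: gene-body OCR+K27ac pairs (density 0.6) are shared between
conditions with treatment gains on up genes (0.15) and losses on down
genes (0.10); intergenic pairs (0.3, space permitting) and
promoter-straddling decoy pairs (0.3) exercise the compartment and
exclusion rules. Differential features follow a per-class mark-rate table
scaled to the studied comparison's order of magnitude. DE fold changes and
FDRs are drawn inside the class-defining regions, so threshold
classification recovers the intended classes exactly.

*Repertoire*: the default composition is 325 singleton clonotypes, two
5-cell groups (treated arm, sub-cluster 4) and four 2-cell groups (one
spanning control clusters 2 and 4) — 343 productive-paired cells across
181 control and 162 treated — plus 185 cells lacking a productive pair
(528 total). V/J elements are filled by deterministic quota (all but 10
singleton clonotypes use TRAV11/TRAJ18; β V counts 196/35/18 for
TRBV13-2/TRBV13-1/TRBV1), so the usage and composition percentages are
properties of the configured composition, not of sampling noise; CDR3
nucleotide strings are seeded-random and unique per clonotype.

What the generators do **not** emulate: read-level data (FASTQ),
spatial autocorrelation of chromatin state, replicate-level biological
dispersion, CpG-density heterogeneity along real genomes, somatic
hypermutation-like CDR3 length biases. Passing recovery tests therefore
demonstrates correctness of the calling and integration logic under the
stated generative model, not performance on real libraries with batch
effects or uneven coverage.

## Problem sizes and determinism

The default study (600 genes, ~17,000 CpG sites per group, ~900 peaks,
528 cells) runs the full chain in about two seconds; the acceptance script
(including 100 odds-ratio-recovery and 1,000 type-I-error replicates at
the truth level, and a doubled end-to-end determinism run) takes under ten
seconds on one CPU. These sizes were chosen so the planted-truth recovery
checks are statistically meaningful (≥ 100 planted regions, binomial SEs
small relative to the tested margins) while the whole suite stays
interactive. All randomness flows through `numpy.random.default_rng`
seeded from the config; outputs are byte-identical across reruns.

## Known limitations

- Region-level Fisher on pooled counts treats reads as independent across
  sites within a region; within-region correlation of methylation state is
  ignored (as is common for count-pooling callers).
- BH is applied once over all tested candidates; the merge step does not
  re-run the multiplicity correction.
- The intergenic linking rule attaches a feature to *every* gene whose
  window covers it, so in dense gene neighbourhoods intergenic marks
  spread to many genes; this mirrors the window-annotation convention but
  inflates per-gene mark prevalence relative to nearest-gene assignment.
- Enhancer "presence" marks (`enhancer_pre`/`enhancer_post`) use the
  ±100 kb annotation window and are typically near-saturating; they are
  carried for completeness, and their association report is NA when a
  margin is degenerate.
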