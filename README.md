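# epiweave

Multi-omic epigenetic integration for studies of T-cell reprogramming:
differentially methylated region (DMR) calling from whole-genome bisulfite
counts, active-enhancer prediction from open-chromatin + H3K27ac peak sets,
window-based feature-to-gene annotation, mark–expression association
statistics, epigenetic group classification, and paired-chain TCR clonotype
analysis — with seeded synthetic-data generators that plant a known truth
for every step.

The package is written for computational immunologists and epigenomicists
who have peak sets, per-cytosine bisulfite counts, differential-expression
tables and per-cell TCR reconstructions in hand (alignment, peak calling
and differential-binding fits are upstream, external steps) and want a
tested, deterministic integration layer over them.

## The statistics at the core

**DMR calling.** Methylation level at a cytosine is m/n: methylated read
count over total coverage. Candidate regions are maximal runs of CpGs
covered in both groups with inter-CpG gaps ≤ 300 bp. A candidate is a DMR
when it has ≥ 5 covered CpGs, the group mean levels differ ≥ 2-fold, and a
two-sided Fisher exact test on the pooled 2×2 count table (methylated vs
unmethylated × control vs treated) gives P ≤ 0.05; Benjamini–Hochberg
q ≤ 0.05 defines the significant set. Adjacent same-direction DMRs with no
intervening failed candidate are joined.

**Active enhancers.** An open chromatin region (OCR) that overlaps ≥ 1
H3K27ac peak and no promoter (2 kb upstream of a TSS) is an active
enhancer; it is genic if it overlaps a gene span, else intergenic, and is
annotated to genes whose ±100 kb TSS window it overlaps (±50 kb for the
hypo-methylated-enhancer analysis).

**Mark–expression association.** For each epigenetic mark, genes classified
as upregulated (FC ≥ 4, FDR ≤ 0.01) and downregulated (log₂FC < 0,
FDR ≤ 0.01) form the 2×2 table [[up∧mark, up∧¬mark], [down∧mark,
down∧¬mark]], tested by Pearson χ² (df = 1, no continuity correction); the
one-sided P is χ²-P/2 in the observed direction. Genes are then classified
into Group 1 (hypo-methylated + differential OCR + H3K27ac gain), Group 2
(hypo + K27ac, no OCR), Group 3 (hypo + OCR, no K27ac), Group 4 (hypo
only), or ungrouped.

**Clonotypes.** Cells with exactly one productive TCRα and TCRβ chain are
grouped by exact identity of (αV, αJ, αCDR3nt, βV, βJ, βCDR3nt); summaries
cover the clonal-group size spectrum, V/J usage, and clonotypes spanning
more than one transcriptional sub-cluster.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted truth:

```sh
python analysis/01_simulate_study.py        # writes results/study/
python analysis/02_call_dmrs.py
python analysis/03_call_enhancers.py
python analysis/04_integrate_marks.py
python analysis/05_clonotypes.py
```

With the default seed the drivers print:

```
called 162 significant DMRs (136 hypo, 26 hyper)
compartments: {'gene_body': 127, 'promoter': 13, 'intergenic': 22}
sensitivity vs truth: 166/166 (100.0%), direction correct for 166/166
```

— every planted region (treated level = control/4 at 100× coverage) is
recovered with the right direction;

```
pre-treatment: 462 active enhancers — 373 (80.74%) in gene bodies ...
post-treatment enhancers overlapping hypo-methylated DMRs: 66/471 (14.01%)
```

— the enhancer rule, compartment partition and DMR colocalization;

```
              mark  up_count  up_total  down_count  down_total  p_one_sided  odds_ratio
    hypo_gene_body        61       162           9          76     0.000023    4.496150
```

— the planted gene-body hypo-methylation ↔ upregulation association
(odds ratio 6 by design) is detected, while class-independent marks
(promoter, intergenic, hyper-methylation) stay non-significant; and

```
331 clonotypes; size spectrum {1: 325, 2: 4, 5: 2}
singleton cells: 94.75%
TRAV11/TRAJ18 alpha usage: 333/343 (97.08%)
```

— the repertoire composition pushed through the clonotype chain.

The same pipeline runs from the command line (`epiweave simulate`,
`epiweave run-all --in <dir> --out <dir>`, `epiweave report`, plus
`call-dmrs`, `call-enhancers`, `annotate`, `integrate`, `clonotypes`
subcommands) or from Python via `epiweave.pipeline`.

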