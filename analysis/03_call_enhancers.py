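#!/usr/bin/env python
"""Predict active enhancers per condition and colocalize them with DMRs.

An active enhancer is an open chromatin region overlapping >= 1 H3K27ac
peak and no promoter (2 kb upstream of a TSS). Enhancers are partitioned
into gene-body vs intergenic compartments, linked to genes within a
+/- 100 kb TSS window, and the post-treatment set is flagged for overlap
with hypo-methylated DMRs; flagged enhancers are linked to genes within
+/- 50 kb. Requires 01 (study) and 02 (DMRs).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from epiweave import chromatin
from epiweave.intervals import AnnotationParams, GenomeIndex, GenomicInterval, read_gene_table
from epiweave.methylome import DMR

STUDY = Path("results/study")
OUT = Path("results/analysis")


def load_dmrs(path):
    df = pd.read_csv(path, sep="\t")
    return [
        DMR(region=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            n_cpg=int(r.n_cpg), level_control=r.level_control,
            level_treated=r.level_treated,
            fold_change=float("inf") if r.fold_change == "inf" else float(r.fold_change),
            direction=r.direction, p_value=r.p_value, q_value=r.q_value)
        for r in df.itertuples()
    ]


def main() -> None:
    if not (OUT / "dmrs.tsv").exists():
        sys.exit("run analysis/02_call_dmrs.py first")
    ann = AnnotationParams()
    genes = read_gene_table(STUDY / "genes.tsv")
    index = GenomeIndex(genes, ann)

    enhancers = {}
    for cond in ("pre", "post"):
        ocrs = chromatin.read_peaks(STUDY / f"ocr_{cond}.narrowPeak", "OCR")
        k27 = chromatin.read_peaks(STUDY / f"k27ac_{cond}.narrowPeak", "H3K27ac")
        enhancers[cond] = chromatin.call_active_enhancers(ocrs, k27, index, ann)
        counts = chromatin.partition_counts(enhancers[cond])
        print(f"{cond}-treatment: {counts['total']} active enhancers — "
              f"{counts['gene_body']} ({counts['gene_body_pct']}%) in gene bodies "
              f"(linked to {counts['gene_body_genes']} genes), "
              f"{counts['intergenic']} ({counts['intergenic_pct']}%) intergenic "
              f"(linked to {counts['intergenic_genes']} genes)")

    dmrs = load_dmrs(OUT / "dmrs.tsv")
    flagged, stats = chromatin.colocalize_enhancer_dmrs(enhancers["post"], dmrs)
    print(f"post-treatment enhancers overlapping hypo-methylated DMRs: "
          f"{stats['n_hypo_methylated']}/{stats['total']} "
          f"({100 * stats['fraction']:.2f}%)")
    hypo = [e for e in flagged if e.hypo_methylated]
    links = chromatin.link_enhancers_to_genes(hypo, genes, ann.enhancer_link_bp)
    print(f"hypo-methylated enhancers proximal (+/- 50 kb) to {len(links)} genes")
    chromatin.write_enhancer_bed(enhancers["pre"], OUT / "enhancers_pre.bed")
    chromatin.write_enhancer_bed(flagged, OUT / "enhancers_post.bed")


if __name__ == "__main__":
    main()
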