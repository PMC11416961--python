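#!/usr/bin/env python
"""Call differentially methylated regions and score them against the truth.

Reads the synthetic study from results/study/, calls DMRs (>= 5 covered
CpGs, >= 2-fold level change, pooled Fisher P <= 0.05, BH q <= 0.05),
merges adjacent same-direction regions, annotates each DMR to gene body /
promoter / intergenic compartments, and reports sensitivity and direction
accuracy against the planted manifest. Writes results/analysis/dmrs.{bed,tsv}.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from epiweave import methylome
from epiweave.intervals import read_gene_table

STUDY = Path("results/study")
OUT = Path("results/analysis")


def main() -> None:
    if not STUDY.exists():
        sys.exit("run analysis/01_simulate_study.py first")
    OUT.mkdir(parents=True, exist_ok=True)

    control = methylome.read_cpg_report(STUDY / "methylome_control.tsv")
    treated = methylome.read_cpg_report(STUDY / "methylome_treated.tsv")
    params = methylome.DmrParams()
    dmrs = methylome.call_dmrs(control, treated, params)
    dmrs = methylome.merge_adjacent_dmrs(dmrs, control, treated, params)
    significant = [d for d in dmrs if d.q_value <= params.q_threshold]
    genes = read_gene_table(STUDY / "genes.tsv")
    annotated = methylome.annotate_dmrs(significant, genes)
    methylome.write_dmr_bed(annotated, OUT / "dmrs.bed")
    methylome.write_dmr_table(annotated, OUT / "dmrs.tsv")

    with open(STUDY / "truth_manifest.json") as fh:
        truth = json.load(fh)["methylome"]["true_regions"]

    def hits(r):
        return [d for d in annotated
                if d.region.chrom == r["chrom"]
                and max(d.region.start, r["start"]) < min(d.region.end, r["end"])]

    detected = [r for r in truth if hits(r)]
    dir_ok = sum(all(d.direction == r["direction"] for d in hits(r)) for r in detected)
    print(f"called {len(annotated)} significant DMRs "
          f"({sum(d.direction == 'hypo' for d in annotated)} hypo, "
          f"{sum(d.direction == 'hyper' for d in annotated)} hyper)")
    by_loc = {loc: sum(d.location == loc for d in annotated)
              for loc in ("gene_body", "promoter", "intergenic")}
    print(f"compartments: {by_loc}")
    print(f"sensitivity vs truth: {len(detected)}/{len(truth)} "
          f"({100 * len(detected) / len(truth):.1f}%), "
          f"direction correct for {dir_ok}/{len(detected)}")


if __name__ == "__main__":
    main()
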