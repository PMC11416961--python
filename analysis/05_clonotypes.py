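#!/usr/bin/env python
"""Paired-chain clonotype analysis of the synthetic repertoire.

Filters to cells with exactly one productive TCRα and TCRβ chain, groups
them into clonotypes by the six-part (V, J, CDR3nt) x 2 key, and reports
the clonal-group size spectrum, the singleton cell fraction, TRAV11/TRAJ18
usage, and clonotypes spanning more than one transcriptional sub-cluster.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from epiweave import clonotypes as clono

STUDY = Path("results/study")


def main() -> None:
    if not STUDY.exists():
        sys.exit("run analysis/01_simulate_study.py first")
    cells = clono.read_tcr_table(STUDY / "tcr_cells.tsv")
    paired, stats = clono.filter_productive_paired(cells)
    print(f"{stats['n_retained']}/{stats['n_input']} cells have exactly one "
          f"productive alpha-beta pair")
    cts = clono.assign_clonotypes(paired)
    s = clono.clonal_summary(cts)
    print(f"{s['n_clonotypes']} clonotypes; size spectrum {s['size_spectrum']}")
    print(f"singleton cells: {100 * s['singleton_cell_fraction']:.2f}%")
    for size, frac in s["cell_fraction_by_size"].items():
        if size > 1:
            print(f"  cells in {size}-cell clonal groups: {100 * frac:.2f}%")
    usage = clono.vj_usage(paired, "alpha", "TRAV11", "TRAJ18")
    print(f"TRAV11/TRAJ18 alpha usage: {usage['count']}/{usage['total']} "
          f"({usage['pct']}%)")
    _, shared = clono.cross_cluster_sharing(cts)
    print(f"clonal groups spanning >1 sub-cluster within a treatment arm: {len(shared)}")
    for ct in shared:
        clusters = ", ".join(f"{t} cluster {c}" for t, c in sorted(ct.clusters_present))
        print(f"  size {ct.size}: {clusters}")


if __name__ == "__main__":
    main()
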