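"""Paired-chain TCR clonotype grouping and clonal-structure summaries.

Cells with exactly one productive TCRα and one productive TCRβ chain are
grouped into clonotypes by exact identity of the six-part key
(αV, αJ, αCDR3, βV, βJ, βCDR3); CDR3 identity is at the nucleotide level
by default, with an amino-acid mode available. Summaries cover the
clonal-group size spectrum, V/J element usage, and clonotype "twins"
spanning more than one transcriptional sub-cluster.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TCRChain",
    "TCRCell",
    "Clonotype",
    "read_tcr_table",
    "write_tcr_table",
    "filter_productive_paired",
    "assign_clonotypes",
    "clonal_summary",
    "vj_usage",
    "cross_cluster_sharing",
]


@dataclass(frozen=True)
class TCRChain:
    locus: str  # 'alpha' | 'beta'
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str = ""
    productive: bool = True

    def __post_init__(self) -> None:
        if self.locus not in ("alpha", "beta"):
            raise ValueError("locus must be 'alpha' or 'beta'")
        if self.cdr3_nt and self.cdr3_aa and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValueError(
                f"cdr3_nt length {len(self.cdr3_nt)} inconsistent with "
                f"cdr3_aa length {len(self.cdr3_aa)}"
            )


@dataclass(frozen=True)
class TCRCell:
    cell_id: str
    treatment: str  # 'control' | 'treated'
    cluster: str
    chains: tuple[TCRChain, ...]

    def chains_at(self, locus: str, productive_only: bool = True) -> list[TCRChain]:
        return [
            c for c in self.chains
            if c.locus == locus and (c.productive or not productive_only)
        ]


@dataclass
class Clonotype:
    key: tuple[str, str, str, str, str, str]
    member_cells: list[TCRCell] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_cells)

    @property
    def clusters_present(self) -> set[tuple[str, str]]:
        """(treatment, cluster) pairs of the member cells."""
        return {(c.treatment, c.cluster) for c in self.member_cells}


_TCR_COLUMNS = [
    "cell_id", "treatment", "cluster",
    "alpha_v", "alpha_j", "alpha_cdr3_nt", "alpha_productive",
    "beta_v", "beta_j", "beta_cdr3_nt", "beta_productive",
]


def read_tcr_table(path) -> list[TCRCell]:
    """Read the per-cell TCR TSV (one row per cell, header required).

    Empty chain fields denote a missing chain; a duplicated cell_id raises.
    """
    cells: list[TCRCell] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in _TCR_COLUMNS if c not in col]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            cell_id = f[col["cell_id"]]
            if cell_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate cell_id {cell_id!r}")
            seen.add(cell_id)
            chains = []
            for locus in ("alpha", "beta"):
                v = f[col[f"{locus}_v"]]
                if not v:
                    continue
                chains.append(
                    TCRChain(
                        locus=locus,
                        v_gene=v,
                        j_gene=f[col[f"{locus}_j"]],
                        cdr3_nt=f[col[f"{locus}_cdr3_nt"]],
                        productive=f[col[f"{locus}_productive"]].lower()
                        in ("1", "true", "yes"),
                    )
                )
            cells.append(
                TCRCell(cell_id, f[col["treatment"]], f[col["cluster"]], tuple(chains))
            )
    return cells


def write_tcr_table(cells: Iterable[TCRCell], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TCR_COLUMNS) + "\n")
        for cell in cells:
            row = [cell.cell_id, cell.treatment, cell.cluster]
            for locus in ("alpha", "beta"):
                chains = cell.chains_at(locus, productive_only=False)
                if chains:
                    c = chains[0]
                    row += [c.v_gene, c.j_gene, c.cdr3_nt, str(int(c.productive))]
                else:
                    row += ["", "", "", ""]
            fh.write("\t".join(row) + "\n")


def filter_productive_paired(cells: Sequence[TCRCell]) -> tuple[list[TCRCell], dict]:
    """Keep cells with exactly one productive α and one productive β chain.

    Cells with more than one productive chain at a locus are excluded (their
    count is reported); the paired repertoire carries one αβ pair per cell.
    """
    kept: list[TCRCell] = []
    n_multi = 0
    for cell in cells:
        alpha = cell.chains_at("alpha")
        beta = cell.chains_at("beta")
        if len(alpha) == 1 and len(beta) == 1:
            kept.append(cell)
        elif len(alpha) > 1 or len(beta) > 1:
            n_multi += 1
    return kept, {
        "n_input": len(cells),
        "n_retained": len(kept),
        "n_multi_chain_excluded": n_multi,
    }


def _clonotype_key(cell: TCRCell, level: str) -> tuple[str, str, str, str, str, str]:
    a = cell.chains_at("alpha")[0]
    b = cell.chains_at("beta")[0]
    if level == "nt":
        return (a.v_gene, a.j_gene, a.cdr3_nt, b.v_gene, b.j_gene, b.cdr3_nt)
    return (a.v_gene, a.j_gene, a.cdr3_aa, b.v_gene, b.j_gene, b.cdr3_aa)


def assign_clonotypes(cells: Sequence[TCRCell], level: str = "nt") -> list[Clonotype]:
    """Partition productive-paired cells by exact six-part key equality.

    ``level`` selects nucleotide (default) or amino-acid CDR3 comparison.
    The result is sorted by descending size then key, so it is invariant to
    the input cell order.
    """
    if level not in ("nt", "aa"):
        raise ValueError("level must be 'nt' or 'aa'")
    groups: dict[tuple, list[TCRCell]] = defaultdict(list)
    for cell in cells:
        groups[_clonotype_key(cell, level)].append(cell)
    clonotypes = [
        Clonotype(key, sorted(members, key=lambda c: c.cell_id))
        for key, members in groups.items()
    ]
    clonotypes.sort(key=lambda ct: (-ct.size, ct.key))
    return clonotypes


def clonal_summary(clonotypes: Sequence[Clonotype]) -> dict:
    """Clonal-structure summary: singleton fraction and size spectrum.

    ``singleton_cell_fraction`` is the fraction of CELLS sitting in size-1
    clonotypes; ``size_spectrum`` maps group size -> number of clonotypes;
    ``cell_fraction_by_size`` maps size -> fraction of cells in groups of
    that size (fractions sum to 1).
    """
    n_cells = sum(ct.size for ct in clonotypes)
    spectrum = Counter(ct.size for ct in clonotypes)
    by_size = {
        size: (size * count) / n_cells if n_cells else 0.0
        for size, count in sorted(spectrum.items())
    }
    return {
        "n_cells": n_cells,
        "n_clonotypes": len(clonotypes),
        "singleton_cell_fraction": by_size.get(1, 0.0),
        "size_spectrum": dict(sorted(spectrum.items())),
        "cell_fraction_by_size": by_size,
    }


def vj_usage(cells: Sequence[TCRCell], locus: str, v_gene: str, j_gene: str) -> dict:
    """Fraction of cells whose productive chain at ``locus`` uses both elements."""
    total = len(cells)
    count = sum(
        1
        for cell in cells
        for c in cell.chains_at(locus)[:1]
        if c.v_gene == v_gene and c.j_gene == j_gene
    )
    return {
        "count": count,
        "total": total,
        "fraction": count / total if total else 0.0,
        "pct": round(100.0 * count / total, 2) if total else 0.0,
    }


def cross_cluster_sharing(
    clonotypes: Sequence[Clonotype], within_treatment: bool = True
) -> tuple[dict, list[Clonotype]]:
    """Incidence of clonotypes across (treatment, cluster) cells and the
    clonotypes spanning more than one sub-cluster.

    With ``within_treatment`` a clonotype is shared when its members span
    >1 cluster inside a single treatment arm; otherwise clusters are
    compared across arms as well. Singletons are never shared.
    """
    incidence: dict[tuple, Counter] = {}
    shared: list[Clonotype] = []
    for ct in clonotypes:
        incidence[ct.key] = Counter((c.treatment, c.cluster) for c in ct.member_cells)
        if ct.size < 2:
            continue
        if within_treatment:
            arms: dict[str, set[str]] = defaultdict(set)
            for c in ct.member_cells:
                arms[c.treatment].add(c.cluster)
            if any(len(clusters) > 1 for clusters in arms.values()):
                shared.append(ct)
        else:
            if len({c.cluster for c in ct.member_cells}) > 1:
                shared.append(ct)
    return incidence, shared
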