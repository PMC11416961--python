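"""Per-gene epigenetic mark matrix and mark-expression association statistics.

The central object is a boolean gene x mark matrix recording, per gene,
which epigenetic changes (hypo-/hyper-methylation by compartment,
differential chromatin accessibility, H3K27ac and H3K4me3 gains/losses,
active-enhancer presence per condition, hypo-methylated proximal enhancers)
link to it, together with its differential-expression class. Association
between a mark and up- vs downregulation is tested on the 2x2 table

    [[up & mark,   up & not mark],
     [down & mark, down & not mark]]

with Pearson chi-square (no continuity correction). The one-sided P is
two-sided/2 when the observed association direction matches the tested
direction (enrichment of the mark among upregulated genes), else
1 - two-sided/2. Fisher's exact test is offered as a robustness
alternative. Genes are further classified into four epigenetic groups by
which combination of hypo-methylation, differential open chromatin and
H3K27ac gain they carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .chromatin import ActiveEnhancer, DiffFeature
from .expression import DERecord
from .methylome import DMR

__all__ = [
    "MARK_COLUMNS",
    "MODIFICATION_TYPES",
    "ContingencyResult",
    "chi_square_2x2",
    "fisher_2x2",
    "build_mark_matrix",
    "association_report",
    "epigenetic_group",
    "assign_groups",
    "mark_weight_tally",
    "modification_burden",
]

MARK_COLUMNS = (
    "hypo_gene_body",
    "hypo_promoter",
    "hypo_intergenic",
    "hyper_gene_body",
    "hyper_promoter",
    "hyper_intergenic",
    "diff_ocr_gain",
    "k27ac_gain",
    "k27ac_loss",
    "k4me3_gain",
    "k4me3_loss",
    "enhancer_pre",
    "enhancer_post",
    "hypo_enhancer_50kb",
)

# type-level collapse used by the modification-burden count (order matters
# for reporting): methylation, chromatin accessibility, H3K27ac, H3K4me3
MODIFICATION_TYPES = {
    "methylation": (
        "hypo_gene_body", "hypo_promoter", "hypo_intergenic",
        "hyper_gene_body", "hyper_promoter", "hyper_intergenic",
    ),
    "accessibility": ("diff_ocr_gain",),
    "H3K27ac": ("k27ac_gain", "k27ac_loss"),
    "H3K4me3": ("k4me3_gain", "k4me3_loss"),
}


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p_two_sided: float
    p_one_sided: float
    odds_ratio: float  # inf allowed at zero cells
    odds_ratio_haldane: float  # Haldane-Anscombe +0.5 estimate
    direction_positive: bool


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("cells must be non-negative")
    return arr


def _odds_ratios(arr: np.ndarray) -> tuple[float, float]:
    a, b, c, d = arr.ravel()
    if b * c == 0:
        plain = math.inf if a * d > 0 else math.nan
    else:
        plain = (a * d) / (b * c)
    hald = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return plain, hald


def chi_square_2x2(table, sided: str = "two", correction: bool = False) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction
    by default.

    One-sided convention: P = two-sided/2 when the first-row/first-column
    cell exceeds its expectation (positive association), else
    1 - two-sided/2. Raises on a zero margin (statistic undefined).
    """
    arr = _validate_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square statistic undefined")
    chi2, p_two, _, expected = chi2_contingency(arr, correction=correction)
    positive = arr[0, 0] > expected[0, 0]
    p_one = p_two / 2 if positive else 1 - p_two / 2
    plain, hald = _odds_ratios(arr)
    res = ContingencyResult(
        table=tuple(tuple(int(x) for x in row) for row in arr),
        chi2=float(chi2),
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        odds_ratio=plain,
        odds_ratio_haldane=hald,
        direction_positive=bool(positive),
    )
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    return res


def fisher_2x2(table, sided: str = "two") -> ContingencyResult:
    """Fisher's exact test (two-sided by the minimum-likelihood rule;
    one-sided reported with the same direction convention as chi-square)."""
    arr = _validate_table(table).astype(int)
    _, p_two = fisher_exact(arr, alternative="two-sided")
    n = arr.sum()
    expected_a = arr[0].sum() * arr[:, 0].sum() / n if n else 0.0
    positive = arr[0, 0] > expected_a
    _, p_greater = fisher_exact(arr, alternative="greater")
    _, p_less = fisher_exact(arr, alternative="less")
    p_one = p_greater if positive else p_less
    plain, hald = _odds_ratios(arr.astype(float))
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    return ContingencyResult(
        table=tuple(tuple(int(x) for x in row) for row in arr),
        chi2=math.nan,
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        odds_ratio=plain,
        odds_ratio_haldane=hald,
        direction_positive=bool(positive),
    )


def build_mark_matrix(
    gene_universe: Sequence[str],
    annotated_dmrs: Sequence[DMR] = (),
    diff_features: Sequence[DiffFeature] = (),
    enhancers_pre: Sequence[ActiveEnhancer] = (),
    enhancers_post: Sequence[ActiveEnhancer] = (),
    hypo_enhancer_links: Mapping[str, Sequence[ActiveEnhancer]] | None = None,
    de_records: Sequence[DERecord] = (),
    diff_fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Assemble the boolean gene x mark matrix plus a de_class column.

    A gene's mark is True iff at least one qualifying feature links to it:
    annotated DMRs set the hypo_/hyper_ compartment marks; differential
    features with FDR <= ``diff_fdr_max`` set the assay gain/loss marks;
    enhancer sets per condition set enhancer_pre/enhancer_post; the
    50 kb hypo-enhancer link map sets hypo_enhancer_50kb. Any feature
    linking a gene outside the universe raises KeyError.
    """
    genes = list(gene_universe)
    if len(set(genes)) != len(genes):
        raise ValueError("gene universe contains duplicates")
    idx = pd.Index(genes, name="gene_id")
    m = pd.DataFrame(False, index=idx, columns=list(MARK_COLUMNS))

    def set_mark(gene_id: str, col: str) -> None:
        if gene_id not in m.index:
            raise KeyError(f"gene {gene_id!r} not in the gene universe")
        m.loc[gene_id, col] = True

    for d in annotated_dmrs:
        if d.location not in ("gene_body", "promoter", "intergenic"):
            raise ValueError("DMRs must be annotated before matrix assembly")
        col = f"{d.direction}_{d.location}"
        for g in d.linked_genes:
            set_mark(g, col)

    assay_col = {"OCR": "diff_ocr", "H3K27ac": "k27ac", "H3K4me3": "k4me3"}
    for f in diff_features:
        if f.fdr > diff_fdr_max:
            continue
        base = assay_col[f.assay]
        col = f"{base}_{'gain' if f.fold_change_sign == 'gain' else 'loss'}"
        if col == "diff_ocr_loss":
            continue  # only accessibility gains are tracked as a mark
        for g in f.linked_genes:
            set_mark(g, col)

    for e in enhancers_pre:
        for g in e.linked_genes:
            set_mark(g, "enhancer_pre")
    for e in enhancers_post:
        for g in e.linked_genes:
            set_mark(g, "enhancer_post")

    for g in (hypo_enhancer_links or {}):
        if hypo_enhancer_links[g]:
            set_mark(g, "hypo_enhancer_50kb")

    de_class = pd.Series("unchanged", index=idx)
    for r in de_records:
        if r.gene_id not in m.index:
            raise KeyError(f"gene {r.gene_id!r} not in the gene universe")
        de_class[r.gene_id] = r.de_class or "unchanged"
    m["de_class"] = de_class
    return m


def association_report(
    matrix: pd.DataFrame, mark_name: str, test: str = "chi2"
) -> dict:
    """Mark prevalence among up- vs downregulated genes plus the 2x2 test.

    Returns counts, percentages (2 decimals), and the ContingencyResult
    (None, with P reported as NaN, when a margin is zero).
    """
    if mark_name not in MARK_COLUMNS:
        raise KeyError(f"unknown mark {mark_name!r}")
    up = matrix[matrix["de_class"] == "up"]
    down = matrix[matrix["de_class"] == "down"]
    a = int(up[mark_name].sum())
    b = len(up) - a
    c = int(down[mark_name].sum())
    d = len(down) - c
    table = [[a, b], [c, d]]
    try:
        result = (fisher_2x2 if test == "fisher" else chi_square_2x2)(table)
    except ValueError:
        result = None
    return {
        "mark": mark_name,
        "up_count": a,
        "up_total": len(up),
        "down_count": c,
        "down_total": len(down),
        "up_pct": round(100.0 * a / len(up), 2) if len(up) else 0.0,
        "down_pct": round(100.0 * c / len(down), 2) if len(down) else 0.0,
        "table": table,
        "result": result,
        "p_one_sided": result.p_one_sided if result else math.nan,
        "p_two_sided": result.p_two_sided if result else math.nan,
        "odds_ratio": result.odds_ratio if result else math.nan,
    }


def epigenetic_group(gene_row: Mapping[str, bool]) -> str:
    """Classify one gene row into Group1-4 or ungrouped.

    hypo = any compartment hypo-methylation; ocr = differential open
    chromatin gain; k27 = H3K27ac gain. Group1: all three; Group2: hypo and
    K27ac without OCR; Group3: hypo and OCR without K27ac; Group4: hypo
    only; ungrouped: not hypo-methylated. Exhaustive and mutually exclusive.
    """
    hypo = bool(
        gene_row["hypo_gene_body"]
        or gene_row["hypo_promoter"]
        or gene_row["hypo_intergenic"]
    )
    ocr = bool(gene_row["diff_ocr_gain"])
    k27 = bool(gene_row["k27ac_gain"])
    if not hypo:
        return "ungrouped"
    if ocr and k27:
        return "Group1"
    if k27:
        return "Group2"
    if ocr:
        return "Group3"
    return "Group4"


def assign_groups(matrix: pd.DataFrame) -> pd.Series:
    """Group label per gene (vectorised epigenetic_group)."""
    return matrix.apply(epigenetic_group, axis=1).rename("group")


def mark_weight_tally(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-mark counts among up- and among downregulated genes.

    The tidy (mark, up_count, down_count) table behind a radar plot of the
    relative weight of each epigenetic mark.
    """
    up = matrix[matrix["de_class"] == "up"]
    down = matrix[matrix["de_class"] == "down"]
    rows = [
        {
            "mark": mark,
            "up_count": int(up[mark].sum()),
            "down_count": int(down[mark].sum()),
        }
        for mark in MARK_COLUMNS
    ]
    return pd.DataFrame(rows)


def modification_burden(matrix: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Count per gene how many of the 4 modification TYPES it carries.

    Types are methylation (any direction/compartment), chromatin
    accessibility, H3K27ac and H3K4me3 (either direction). Returns the
    0-4 count per gene and a histogram per DE class with absolute counts
    and within-class percentages (summing to 100 per class).
    """
    counts = pd.Series(0, index=matrix.index, name="burden")
    for cols in MODIFICATION_TYPES.values():
        counts += matrix[list(cols)].any(axis=1).astype(int)

    rows = []
    for cls, grp in matrix.groupby("de_class", sort=True):
        sub = counts.loc[grp.index]
        total = len(sub)
        for k in range(5):
            n = int((sub == k).sum())
            rows.append(
                {
                    "de_class": cls,
                    "n_types": k,
                    "n_genes": n,
                    "pct": round(100.0 * n / total, 2) if total else 0.0,
                }
            )
    return counts, pd.DataFrame(rows)
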