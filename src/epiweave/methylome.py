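"""Bisulfite count handling and differentially methylated region (DMR) calling.

The caller follows explicit region criteria: a candidate region is a run of
CpGs covered in both groups; it is a DMR when it holds at least ``min_cpg``
sites, the mean methylation level changes at least ``min_fold``-fold between
groups, and a Fisher exact test on the pooled read counts gives
P <= ``alpha``. Benjamini-Hochberg q-values are computed across all tested
candidates; the significant set uses q <= ``q_threshold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .intervals import (
    AnnotationParams,
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    classify_location,
)

__all__ = [
    "CpGSiteCounts",
    "DmrParams",
    "DMR",
    "read_cpg_report",
    "write_cpg_report",
    "methylation_level",
    "segment_candidates",
    "call_dmrs",
    "merge_adjacent_dmrs",
    "annotate_dmrs",
    "write_dmr_bed",
    "write_dmr_table",
]


@dataclass(frozen=True)
class CpGSiteCounts:
    """Read counts at one cytosine: ``meth_count`` of ``total_count`` reads methylated."""

    chrom: str
    pos: int  # 0-based
    strand: str
    meth_count: int
    total_count: int
    context: str = "CpG"

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.total_count < 0:
            raise ValueError("counts must be non-negative")
        if self.meth_count > self.total_count:
            raise ValueError("meth_count exceeds total_count")


@dataclass(frozen=True)
class DmrParams:
    """DMR-calling thresholds.

    min_cpg
        Minimum covered CpG sites per region (default 5).
    min_fold
        Minimum fold change between group mean methylation levels (default 2).
    alpha
        Fisher exact P threshold on the pooled 2x2 count table (default 0.05).
    q_threshold
        BH q threshold defining the significant DMR set (default 0.05).
    max_gap_bp
        Maximum distance between consecutive CpGs within one candidate run
        (default 300 bp, a common DMR-caller default).
    """

    min_cpg: int = 5
    min_fold: float = 2.0
    alpha: float = 0.05
    q_threshold: float = 0.05
    max_gap_bp: int = 300

    def __post_init__(self) -> None:
        if self.min_cpg < 1:
            raise ValueError("min_cpg must be >= 1")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        for name in ("alpha", "q_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.max_gap_bp < 1:
            raise ValueError("max_gap_bp must be >= 1")


@dataclass(frozen=True)
class DMR:
    region: GenomicInterval
    n_cpg: int
    level_control: float
    level_treated: float
    fold_change: float  # larger level / smaller level; inf when one level is 0
    direction: str  # 'hypo' | 'hyper' in treated vs control
    p_value: float
    q_value: float
    location: str = ""  # gene_body | promoter | intergenic, set by annotate_dmrs
    linked_genes: tuple[str, ...] = ()
    # pooled counts, kept for merging: (meth, unmeth) per group
    pooled_control: tuple[int, int] = (0, 0)
    pooled_treated: tuple[int, int] = (0, 0)


def read_cpg_report(path, contexts: tuple[str, ...] = ("CpG",)) -> list[CpGSiteCounts]:
    """Read a Bismark-style per-cytosine report.

    Columns: chrom, 1-based position, strand, methylated count, unmethylated
    count, and optionally context (CpG/CHG/CHH; rows whose context is not in
    ``contexts`` are dropped). Positions are converted to 0-based.
    """
    sites: list[CpGSiteCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            try:
                pos1 = int(fields[1])
                meth = int(fields[3])
                unmeth = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            if pos1 < 1 or meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count or position")
            context = fields[5] if len(fields) > 5 else "CpG"
            if context not in contexts:
                continue
            sites.append(
                CpGSiteCounts(fields[0], pos1 - 1, fields[2], meth, meth + unmeth, context)
            )
    return sites


def write_cpg_report(sites: Iterable[CpGSiteCounts], path) -> None:
    """Write sites back to the 1-based report dialect read by read_cpg_report."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                "\t".join(
                    [
                        s.chrom,
                        str(s.pos + 1),
                        s.strand,
                        str(s.meth_count),
                        str(s.total_count - s.meth_count),
                        s.context,
                    ]
                )
                + "\n"
            )


def methylation_level(site: CpGSiteCounts) -> float | None:
    """meth_count / total_count, or None at zero coverage (excluded downstream)."""
    if site.total_count == 0:
        return None
    return site.meth_count / site.total_count


def pool_replicates(replicates: Sequence[Sequence[CpGSiteCounts]]) -> list[CpGSiteCounts]:
    """Sum counts per site across replicate reports of one group."""
    acc: dict[tuple[str, int, str], list[int]] = {}
    for rep in replicates:
        for s in rep:
            key = (s.chrom, s.pos, s.strand)
            cur = acc.setdefault(key, [0, 0])
            cur[0] += s.meth_count
            cur[1] += s.total_count
    return [
        CpGSiteCounts(chrom, pos, strand, m, t)
        for (chrom, pos, strand), (m, t) in sorted(acc.items())
    ]


def _site_maps(sites: Sequence[CpGSiteCounts]) -> dict[tuple[str, int], CpGSiteCounts]:
    out: dict[tuple[str, int], CpGSiteCounts] = {}
    for s in sites:
        key = (s.chrom, s.pos)
        if key in out:
            prev = out[key]
            out[key] = CpGSiteCounts(
                s.chrom, s.pos, prev.strand,
                prev.meth_count + s.meth_count, prev.total_count + s.total_count,
            )
        else:
            out[key] = s
    return out


def segment_candidates(
    control_sites: Sequence[CpGSiteCounts],
    treated_sites: Sequence[CpGSiteCounts],
    params: DmrParams = DmrParams(),
) -> list[list[tuple[CpGSiteCounts, CpGSiteCounts]]]:
    """Maximal runs of CpGs covered in both groups with gaps <= max_gap_bp.

    Returns one list of (control_site, treated_site) pairs per candidate,
    sorted by coordinate; runs shorter than ``min_cpg`` are discarded.
    """
    ctrl = _site_maps(control_sites)
    trt = _site_maps(treated_sites)
    shared = sorted(
        k for k in ctrl.keys() & trt.keys()
        if ctrl[k].total_count > 0 and trt[k].total_count > 0
    )
    candidates: list[list[tuple[CpGSiteCounts, CpGSiteCounts]]] = []
    run: list[tuple[str, int]] = []

    def flush() -> None:
        if len(run) >= params.min_cpg:
            candidates.append([(ctrl[k], trt[k]) for k in run])

    for key in shared:
        if run and (key[0] != run[-1][0] or key[1] - run[-1][1] > params.max_gap_bp):
            flush()
            run = []
        run.append(key)
    flush()
    return candidates


def _mean_level(sites: Sequence[CpGSiteCounts]) -> float:
    levels = [lv for s in sites if (lv := methylation_level(s)) is not None]
    return sum(levels) / len(levels)


def call_dmrs(
    control_sites: Sequence[CpGSiteCounts],
    treated_sites: Sequence[CpGSiteCounts],
    params: DmrParams = DmrParams(),
) -> list[DMR]:
    """Call DMRs from per-site counts of the two groups.

    Per candidate region, methylated/unmethylated read counts are pooled
    across sites into one 2x2 table per group and tested with a two-sided
    Fisher exact test; mean per-site levels define direction and fold change.
    Regions pass with fold >= min_fold and P <= alpha. q-values are BH over
    all tested candidates; callers filter on q <= q_threshold for the
    significant set (the returned DMRs keep all passing regions with their q).
    """
    candidates = segment_candidates(control_sites, treated_sites, params)
    if not candidates:
        return []

    stats = []
    for cand in candidates:
        c_sites = [c for c, _ in cand]
        t_sites = [t for _, t in cand]
        c_m = sum(s.meth_count for s in c_sites)
        c_u = sum(s.total_count - s.meth_count for s in c_sites)
        t_m = sum(s.meth_count for s in t_sites)
        t_u = sum(s.total_count - s.meth_count for s in t_sites)
        lv_c = _mean_level(c_sites)
        lv_t = _mean_level(t_sites)
        _, p = fisher_exact([[c_m, c_u], [t_m, t_u]], alternative="two-sided")
        stats.append((cand, c_m, c_u, t_m, t_u, lv_c, lv_t, p))

    # BH across ALL tested candidates, before the fold/alpha filter
    _, qvals, _, _ = multipletests([s[7] for s in stats], method="fdr_bh")

    dmrs: list[DMR] = []
    for (cand, c_m, c_u, t_m, t_u, lv_c, lv_t, p), q in zip(stats, qvals):
        if lv_c == 0.0 and lv_t == 0.0:
            continue  # no methylation in either group: no call
        lo, hi = sorted((lv_c, lv_t))
        fold = math.inf if lo == 0.0 else hi / lo
        if fold < params.min_fold or p > params.alpha:
            continue
        first = cand[0][0]
        last = cand[-1][0]
        dmrs.append(
            DMR(
                region=GenomicInterval(first.chrom, first.pos, last.pos + 1),
                n_cpg=len(cand),
                level_control=lv_c,
                level_treated=lv_t,
                fold_change=fold,
                direction="hypo" if lv_t < lv_c else "hyper",
                p_value=p,
                q_value=q,
                pooled_control=(c_m, c_u),
                pooled_treated=(t_m, t_u),
            )
        )
    dmrs.sort(key=lambda d: (d.region.chrom, d.region.start))
    return dmrs


def merge_adjacent_dmrs(
    dmrs: Sequence[DMR],
    control_sites: Sequence[CpGSiteCounts] = (),
    treated_sites: Sequence[CpGSiteCounts] = (),
    params: DmrParams = DmrParams(),
) -> list[DMR]:
    """Join runs of adjacent same-direction DMRs into continuous regions.

    Two consecutive DMRs on one chromosome merge when they share a direction
    and every tested candidate lying between them (recomputed from the site
    lists) was itself called — i.e. the whole stretch is differentially
    methylated. Without site lists, consecutive same-direction DMRs with no
    gap information merge only when abutting within ``max_gap_bp``. Merged
    statistics are recomputed from pooled counts; per-group levels are
    n_cpg-weighted means of member levels. Idempotent.
    """
    if not dmrs:
        return []
    ordered = sorted(dmrs, key=lambda d: (d.region.chrom, d.region.start))

    if control_sites and treated_sites:
        # interval list of tested-but-uncalled candidates, per chromosome
        candidates = segment_candidates(control_sites, treated_sites, params)
        called_spans = [
            (d.region.chrom, d.region.start, d.region.end) for d in ordered
        ]

        def is_called(chrom: str, start: int, end: int) -> bool:
            return any(
                c == chrom and max(s, start) < min(e, end)
                for c, s, e in called_spans
            )

        failed: list[tuple[str, int, int]] = []
        for cand in candidates:
            chrom = cand[0][0].chrom
            start, end = cand[0][0].pos, cand[-1][0].pos + 1
            if not is_called(chrom, start, end):
                failed.append((chrom, start, end))

        def blocked(prev: DMR, nxt: DMR) -> bool:
            return any(
                c == prev.region.chrom
                and s >= prev.region.end
                and e <= nxt.region.start
                for c, s, e in failed
            )

    else:

        def blocked(prev: DMR, nxt: DMR) -> bool:
            return nxt.region.start - prev.region.end > params.max_gap_bp

    groups: list[list[DMR]] = [[ordered[0]]]
    for d in ordered[1:]:
        prev = groups[-1][-1]
        if (
            d.region.chrom == prev.region.chrom
            and d.direction == prev.direction
            and not blocked(prev, d)
        ):
            groups[-1].append(d)
        else:
            groups.append([d])

    merged: list[DMR] = []
    for grp in groups:
        if len(grp) == 1:
            merged.append(grp[0])
            continue
        c_m = sum(d.pooled_control[0] for d in grp)
        c_u = sum(d.pooled_control[1] for d in grp)
        t_m = sum(d.pooled_treated[0] for d in grp)
        t_u = sum(d.pooled_treated[1] for d in grp)
        n = sum(d.n_cpg for d in grp)
        lv_c = sum(d.level_control * d.n_cpg for d in grp) / n
        lv_t = sum(d.level_treated * d.n_cpg for d in grp) / n
        lo, hi = sorted((lv_c, lv_t))
        fold = math.inf if lo == 0.0 else hi / lo
        _, p = fisher_exact([[c_m, c_u], [t_m, t_u]], alternative="two-sided")
        merged.append(
            DMR(
                region=GenomicInterval(
                    grp[0].region.chrom, grp[0].region.start, grp[-1].region.end
                ),
                n_cpg=n,
                level_control=lv_c,
                level_treated=lv_t,
                fold_change=fold,
                direction=grp[0].direction,
                p_value=p,
                q_value=min(d.q_value for d in grp),
                pooled_control=(c_m, c_u),
                pooled_treated=(t_m, t_u),
            )
        )
    return merged


def annotate_dmrs(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel] | GenomeIndex,
    ann_params: AnnotationParams = AnnotationParams(),
) -> list[DMR]:
    """Fill location and linked_genes per DMR via the shared window rules."""
    index = genes if isinstance(genes, GenomeIndex) else GenomeIndex(genes, ann_params)
    out: list[DMR] = []
    for d in dmrs:
        loc, linked = classify_location(d.region, index, ann_params)
        out.append(replace(d, location=loc, linked_genes=tuple(linked)))
    return out


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    """BED6+: chrom, start, end, name, -log10 q, direction."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs, start=1):
            score = 999.0 if d.q_value == 0 else -math.log10(d.q_value)
            fh.write(
                "\t".join(
                    [
                        d.region.chrom,
                        str(d.region.start),
                        str(d.region.end),
                        f"DMR_{i}",
                        f"{score:.3f}",
                        d.direction,
                    ]
                )
                + "\n"
            )


def write_dmr_table(dmrs: Sequence[DMR], path) -> None:
    cols = [
        "chrom", "start", "end", "n_cpg", "level_control", "level_treated",
        "fold_change", "direction", "p_value", "q_value", "location", "linked_genes",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in dmrs:
            fh.write(
                "\t".join(
                    [
                        d.region.chrom,
                        str(d.region.start),
                        str(d.region.end),
                        str(d.n_cpg),
                        f"{d.level_control:.6g}",
                        f"{d.level_treated:.6g}",
                        "inf" if math.isinf(d.fold_change) else f"{d.fold_change:.6g}",
                        d.direction,
                        f"{d.p_value:.6g}",
                        f"{d.q_value:.6g}",
                        d.location,
                        ",".join(d.linked_genes),
                    ]
                )
                + "\n"
            )
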