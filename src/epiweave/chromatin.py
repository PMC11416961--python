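"""Peak sets, differential features, and active-enhancer prediction.

An active enhancer is an open chromatin region (OCR) that overlaps at least
one H3K27ac peak from the same condition and does not overlap any promoter
interval. Enhancers are partitioned into gene-body vs intergenic
compartments and linked to genes through symmetric TSS windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from intervaltree import IntervalTree

from .intervals import (
    AnnotationParams,
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    overlaps,
    tss_window,
)
from .methylome import DMR

__all__ = [
    "Peak",
    "DiffFeature",
    "ActiveEnhancer",
    "read_peaks",
    "write_peaks",
    "read_diff_features",
    "write_diff_features",
    "call_active_enhancers",
    "partition_counts",
    "link_enhancers_to_genes",
    "colocalize_enhancer_dmrs",
    "write_enhancer_bed",
]

ASSAYS = ("OCR", "H3K27ac", "H3K4me3")


@dataclass(frozen=True)
class Peak:
    region: GenomicInterval
    assay: str
    signal: float | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.signal is not None and self.signal < 0:
            raise ValueError("signal must be non-negative")


@dataclass(frozen=True)
class DiffFeature:
    """A differential peak record: direction of change plus FDR, as produced
    by an external differential-binding fit and consumed here as input."""

    region: GenomicInterval
    assay: str
    fold_change_sign: str  # 'gain' | 'loss'
    fdr: float
    linked_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.fold_change_sign not in ("gain", "loss"):
            raise ValueError("fold_change_sign must be 'gain' or 'loss'")
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must lie in [0, 1]")


@dataclass(frozen=True)
class ActiveEnhancer:
    region: GenomicInterval
    compartment: str  # 'gene_body' | 'intergenic'
    linked_genes: tuple[str, ...] = ()
    hypo_methylated: bool = False


def read_peaks(path, assay: str) -> list[Peak]:
    """Read peaks from BED3+ or 10-column narrowPeak.

    narrowPeak column 7 (signalValue) becomes ``signal``; the summit column
    is ignored. A plain BED3 gives peaks without signal.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            signal = None
            if len(fields) >= 10:  # narrowPeak
                try:
                    signal = float(fields[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad signalValue") from exc
            peaks.append(Peak(iv, assay, signal))
    return peaks


def write_peaks(peaks: Sequence[Peak], path, dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            if dialect == "narrowPeak":
                fields = [
                    p.region.chrom, str(p.region.start), str(p.region.end),
                    f"peak_{i}", "0", ".",
                    f"{p.signal if p.signal is not None else 0:.4g}",
                    "-1", "-1", "-1",
                ]
            else:
                fields = [p.region.chrom, str(p.region.start), str(p.region.end)]
            fh.write("\t".join(fields) + "\n")


def read_diff_features(path) -> list[DiffFeature]:
    """Read a differential-feature TSV: chrom, start, end, assay, direction,
    fdr, comma-separated gene list (header line optional)."""
    out: list[DiffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                fdr = float(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            genes = tuple(g for g in fields[6].split(",") if g) if len(fields) > 6 else ()
            out.append(DiffFeature(iv, fields[3], fields[4], fdr, genes))
    return out


def write_diff_features(features: Sequence[DiffFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tassay\tdirection\tfdr\tgenes\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.region.chrom, str(f.region.start), str(f.region.end),
                        f.assay, f.fold_change_sign, f"{f.fdr:.6g}",
                        ",".join(f.linked_genes),
                    ]
                )
                + "\n"
            )


def _tree_of(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _any_overlap(trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree and tree.overlap(iv.start, iv.end))


def call_active_enhancers(
    ocrs: Sequence[Peak],
    k27ac: Sequence[Peak],
    genes: Sequence[GeneModel] | GenomeIndex,
    ann_params: AnnotationParams = AnnotationParams(),
    interval_mode: str = "ocr",
) -> list[ActiveEnhancer]:
    """Predict active enhancers from one condition's OCR and H3K27ac peaks.

    An enhancer is each OCR that (i) overlaps >= 1 H3K27ac peak and (ii)
    overlaps no promoter interval. By default the reported interval is the
    whole OCR; ``interval_mode='intersection'`` reports the OCR/K27ac
    intersection hull instead. Compartment is gene_body when the OCR overlaps
    any gene span, else intergenic; linked genes are those whose
    +/- ``gene_window_bp`` TSS window overlaps the OCR.
    """
    if interval_mode not in ("ocr", "intersection"):
        raise ValueError("interval_mode must be 'ocr' or 'intersection'")
    index = genes if isinstance(genes, GenomeIndex) else GenomeIndex(genes, ann_params)
    k27_trees: dict[str, IntervalTree] = {}
    for p in k27ac:
        k27_trees.setdefault(p.region.chrom, IntervalTree()).addi(
            p.region.start, p.region.end
        )

    enhancers: list[ActiveEnhancer] = []
    for ocr in sorted(ocrs, key=lambda p: (p.region.chrom, p.region.start, p.region.end)):
        tree = k27_trees.get(ocr.region.chrom)
        hits = tree.overlap(ocr.region.start, ocr.region.end) if tree else set()
        if not hits:
            continue
        if index.genes_with_promoter_overlap(ocr.region):
            continue
        if interval_mode == "intersection":
            start = max(ocr.region.start, min(h.begin for h in hits))
            end = min(ocr.region.end, max(h.end for h in hits))
            region = GenomicInterval(ocr.region.chrom, start, end)
        else:
            region = ocr.region
        genic = bool(index.genes_overlapping_span(ocr.region))
        linked = tuple(index.genes_within_window(ocr.region))
        enhancers.append(
            ActiveEnhancer(
                region=region,
                compartment="gene_body" if genic else "intergenic",
                linked_genes=linked,
            )
        )
    return enhancers


def partition_counts(enhancers: Sequence[ActiveEnhancer]) -> dict:
    """Totals and per-compartment gene tallies for an enhancer set.

    Percentages are reported to 2 decimals; gene counts are the number of
    distinct genes linked to >= 1 enhancer of the compartment.
    """
    gene_body = [e for e in enhancers if e.compartment == "gene_body"]
    intergenic = [e for e in enhancers if e.compartment == "intergenic"]
    total = len(enhancers)

    def pct(n: int) -> float:
        return round(100.0 * n / total, 2) if total else 0.0

    return {
        "total": total,
        "gene_body": len(gene_body),
        "intergenic": len(intergenic),
        "gene_body_pct": pct(len(gene_body)),
        "intergenic_pct": pct(len(intergenic)),
        "gene_body_genes": len({g for e in gene_body for g in e.linked_genes}),
        "intergenic_genes": len({g for e in intergenic for g in e.linked_genes}),
    }


def link_enhancers_to_genes(
    enhancers: Sequence[ActiveEnhancer],
    genes: Sequence[GeneModel],
    half_width: int,
) -> dict[str, list[ActiveEnhancer]]:
    """Map gene_id -> enhancers overlapping its +/- half_width TSS window.

    Used with half_width = 50 kb for the hypo-methylated-enhancer analysis
    and 100 kb for general annotation. Many-to-many: a gene may link several
    enhancers and an enhancer several genes.
    """
    enh_trees: dict[str, IntervalTree] = {}
    for i, e in enumerate(enhancers):
        enh_trees.setdefault(e.region.chrom, IntervalTree()).addi(
            e.region.start, e.region.end, i
        )
    links: dict[str, list[ActiveEnhancer]] = {}
    for g in genes:
        w = tss_window(g, half_width)
        tree = enh_trees.get(w.chrom)
        if not tree:
            continue
        hits = sorted(h.data for h in tree.overlap(w.start, w.end))
        if hits:
            links[g.gene_id] = [enhancers[i] for i in hits]
    return links


def colocalize_enhancer_dmrs(
    enhancers: Sequence[ActiveEnhancer], dmrs: Sequence[DMR]
) -> tuple[list[ActiveEnhancer], dict]:
    """Flag enhancers overlapping >= 1 hypo-methylated DMR.

    Returns the flagged enhancer list plus a summary with the flagged count
    and its fraction of the total.
    """
    hypo_trees = _tree_of([d.region for d in dmrs if d.direction == "hypo"])
    flagged = [
        replace(e, hypo_methylated=_any_overlap(hypo_trees, e.region))
        for e in enhancers
    ]
    n_flagged = sum(e.hypo_methylated for e in flagged)
    total = len(flagged)
    return flagged, {
        "n_hypo_methylated": n_flagged,
        "total": total,
        "fraction": n_flagged / total if total else 0.0,
    }


def write_enhancer_bed(enhancers: Sequence[ActiveEnhancer], path) -> None:
    """BED6+ with compartment and hypo-methylation flag columns."""
    with open(path, "w") as fh:
        for i, e in enumerate(enhancers, start=1):
            fh.write(
                "\t".join(
                    [
                        e.region.chrom, str(e.region.start), str(e.region.end),
                        f"enh_{i}", "0", ".",
                        e.compartment, str(int(e.hypo_methylated)),
                        ",".join(e.linked_genes),
                    ]
                )
                + "\n"
            )
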