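"""Genomic coordinate model: intervals, gene models, promoter/window rules, BED I/O.

All coordinates are 0-based half-open (BED convention). Inputs that use
1-based positions (per-cytosine reports) are converted at their parser
boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationParams",
    "overlaps",
    "promoters_of",
    "promoter_of",
    "tss_window",
    "classify_location",
    "GenomeIndex",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A whole-gene span with a strand-derived transcription start site.

    The TSS is the first transcribed base: ``span.start`` on the + strand,
    ``span.end - 1`` on the - strand.
    """

    gene_id: str
    span: GenomicInterval
    name: str = ""

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand == "+" else self.span.end - 1


@dataclass(frozen=True)
class AnnotationParams:
    """Window lengths (bp) governing promoter and gene-window annotation.

    Defaults follow the operational definitions used throughout the analysis:
    promoters are the 2 kb upstream of the TSS, genes are annotated to
    features within a +/-100 kb TSS window, and enhancer-gene links use a
    +/-50 kb TSS window.
    """

    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 0
    gene_window_bp: int = 100_000
    enhancer_link_bp: int = 50_000

    def __post_init__(self) -> None:
        for name in (
            "promoter_upstream_bp",
            "promoter_downstream_bp",
            "gene_window_bp",
            "enhancer_link_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def promoter_of(gene: GeneModel, params: AnnotationParams = AnnotationParams()) -> GenomicInterval:
    """The promoter interval of one gene, clipped at the chromosome start.

    On the + strand this is ``[tss - upstream, tss + downstream)``; on the -
    strand the mirror image about the TSS coordinate,
    ``[tss - downstream, tss + upstream)``.
    """
    up, down = params.promoter_upstream_bp, params.promoter_downstream_bp
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    start = max(0, start)
    if end <= start:
        # fully clipped or zero-length (up = down = 0); return the 1 bp at the
        # clip point so downstream set logic stays total
        end = start + 1
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def promoters_of(
    genes: Sequence[GeneModel], params: AnnotationParams = AnnotationParams()
) -> list[GenomicInterval]:
    """Promoter intervals for a gene list, in input order."""
    return [promoter_of(g, params) for g in genes]


def tss_window(gene: GeneModel, half_width: int) -> GenomicInterval:
    """The symmetric, strand-independent window ``[tss - w, tss + w + 1)``.

    At ``half_width = 0`` this is the single TSS base. Clipped at 0.
    A feature overlapping this window lies within ``half_width`` bp of the
    TSS (inclusive at exactly ``half_width``).
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    return GenomicInterval(
        gene.chrom, max(0, gene.tss - half_width), gene.tss + half_width + 1
    )


class GenomeIndex:
    """Interval-tree index over gene spans, promoters and TSS windows.

    Built once per gene set; answers the overlap queries behind location
    classification and gene linking in O(log n).
    """

    def __init__(self, genes: Sequence[GeneModel], params: AnnotationParams = AnnotationParams()):
        self.genes = list(genes)
        self.params = params
        self._spans: dict[str, IntervalTree] = {}
        self._promoters: dict[str, IntervalTree] = {}
        self._windows: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._spans.setdefault(g.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g.gene_id
            )
            p = promoter_of(g, params)
            self._promoters.setdefault(g.chrom, IntervalTree()).addi(
                p.start, p.end, g.gene_id
            )
            w = tss_window(g, params.gene_window_bp)
            self._windows.setdefault(g.chrom, IntervalTree()).addi(
                w.start, w.end, g.gene_id
            )

    @staticmethod
    def _hits(trees: dict[str, IntervalTree], iv: GenomicInterval) -> list[str]:
        tree = trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted({h.data for h in tree.overlap(iv.start, iv.end)})

    def genes_overlapping_span(self, iv: GenomicInterval) -> list[str]:
        return self._hits(self._spans, iv)

    def genes_with_promoter_overlap(self, iv: GenomicInterval) -> list[str]:
        return self._hits(self._promoters, iv)

    def genes_within_window(self, iv: GenomicInterval) -> list[str]:
        return self._hits(self._windows, iv)


def classify_location(
    feature: GenomicInterval,
    genes: Sequence[GeneModel] | GenomeIndex,
    params: AnnotationParams = AnnotationParams(),
) -> tuple[str, list[str]]:
    """Classify a feature as gene_body, promoter or intergenic and link genes.

    Precedence is gene_body > promoter > intergenic: a feature overlapping
    any gene span is genic regardless of promoter overlap; a non-genic
    feature in any promoter is promoter-class; anything else is intergenic
    and links every gene whose +/- ``gene_window_bp`` TSS window it overlaps
    (possibly none). Exactly one label is always returned.
    """
    index = genes if isinstance(genes, GenomeIndex) else GenomeIndex(genes, params)
    hits = index.genes_overlapping_span(feature)
    if hits:
        return "gene_body", hits
    hits = index.genes_with_promoter_overlap(feature)
    if hits:
        return "promoter", hits
    return "intergenic", index.genes_within_window(feature)


# ---------------------------------------------------------------------------
# I/O: BED3+ and the 6-column gene table
# ---------------------------------------------------------------------------


def read_bed(path) -> list[tuple[GenomicInterval, list[str]]]:
    """Read a BED3+ file into (interval, extra_columns) pairs.

    Columns beyond the first three are preserved verbatim as opaque strings.
    A column 6 that is '+', '-' or '.' is also used as the strand. Malformed
    lines raise ValueError naming the line number.
    """
    out: list[tuple[GenomicInterval, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append((iv, fields[3:]))
    return out


def write_bed(records: Iterable[GenomicInterval | tuple[GenomicInterval, list[str]]], path) -> None:
    """Write intervals (optionally with extra columns) as BED."""
    with open(path, "w") as fh:
        for rec in records:
            iv, extra = rec if isinstance(rec, tuple) else (rec, [])
            fields = [iv.chrom, str(iv.start), str(iv.end)] + list(extra)
            fh.write("\t".join(fields) + "\n")


def read_gene_table(path) -> list[GeneModel]:
    """Read the 6-column gene table (gene_id, chrom, start, end, strand, name)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            gene_id, chrom = fields[0], fields[1]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            try:
                span = GenomicInterval(chrom, int(fields[2]), int(fields[3]), fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(gene_id, span, fields[5] if len(fields) > 5 else ""))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [g.gene_id, g.chrom, str(g.span.start), str(g.span.end), g.strand, g.name]
                )
                + "\n"
            )
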