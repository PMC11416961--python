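"""Seeded generators for every pipeline input, with ground-truth manifests.

The generators emit exactly the file dialects the pipeline consumes — a
gene-model table, per-cytosine count reports for a control and a treated
group, OCR/H3K27ac/H3K4me3 peak sets per condition, differential-feature
and differential-expression tables, and a per-cell TCR table — plus a JSON
manifest of the planted truth (true DMR intervals and directions, DE
classes, the clonotype partition) sufficient to score every caller.

The statistical heart is a tunable association between gene-body
hypo-methylation and upregulation: an upregulated gene carries a planted
hypo-methylated gene-body region with probability ``p_up`` and a down- or
unregulated gene with probability ``p_hypo_baseline``, where the odds ratio
``(p_up/(1-p_up)) / (p0/(1-p0))`` equals ``theta``. Defaults mirror a
two-arm bulk methylome study of ~600 genes with 162 up- and 76
downregulated genes, baseline hypo probability 0.08 and theta 6.

CpG sites are laid out in discrete islands (8 sites, 50 bp apart) separated
by more than the segmentation gap, so each island is one candidate region.
Coverage is Poisson, methylated counts Binomial, baseline levels Beta.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatin import DiffFeature, Peak
from .clonotypes import TCRCell, TCRChain
from .expression import DERecord
from .integration import MARK_COLUMNS
from .intervals import GeneModel, GenomicInterval

__all__ = [
    "StudyConfig",
    "ClonalGroupSpec",
    "gen_genome",
    "gen_de_truth",
    "assign_hypo_truth",
    "truth_mark_matrix",
    "gen_methylome",
    "gen_peaks_and_de",
    "gen_repertoire",
]


@dataclass(frozen=True)
class ClonalGroupSpec:
    """A clonal group of ``size`` cells placed in the given clusters.

    ``clusters`` is a list of (treatment, cluster) pairs, one per member
    cell, so a group can span sub-clusters.
    """

    size: int
    clusters: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("clonal group size must be >= 1")
        if len(self.clusters) != self.size:
            raise ValueError("need one (treatment, cluster) pair per member")


def _default_clonal_groups() -> tuple[ClonalGroupSpec, ...]:
    """The studied repertoire composition: 325 singleton clonotypes plus two
    5-cell groups (treated, cluster 4) and four 2-cell groups, one of which
    spans clusters 2 and 4 of the control arm. Totals 343 cells."""
    groups = [
        ClonalGroupSpec(5, tuple([("treated", "4")] * 5)),
        ClonalGroupSpec(5, tuple([("treated", "4")] * 5)),
        ClonalGroupSpec(2, (("control", "4"), ("control", "4"))),
        ClonalGroupSpec(2, (("treated", "4"), ("treated", "4"))),
        ClonalGroupSpec(2, (("control", "2"), ("control", "4"))),
        ClonalGroupSpec(2, (("control", "2"), ("control", "2"))),
    ]
    # singletons: 175 control (clusters 1-4), 150 treated (clusters 1-5),
    # bringing the arms to 181 control and 162 treated cells
    control_clusters = ["1", "2", "3", "4"]
    treated_clusters = ["1", "2", "3", "4", "5"]
    for i in range(175):
        groups.append(ClonalGroupSpec(1, (("control", control_clusters[i % 4]),)))
    for i in range(150):
        groups.append(ClonalGroupSpec(1, (("treated", treated_clusters[i % 5]),)))
    return tuple(groups)


@dataclass(frozen=True)
class StudyConfig:
    """All generator knobs; a pure function of this object and its seed."""

    seed: int = 0
    # genome
    n_chromosomes: int = 4
    chrom_length_bp: int = 2_000_000
    n_genes: int = 600
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    gene_gap_range: tuple[int, int] = (2_000, 12_000)
    # DE classes
    n_up: int = 162
    n_down: int = 76
    # methylation <-> expression association
    theta: float = 6.0
    p_hypo_baseline: float = 0.08
    p_hyper: float = 0.05
    promoter_hypo_rate: float = 0.02  # class-independent (odds ratio 1)
    intergenic_hypo_rate: float = 0.05  # class-independent (odds ratio 1)
    # methylome counts
    coverage_mean: float = 100.0
    cpg_spacing_bp: int = 50
    island_n_cpg: int = 8
    control_level_alpha: float = 8.0
    control_level_beta: float = 2.0
    effect_fold: float = 4.0
    # peaks / differential features
    peak_density: float = 0.6  # P(gene carries a gene-body enhancer pair, pre)
    intergenic_peak_density: float = 0.3  # P(downstream intergenic pair, space permitting)
    promoter_peak_rate: float = 0.3  # promoter-overlapping OCR+K27ac decoys
    enhancer_gain_rate: float = 0.15  # post-only enhancers on up genes
    enhancer_loss_rate: float = 0.10  # pre-only enhancers on down genes
    mark_rates: dict = field(
        default_factory=lambda: {
            "diff_ocr_gain": {"up": 0.15, "down": 0.03, "unchanged": 0.02},
            "k27ac_gain": {"up": 0.12, "down": 0.01, "unchanged": 0.02},
            "k27ac_loss": {"up": 0.01, "down": 0.05, "unchanged": 0.02},
            "k4me3_gain": {"up": 0.06, "down": 0.0, "unchanged": 0.01},
            "k4me3_loss": {"up": 0.0, "down": 0.05, "unchanged": 0.01},
        }
    )
    # repertoire
    clonal_groups: tuple[ClonalGroupSpec, ...] = field(
        default_factory=_default_clonal_groups
    )
    n_alpha_alt: int = 10  # singleton clonotypes NOT using the prevalent aV/aJ
    n_unpaired_control: int = 96  # cells without a productive alpha-beta pair
    n_unpaired_treated: int = 89
    alpha_v: str = "TRAV11"
    alpha_j: str = "TRAJ18"
    beta_v_counts: dict = field(
        default_factory=lambda: {"TRBV13-2": 196, "TRBV13-1": 35, "TRBV1": 18}
    )

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must not exceed n_genes")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0 < self.p_hypo_baseline < 1:
            raise ValueError("p_hypo_baseline must lie in (0, 1)")

    @property
    def n_null(self) -> int:
        return self.n_genes - self.n_up - self.n_down

    @property
    def p_hypo_up(self) -> float:
        """Hypo probability for upregulated genes implied by theta."""
        odds = self.theta * self.p_hypo_baseline / (1 - self.p_hypo_baseline)
        return odds / (1 + odds)


def _rng(config: StudyConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def gen_genome(config: StudyConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene spans on both strands; deterministic per seed."""
    rng = _rng(config, 1)
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chromosomes)
    }
    genes: list[GeneModel] = []
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes) if config.n_genes else 0
    gid = 0
    for chrom in chrom_sizes:
        pos = int(rng.integers(5_000, 15_000))
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            length = int(rng.integers(*config.gene_length_range))
            if pos + length + 5_000 > config.chrom_length_bp:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                GeneModel(
                    f"g{gid:04d}", GenomicInterval(chrom, pos, pos + length, strand)
                )
            )
            pos += length + int(rng.integers(*config.gene_gap_range))
    if gid < config.n_genes:
        raise ValueError(
            f"genome too small: placed {gid} of {config.n_genes} genes; "
            "increase chrom_length_bp or n_chromosomes"
        )
    return genes, chrom_sizes


def gen_de_truth(config: StudyConfig) -> dict[str, str]:
    """Random assignment of up/down/unchanged classes to gene ids."""
    rng = _rng(config, 2)
    ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    truth = {}
    for rank, idx in enumerate(perm):
        if rank < config.n_up:
            cls = "up"
        elif rank < config.n_up + config.n_down:
            cls = "down"
        else:
            cls = "unchanged"
        truth[ids[idx]] = cls
    return {g: truth[g] for g in ids}


def assign_hypo_truth(
    config: StudyConfig, de_truth: dict[str, str], rng: np.random.Generator
) -> dict[str, dict[str, bool]]:
    """Planted per-gene methylation-change flags.

    Gene-body hypo-methylation follows the theta model; hyper-methylation
    and promoter/intergenic hypo-methylation are class-independent.
    """
    flags: dict[str, dict[str, bool]] = {}
    for gene_id, cls in de_truth.items():
        p_hypo = config.p_hypo_up if cls == "up" else config.p_hypo_baseline
        flags[gene_id] = {
            "hypo_gene_body": bool(rng.random() < p_hypo),
            "hyper_gene_body": bool(rng.random() < config.p_hyper),
            "hypo_promoter": bool(rng.random() < config.promoter_hypo_rate),
            "hypo_intergenic": bool(rng.random() < config.intergenic_hypo_rate),
        }
    return flags


def truth_mark_matrix(
    de_truth: dict[str, str], hypo_flags: dict[str, dict[str, bool]]
) -> pd.DataFrame:
    """The mark matrix implied directly by the planted truth (no reads).

    Used for parameter-recovery studies of the association statistics in
    isolation from the read-level calling chain.
    """
    idx = pd.Index(list(de_truth), name="gene_id")
    m = pd.DataFrame(False, index=idx, columns=list(MARK_COLUMNS))
    for col in ("hypo_gene_body", "hyper_gene_body", "hypo_promoter", "hypo_intergenic"):
        m[col] = [hypo_flags[g][col] for g in idx]
    m["de_class"] = pd.Series(de_truth)
    return m


def _island_positions(start: int, n: int, spacing: int) -> list[int]:
    return [start + i * spacing for i in range(n)]


def gen_methylome(
    config: StudyConfig,
    genome: Sequence[GeneModel],
    de_truth: dict[str, str],
) -> tuple[list, list, dict]:
    """Control and treated per-CpG count lists plus the truth manifest.

    Each gene carries one background island (same level in both groups) and,
    when flagged, planted effect islands in the gene body, the promoter
    region or downstream intergenic space. In hypo regions the treated level
    is the control level divided by ``effect_fold``; hyper regions mirror
    this. The manifest lists every planted region with its direction and
    intended compartment.
    """
    from .methylome import CpGSiteCounts  # local import to avoid cycle at module load

    rng = _rng(config, 3)
    flags = assign_hypo_truth(config, de_truth, rng)
    spacing = config.cpg_spacing_bp
    n_cpg = config.island_n_cpg
    island_span = (n_cpg - 1) * spacing + 1

    control: list[CpGSiteCounts] = []
    treated: list[CpGSiteCounts] = []
    true_regions: list[dict] = []

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span.start)

    def emit_island(chrom: str, start: int, level_c: float, level_t: float) -> None:
        for pos in _island_positions(start, n_cpg, spacing):
            for sink, level in ((control, level_c), (treated, level_t)):
                cov = int(rng.poisson(config.coverage_mean))
                meth = int(rng.binomial(cov, level)) if cov else 0
                sink.append(CpGSiteCounts(chrom, pos, "+", meth, cov))

    for chrom, genes in by_chrom.items():
        for i, g in enumerate(genes):
            f = flags[g.gene_id]
            base = float(rng.beta(config.control_level_alpha, config.control_level_beta))
            base = min(max(base, 0.05), 0.98)
            # background island near the gene start: identical levels
            bg_start = g.span.start + 100
            emit_island(chrom, bg_start, base, base)

            mid = g.span.start + len(g.span) // 2
            if f["hypo_gene_body"] or f["hyper_gene_body"]:
                hypo = f["hypo_gene_body"]
                lv_c = base if hypo else base / config.effect_fold
                lv_t = base / config.effect_fold if hypo else base
                emit_island(chrom, mid, lv_c, lv_t)
                if config.effect_fold > 1:
                    true_regions.append(
                        {
                            "chrom": chrom,
                            "start": mid,
                            "end": mid + island_span,
                            "direction": "hypo" if hypo else "hyper",
                            "gene_id": g.gene_id,
                            "location": "gene_body",
                        }
                    )

            if f["hypo_promoter"]:
                # inside the 2 kb upstream promoter window
                if g.strand == "+":
                    pstart = g.tss - 1_800
                else:
                    pstart = g.tss + 1_800 - island_span
                if pstart > 0:
                    emit_island(chrom, pstart, base, base / config.effect_fold)
                    if config.effect_fold > 1:
                        true_regions.append(
                            {
                                "chrom": chrom,
                                "start": pstart,
                                "end": pstart + island_span,
                                "direction": "hypo",
                                "gene_id": g.gene_id,
                                "location": "promoter",
                            }
                        )

            if f["hypo_intergenic"]:
                # downstream gap, clear of this gene, the next gene and any
                # promoter (2 kb flanks on both sides)
                nxt = genes[i + 1].span.start if i + 1 < len(genes) else config.chrom_length_bp
                istart = g.span.end + 2_500
                if istart + island_span < nxt - 2_500:
                    emit_island(chrom, istart, base, base / config.effect_fold)
                    if config.effect_fold > 1:
                        true_regions.append(
                            {
                                "chrom": chrom,
                                "start": istart,
                                "end": istart + island_span,
                                "direction": "hypo",
                                "gene_id": g.gene_id,
                                "location": "intergenic",
                            }
                        )

    manifest = {
        "true_regions": true_regions,
        "hypo_flags": flags,
        "theta": config.theta,
        "effect_fold": config.effect_fold,
    }
    control.sort(key=lambda s: (s.chrom, s.pos))
    treated.sort(key=lambda s: (s.chrom, s.pos))
    return control, treated, manifest


def gen_peaks_and_de(
    config: StudyConfig,
    genome: Sequence[GeneModel],
    de_truth: dict[str, str],
) -> dict:
    """Peak sets per condition, differential-feature tables, and a DE table.

    Enhancer-candidate OCR/H3K27ac pairs are planted in gene bodies
    (shared between conditions, with treatment-specific gains on up genes
    and losses on down genes); promoter-overlapping decoy pairs exercise the
    promoter-exclusion rule. Differential features are assigned per the
    ``mark_rates`` table. DE fold changes and FDRs are drawn so that
    threshold classification recovers the intended classes exactly.
    """
    rng = _rng(config, 4)
    ocr_pre: list[Peak] = []
    ocr_post: list[Peak] = []
    k27_pre: list[Peak] = []
    k27_post: list[Peak] = []
    diff_features: list[DiffFeature] = []
    truth_enhancers: dict[str, dict[str, bool]] = {}

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span.start)
    next_start = {}
    for chrom, lst in by_chrom.items():
        for i, g in enumerate(lst):
            next_start[g.gene_id] = (
                lst[i + 1].span.start if i + 1 < len(lst) else config.chrom_length_bp
            )

    for g in genome:
        cls = de_truth[g.gene_id]
        mid = g.span.start + len(g.span) // 2
        body_ocr = GenomicInterval(g.chrom, mid, mid + 500)
        body_k27 = GenomicInterval(g.chrom, mid + 200, mid + 700)

        has_pre = rng.random() < config.peak_density
        gain = cls == "up" and rng.random() < config.enhancer_gain_rate
        loss = cls == "down" and has_pre and rng.random() < config.enhancer_loss_rate
        has_post = (has_pre and not loss) or gain

        if has_pre:
            ocr_pre.append(Peak(body_ocr, "OCR", float(rng.uniform(2, 20))))
            k27_pre.append(Peak(body_k27, "H3K27ac", float(rng.uniform(2, 20))))
        if has_post:
            ocr_post.append(Peak(body_ocr, "OCR", float(rng.uniform(2, 20))))
            k27_post.append(Peak(body_k27, "H3K27ac", float(rng.uniform(2, 20))))
        truth_enhancers[g.gene_id] = {"pre": bool(has_pre), "post": bool(has_post)}

        # intergenic enhancer pair in the downstream gap, clear of this
        # gene, the next gene and both promoters (2 kb flanks), and of the
        # planted intergenic methylation island at gene.end + 2.5 kb
        istart = g.span.end + 4_000
        if (
            rng.random() < config.intergenic_peak_density
            and istart + 700 < next_start[g.gene_id] - 2_500
        ):
            iocr = GenomicInterval(g.chrom, istart, istart + 500)
            ik27 = GenomicInterval(g.chrom, istart + 200, istart + 700)
            for lst in (ocr_pre, ocr_post):
                lst.append(Peak(iocr, "OCR", float(rng.uniform(2, 20))))
            for lst in (k27_pre, k27_post):
                lst.append(Peak(ik27, "H3K27ac", float(rng.uniform(2, 20))))

        if rng.random() < config.promoter_peak_rate:
            # decoy pair straddling the promoter: must never become an enhancer
            if g.strand == "+":
                decoy = GenomicInterval(g.chrom, max(0, g.tss - 1_000), g.tss - 400)
            else:
                decoy = GenomicInterval(g.chrom, g.tss + 400, g.tss + 1_000)
            for lst in (ocr_pre, ocr_post):
                lst.append(Peak(decoy, "OCR", float(rng.uniform(2, 20))))
            for lst in (k27_pre, k27_post):
                lst.append(Peak(decoy, "H3K27ac", float(rng.uniform(2, 20))))

        for mark, rates in config.mark_rates.items():
            if rng.random() >= rates.get(cls, 0.0):
                continue
            assay = {"diff_ocr": "OCR", "k27ac": "H3K27ac", "k4me3": "H3K4me3"}[
                mark.rsplit("_", 1)[0]
            ]
            sign = mark.rsplit("_", 1)[1]
            offset = int(rng.integers(0, max(1, len(g.span) - 300)))
            region = GenomicInterval(
                g.chrom, g.span.start + offset, g.span.start + offset + 300
            )
            diff_features.append(
                DiffFeature(region, assay, sign, float(rng.uniform(0, 0.009)), (g.gene_id,))
            )

    de_records: list[DERecord] = []
    for g in genome:
        cls = de_truth[g.gene_id]
        if cls == "up":
            fc = float(2.0 ** rng.uniform(2.0, 6.0))
            fdr = float(10.0 ** -rng.uniform(3.0, 8.0))
        elif cls == "down":
            fc = float(2.0 ** rng.uniform(-6.0, -0.5))
            fdr = float(10.0 ** -rng.uniform(3.0, 8.0))
        else:
            fc = float(2.0 ** rng.uniform(-1.5, 1.9))
            fdr = float(rng.uniform(0.02, 0.9))
        de_records.append(DERecord(g.gene_id, fc, fdr))

    for lst in (ocr_pre, ocr_post, k27_pre, k27_post):
        lst.sort(key=lambda p: (p.region.chrom, p.region.start))
    diff_features.sort(key=lambda f: (f.region.chrom, f.region.start))

    return {
        "ocr_pre": ocr_pre,
        "ocr_post": ocr_post,
        "k27ac_pre": k27_pre,
        "k27ac_post": k27_post,
        "diff_features": diff_features,
        "de_records": de_records,
        "truth_enhancers": truth_enhancers,
    }


_NT = np.array(list("ACGT"))


def _random_cdr3(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        k = int(rng.integers(12, 17))
        s = "".join(rng.choice(_NT, size=3 * k))
        if s not in used:
            used.add(s)
            return s


def gen_repertoire(config: StudyConfig) -> tuple[list[TCRCell], dict]:
    """A paired-chain repertoire realising the configured clonal composition.

    V/J elements are assigned by deterministic quota so the configured usage
    counts hold exactly: all clonotypes except ``n_alpha_alt`` singletons use
    the prevalent α pair, and β V elements are filled largest-quota-first
    (clonal groups first). CDR3 nucleotide strings are random and unique per
    clonotype; members of a clonotype share both chains exactly.
    """
    rng = _rng(config, 5)
    groups = sorted(config.clonal_groups, key=lambda g: -g.size)
    n_cells = sum(g.size for g in groups)

    # beta V quota expanded to clonotype assignments, largest groups first
    beta_quota = dict(config.beta_v_counts)
    n_other = n_cells - sum(beta_quota.values())
    if n_other < 0:
        raise ValueError("beta_v_counts exceed the repertoire size")
    alt_betas = ["TRBV5", "TRBV29", "TRBV19", "TRBV16"]

    singleton_idx = [i for i, g in enumerate(groups) if g.size == 1]
    alpha_alt_set = set(singleton_idx[-config.n_alpha_alt:]) if config.n_alpha_alt else set()
    alt_alphas = [("TRAV12-1", "TRAJ33"), ("TRAV14-2", "TRAJ12"), ("TRAV6-5", "TRAJ31")]

    cells: list[TCRCell] = []
    used_cdr3: set[str] = set()
    truth_partition: dict[str, int] = {}
    beta_items = sorted(beta_quota.items(), key=lambda kv: -kv[1])
    cell_no = 0
    for ct_idx, grp in enumerate(groups):
        if ct_idx in alpha_alt_set:
            av, aj = alt_alphas[ct_idx % len(alt_alphas)]
        else:
            av, aj = config.alpha_v, config.alpha_j
        bv = None
        for name, left in beta_items:
            if left >= grp.size:
                bv = name
                beta_quota[name] -= grp.size
                break
        beta_items = sorted(beta_quota.items(), key=lambda kv: -kv[1])
        if bv is None:
            bv = alt_betas[ct_idx % len(alt_betas)]
        bj = f"TRBJ{1 + ct_idx % 2}-{1 + ct_idx % 5}"

        alpha = TCRChain("alpha", av, aj, _random_cdr3(rng, used_cdr3), productive=True)
        beta = TCRChain("beta", bv, bj, _random_cdr3(rng, used_cdr3), productive=True)
        for treatment, cluster in grp.clusters:
            cell_no += 1
            cid = f"cell{cell_no:04d}"
            cells.append(TCRCell(cid, treatment, cluster, (alpha, beta)))
            truth_partition[cid] = ct_idx

    # cells that fail the productive-pair filter: missing or unproductive beta
    for treatment, n_extra in (
        ("control", config.n_unpaired_control),
        ("treated", config.n_unpaired_treated),
    ):
        for i in range(n_extra):
            cell_no += 1
            alpha = TCRChain(
                "alpha", config.alpha_v, config.alpha_j,
                _random_cdr3(rng, used_cdr3), productive=True,
            )
            if i % 2 == 0:
                chains: tuple[TCRChain, ...] = (alpha,)  # no beta recovered
            else:
                chains = (
                    alpha,
                    TCRChain(
                        "beta", "TRBV13-2", "TRBJ2-1",
                        _random_cdr3(rng, used_cdr3), productive=False,
                    ),
                )
            cells.append(
                TCRCell(f"cell{cell_no:04d}", treatment, str(1 + i % 4), chains)
            )

    order = rng.permutation(len(cells))
    cells = [cells[i] for i in order]
    manifest = {
        "n_cells_total": len(cells),
        "n_productive_paired": n_cells,
        "n_clonotypes": len(groups),
        "partition": truth_partition,
        "size_spectrum": {},
    }
    from collections import Counter

    manifest["size_spectrum"] = dict(sorted(Counter(g.size for g in groups).items()))
    return cells, manifest
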