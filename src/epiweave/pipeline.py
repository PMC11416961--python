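"""End-to-end orchestration: simulate a study, run the analysis chain, report.

``simulate_study`` writes a complete synthetic study to disk in the file
dialects the pipeline reads. ``run_all`` executes the full chain — DMR
calling, enhancer prediction, DMR/enhancer annotation, DE classification,
mark-matrix assembly, association tests, group labels, mark tallies,
modification burden, clonotype analysis — writing every intermediate table
plus a single JSON summary of the headline statistics. Both are
deterministic for a fixed seed/config.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from . import chromatin, clonotypes as clono, expression, integration, methylome, simulate
from .intervals import AnnotationParams, GenomeIndex, read_gene_table, write_gene_table

__all__ = ["RunConfig", "simulate_study", "run_all", "report"]


@dataclass
class RunConfig:
    """Paths to every input plus the analysis parameters."""

    genes: str = "genes.tsv"
    methylome_control: str = "methylome_control.tsv"
    methylome_treated: str = "methylome_treated.tsv"
    ocr_pre: str = "ocr_pre.narrowPeak"
    ocr_post: str = "ocr_post.narrowPeak"
    k27ac_pre: str = "k27ac_pre.narrowPeak"
    k27ac_post: str = "k27ac_post.narrowPeak"
    diff_features: str = "diff_features.tsv"
    de_table: str = "de_table.tsv"
    de_scale: str = "linear"
    tcr_table: str = "tcr_cells.tsv"
    outdir: str = "results"
    seed: int = 0
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    dmr: methylome.DmrParams = field(default_factory=methylome.DmrParams)
    de: expression.DEParams = field(default_factory=expression.DEParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (
            ("annotation", AnnotationParams),
            ("dmr", methylome.DmrParams),
            ("de", expression.DEParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def resolve(self, base: str) -> "RunConfig":
        """Return a copy with relative input paths joined onto ``base``."""
        out = dataclasses.replace(self)
        for name in (
            "genes", "methylome_control", "methylome_treated",
            "ocr_pre", "ocr_post", "k27ac_pre", "k27ac_post",
            "diff_features", "de_table", "tcr_table",
        ):
            p = getattr(out, name)
            if not os.path.isabs(p):
                setattr(out, name, os.path.join(base, p))
        return out


def simulate_study(config: simulate.StudyConfig, outdir: str) -> dict:
    """Generate a full synthetic study on disk; returns the file map."""
    os.makedirs(outdir, exist_ok=True)
    genome, chrom_sizes = simulate.gen_genome(config)
    de_truth = simulate.gen_de_truth(config)
    control, treated, meth_manifest = simulate.gen_methylome(config, genome, de_truth)
    peaks = simulate.gen_peaks_and_de(config, genome, de_truth)
    cells, rep_manifest = simulate.gen_repertoire(config)

    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("genes", "genes.tsv"),
        ("chrom_sizes", "chrom_sizes.tsv"),
        ("methylome_control", "methylome_control.tsv"),
        ("methylome_treated", "methylome_treated.tsv"),
        ("ocr_pre", "ocr_pre.narrowPeak"),
        ("ocr_post", "ocr_post.narrowPeak"),
        ("k27ac_pre", "k27ac_pre.narrowPeak"),
        ("k27ac_post", "k27ac_post.narrowPeak"),
        ("diff_features", "diff_features.tsv"),
        ("de_table", "de_table.tsv"),
        ("tcr_table", "tcr_cells.tsv"),
        ("truth", "truth_manifest.json"),
    ]}

    write_gene_table(genome, paths["genes"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    methylome.write_cpg_report(control, paths["methylome_control"])
    methylome.write_cpg_report(treated, paths["methylome_treated"])
    chromatin.write_peaks(peaks["ocr_pre"], paths["ocr_pre"])
    chromatin.write_peaks(peaks["ocr_post"], paths["ocr_post"])
    chromatin.write_peaks(peaks["k27ac_pre"], paths["k27ac_pre"])
    chromatin.write_peaks(peaks["k27ac_post"], paths["k27ac_post"])
    chromatin.write_diff_features(peaks["diff_features"], paths["diff_features"])
    expression.write_de_table(peaks["de_records"], paths["de_table"])
    clono.write_tcr_table(cells, paths["tcr_table"])

    truth = {
        "config": {
            "seed": config.seed,
            "n_genes": config.n_genes,
            "n_up": config.n_up,
            "n_down": config.n_down,
            "theta": config.theta,
            "effect_fold": config.effect_fold,
            "coverage_mean": config.coverage_mean,
        },
        "de_truth": de_truth,
        "methylome": meth_manifest,
        "enhancers": peaks["truth_enhancers"],
        "repertoire": rep_manifest,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def _jsonable(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def run_all(cfg: RunConfig) -> dict:
    """Execute the whole analysis chain; writes intermediates and a summary.

    Returns the summary dict that is also written to ``summary.json``.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731

    genes = read_gene_table(cfg.genes)
    index = GenomeIndex(genes, cfg.annotation)

    # --- methylome: DMR calling, merging, annotation -----------------------
    control = methylome.read_cpg_report(cfg.methylome_control)
    treated = methylome.read_cpg_report(cfg.methylome_treated)
    dmrs = methylome.call_dmrs(control, treated, cfg.dmr)
    dmrs = methylome.merge_adjacent_dmrs(dmrs, control, treated, cfg.dmr)
    significant = [d for d in dmrs if d.q_value <= cfg.dmr.q_threshold]
    annotated = methylome.annotate_dmrs(significant, index, cfg.annotation)
    methylome.write_dmr_bed(annotated, out("dmrs.bed"))
    methylome.write_dmr_table(annotated, out("dmrs.tsv"))

    # --- chromatin: enhancers per condition, hypo colocalisation -----------
    enhancers = {}
    for cond in ("pre", "post"):
        ocrs = chromatin.read_peaks(getattr(cfg, f"ocr_{cond}"), "OCR")
        k27 = chromatin.read_peaks(getattr(cfg, f"k27ac_{cond}"), "H3K27ac")
        enhancers[cond] = chromatin.call_active_enhancers(
            ocrs, k27, index, cfg.annotation
        )
    flagged_post, coloc_stats = chromatin.colocalize_enhancer_dmrs(
        enhancers["post"], annotated
    )
    hypo_enh = [e for e in flagged_post if e.hypo_methylated]
    links50 = chromatin.link_enhancers_to_genes(
        hypo_enh, genes, cfg.annotation.enhancer_link_bp
    )
    chromatin.write_enhancer_bed(enhancers["pre"], out("enhancers_pre.bed"))
    chromatin.write_enhancer_bed(flagged_post, out("enhancers_post.bed"))

    # --- expression --------------------------------------------------------
    de_records = expression.classify_de(
        expression.read_de_table(cfg.de_table, cfg.de_scale), cfg.de
    )
    expression.write_de_table(de_records, out("de_classified.tsv"))

    # --- integration -------------------------------------------------------
    diff_features = chromatin.read_diff_features(cfg.diff_features)
    matrix = integration.build_mark_matrix(
        [g.gene_id for g in genes],
        annotated_dmrs=annotated,
        diff_features=diff_features,
        enhancers_pre=enhancers["pre"],
        enhancers_post=flagged_post,
        hypo_enhancer_links=links50,
        de_records=de_records,
    )
    matrix.to_csv(out("mark_matrix.tsv"), sep="\t")

    assoc_rows = []
    for mark in integration.MARK_COLUMNS:
        rep = integration.association_report(matrix, mark)
        assoc_rows.append(
            {
                "mark": mark,
                "up_count": rep["up_count"],
                "up_total": rep["up_total"],
                "down_count": rep["down_count"],
                "down_total": rep["down_total"],
                "up_pct": rep["up_pct"],
                "down_pct": rep["down_pct"],
                "chi2": rep["result"].chi2 if rep["result"] else float("nan"),
                "p_one_sided": rep["p_one_sided"],
                "p_two_sided": rep["p_two_sided"],
                "odds_ratio": rep["odds_ratio"],
            }
        )
    import pandas as pd

    assoc = pd.DataFrame(assoc_rows)
    assoc.to_csv(out("associations.tsv"), sep="\t", index=False, float_format="%.6g")

    groups = integration.assign_groups(matrix)
    groups.to_frame().to_csv(out("groups.tsv"), sep="\t")
    tally = integration.mark_weight_tally(matrix)
    tally.to_csv(out("mark_tally.tsv"), sep="\t", index=False)
    burden, burden_hist = integration.modification_burden(matrix)
    burden_hist.to_csv(out("burden.tsv"), sep="\t", index=False)

    # --- clonotypes --------------------------------------------------------
    cells = clono.read_tcr_table(cfg.tcr_table)
    paired, filter_stats = clono.filter_productive_paired(cells)
    cts = clono.assign_clonotypes(paired)
    csummary = clono.clonal_summary(cts)
    usage = clono.vj_usage(paired, "alpha", "TRAV11", "TRAJ18")
    _, shared = clono.cross_cluster_sharing(cts)
    with open(out("shared_clonotypes.tsv"), "w") as fh:
        fh.write("alpha_v\talpha_j\talpha_cdr3\tbeta_v\tbeta_j\tbeta_cdr3\tsize\tclusters\n")
        for ct in shared:
            clusters = ",".join(
                f"{t}:{c}" for t, c in sorted(ct.clusters_present)
            )
            fh.write("\t".join(list(ct.key) + [str(ct.size), clusters]) + "\n")

    de_counts = {
        cls: sum(1 for r in de_records if r.de_class == cls)
        for cls in ("up", "down", "unchanged")
    }
    summary = {
        "n_genes": len(genes),
        "dmr": {
            "n_called": len(dmrs),
            "n_significant_q": len(annotated),
            "n_hypo": sum(d.direction == "hypo" for d in annotated),
            "n_hyper": sum(d.direction == "hyper" for d in annotated),
            "by_location": {
                loc: sum(d.location == loc for d in annotated)
                for loc in ("gene_body", "promoter", "intergenic")
            },
        },
        "enhancers": {
            "pre": chromatin.partition_counts(enhancers["pre"]),
            "post": chromatin.partition_counts(flagged_post),
            "hypo_colocalisation": coloc_stats,
            "n_genes_linked_50kb": len(links50),
        },
        "de_classes": de_counts,
        "associations": {
            row["mark"]: {
                "up": f"{row['up_count']}/{row['up_total']}",
                "down": f"{row['down_count']}/{row['down_total']}",
                "p_one_sided": _jsonable(row["p_one_sided"]),
                "odds_ratio": _jsonable(row["odds_ratio"]),
            }
            for row in assoc_rows
        },
        "groups": groups.value_counts().to_dict(),
        "clonotypes": {
            **filter_stats,
            "n_clonotypes": csummary["n_clonotypes"],
            "singleton_cell_fraction": csummary["singleton_cell_fraction"],
            "size_spectrum": {str(k): v for k, v in csummary["size_spectrum"].items()},
            "alpha_TRAV11_TRAJ18_pct": usage["pct"],
            "n_shared_across_clusters": len(shared),
        },
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonable)
    return summary


def report(outdir: str, figures: bool = False) -> list[str]:
    """Render human-readable tables (and optionally figures) from run_all
    outputs; returns the lines printed."""
    import pandas as pd

    lines: list[str] = []
    summary_path = os.path.join(outdir, "summary.json")
    if not os.path.exists(summary_path):
        return ["no summary.json found; run the pipeline first"]
    with open(summary_path) as fh:
        summary = json.load(fh)
    lines.append("== headline statistics ==")
    lines.append(json.dumps(summary, indent=1, sort_keys=True))

    tally_path = os.path.join(outdir, "mark_tally.tsv")
    if os.path.exists(tally_path):
        tally = pd.read_csv(tally_path, sep="\t")
        lines.append("\n== mark weight tally (radar data) ==")
        lines.append(tally.to_string(index=False))
        if figures and len(tally):
            _radar_figure(tally, os.path.join(outdir, "mark_radar.png"))
            lines.append(f"wrote {os.path.join(outdir, 'mark_radar.png')}")

    burden_path = os.path.join(outdir, "burden.tsv")
    if os.path.exists(burden_path):
        hist = pd.read_csv(burden_path, sep="\t")
        lines.append("\n== modification-burden histogram ==")
        lines.append(hist.to_string(index=False))
        if figures and len(hist):
            _burden_figure(hist, os.path.join(outdir, "burden.png"))

    matrix_path = os.path.join(outdir, "mark_matrix.tsv")
    if figures and os.path.exists(matrix_path):
        m = pd.read_csv(matrix_path, sep="\t", index_col=0)
        _heatmap_figure(m, os.path.join(outdir, "mark_heatmap.png"))
    return lines


def _radar_figure(tally, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    marks = tally["mark"].tolist()
    angles = np.linspace(0, 2 * np.pi, len(marks), endpoint=False)
    fig, axes = plt.subplots(
        1, 2, figsize=(11, 5), subplot_kw={"projection": "polar"}
    )
    for ax, col, title in zip(axes, ("up_count", "down_count"), ("upregulated", "downregulated")):
        vals = tally[col].to_numpy(dtype=float)
        ax.plot(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]])
        ax.fill(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]], alpha=0.25)
        ax.set_xticks(angles)
        ax.set_xticklabels(marks, fontsize=6)
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _burden_figure(hist, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, grp in hist.groupby("de_class"):
        ax.plot(grp["n_types"], grp["pct"], marker="o", label=cls)
    ax.set_xlabel("number of modification types (0-4)")
    ax.set_ylabel("% of genes in class")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _heatmap_figure(matrix, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    marks = [c for c in matrix.columns if c != "de_class"]
    sub = matrix.loc[matrix["de_class"] != "unchanged", marks].astype(int)
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(sub.to_numpy(), aspect="auto", interpolation="nearest", cmap="Greys")
    ax.set_xticks(range(len(marks)))
    ax.set_xticklabels(marks, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
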