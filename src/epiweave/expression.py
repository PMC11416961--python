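"""Differential-expression tables and threshold classification.

Genes are classified as upregulated (linear fold change >= 4 with
FDR <= 0.01), downregulated (log2 fold change below 0 with FDR <= 0.01)
or unchanged. The asymmetry — up needs a 4-fold gain, down any significant
negative change — follows the operational definition used throughout the
downstream contingency analyses; a symmetric down threshold (FC <= 1/4)
is available via ``symmetric_down``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "DERecord",
    "DEParams",
    "GenePanel",
    "read_de_table",
    "write_de_table",
    "classify_de",
    "subset_panel",
    "read_panel",
]


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    fold_change: float  # linear scale, treated / control
    fdr: float
    de_class: str = ""  # 'up' | 'down' | 'unchanged', set by classify_de

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("linear fold change must be > 0")
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must lie in [0, 1]")

    @property
    def log2_fc(self) -> float:
        return math.log2(self.fold_change)


@dataclass(frozen=True)
class DEParams:
    up_min_fc: float = 4.0
    down_max_log2fc: float = 0.0  # down iff log2FC < this
    fdr_max: float = 0.01
    symmetric_down: bool = False  # down iff FC <= 1/up_min_fc instead

    def __post_init__(self) -> None:
        if self.up_min_fc < 1:
            raise ValueError("up_min_fc must be >= 1")


@dataclass(frozen=True)
class GenePanel:
    """A curated gene list (e.g. a lineage-relevant panel), unique non-empty ids."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("panel must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("panel gene ids must be unique")


def read_de_table(path, scale: str = "linear") -> list[DERecord]:
    """Read a DE TSV (gene_id, fc-or-log2fc, fdr); log2 input is converted
    to the linear scale internally."""
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    out: list[DERecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError(f"{path}: expected >= 3 columns (gene, fc, fdr)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                fc = float(fields[1])
                fdr = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if scale == "log2":
                fc = 2.0 ** fc
            try:
                out.append(DERecord(fields[0], fc, fdr))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_de_table(records: Sequence[DERecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfold_change\tfdr\tde_class\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fold_change:.6g}\t{r.fdr:.6g}\t{r.de_class}\n")


def classify_de(records: Sequence[DERecord], params: DEParams = DEParams()) -> list[DERecord]:
    """Assign de_class per record; a pure function of (FC, FDR, params)."""
    out: list[DERecord] = []
    for r in records:
        if r.fdr <= params.fdr_max and r.fold_change >= params.up_min_fc:
            cls = "up"
        elif r.fdr <= params.fdr_max and (
            r.fold_change <= 1.0 / params.up_min_fc
            if params.symmetric_down
            else r.log2_fc < params.down_max_log2fc
        ):
            cls = "down"
        else:
            cls = "unchanged"
        out.append(replace(r, de_class=cls))
    return out


def subset_panel(
    records: Sequence[DERecord], panel: GenePanel
) -> tuple[list[DERecord], dict[str, int]]:
    """Restrict records to panel genes (order preserved) with per-class counts."""
    wanted = set(panel.gene_ids)
    subset = [r for r in records if r.gene_id in wanted]
    counts = {"up": 0, "down": 0, "unchanged": 0}
    for r in subset:
        counts[r.de_class or "unchanged"] += 1
    return subset, counts


def read_panel(path, name: str = "panel") -> GenePanel:
    """One gene id per line; blank lines and # comments ignored."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return GenePanel(name, tuple(ids))
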