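"""Marker-panel heatmap normalizations and the qPCR relative-abundance pipeline.

Heatmaps: per-gene rows are either scaled to peak at 1 (``max1``) or
z-scored across stages. qPCR: triplicate threshold cycles are averaged
against a reference gene (HPRT by default), converted to linear folds with
2^-dCT, double-normalized (each gene sums to 1 across all stage/population
conditions, then each condition column sums to 1 across genes — pie-chart
fractions), and optionally collapsed into marker groups such as deep-layer
(TBR1/RELN, CTIP2/FEZF2) versus upper-layer (CUX1/CUX2/SATB2) neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign, DEFAULT_DESIGN
from .matrix import ExpressionMatrix, stage_trajectory_frame

HEATMAP_MODES = ("max1", "zscore")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker genes with a germinal-zone annotation per gene."""

    genes: tuple[str, ...]
    zones: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")


@dataclass
class CtTable:
    """Long-format replicate Ct values with a designated reference gene.

    ``data`` columns: gene, stage, population, replicate, ct. Every
    condition carrying a target gene must also carry the reference.
    """

    data: pd.DataFrame
    reference: str = "HPRT"

    def __post_init__(self) -> None:
        required = {"gene", "stage", "population", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and > 0")
        for (stage, pop), grp in self.data.groupby(["stage", "population"]):
            genes = set(grp["gene"])
            if genes - {self.reference} and self.reference not in genes:
                raise ValueError(
                    f"reference {self.reference!r} not measured at ({stage}, {pop})"
                )

    def conditions(self) -> list[tuple[str, str]]:
        return sorted({(s, p) for s, p in zip(self.data["stage"], self.data["population"])})

    def target_genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference})


@dataclass(frozen=True)
class MarkerGroups:
    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"marker group {name!r} is empty")


def relative_heatmap(
    em: ExpressionMatrix,
    panel: MarkerPanel,
    population: str,
    mode: str = "max1",
    design: StageDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Gene x stage relative-expression matrix for one population.

    ``max1``: each row divided by its (positive) maximum, so the peak stage
    reads exactly 1. ``zscore``: rows centered and scaled to unit standard
    deviation (population formula); constant rows are an error.
    """
    if mode not in HEATMAP_MODES:
        raise ValueError(f"mode must be one of {HEATMAP_MODES}")
    missing = [g for g in panel.genes if g not in em.gene_ids]
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing}")
    traj = stage_trajectory_frame(em, design, population=population)
    rows = traj.loc[list(panel.genes)]
    if mode == "max1":
        rmax = rows.max(axis=1)
        if (rmax <= 0).any():
            bad = list(rmax.index[rmax <= 0])
            raise ValueError(f"non-positive row maximum for genes {bad}")
        return rows.div(rmax, axis=0)
    sd = rows.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant rows cannot be z-scored: {bad}")
    return rows.sub(rows.mean(axis=1), axis=0).div(sd, axis=0)


def mean_delta_ct(ct: CtTable, gene: str, stage: str, population: str) -> float:
    """dCT = mean replicate Ct of the gene minus mean replicate Ct of the reference."""
    cond = (ct.data["stage"] == stage) & (ct.data["population"] == population)
    gene_ct = ct.data.loc[cond & (ct.data["gene"] == gene), "ct"]
    ref_ct = ct.data.loc[cond & (ct.data["gene"] == ct.reference), "ct"]
    if gene_ct.empty:
        raise ValueError(f"no Ct for {gene!r} at ({stage}, {population})")
    if ref_ct.empty:
        raise ValueError(f"no reference Ct at ({stage}, {population})")
    return float(gene_ct.mean() - ref_ct.mean())


def fold_change(delta_ct: float | np.ndarray) -> float | np.ndarray:
    """Linear relative expression by the 2^-dCT rule."""
    return 2.0 ** (-np.asarray(delta_ct, dtype=float)) if np.ndim(delta_ct) else 2.0 ** (-delta_ct)


def qpcr_fold_table(ct: CtTable) -> pd.DataFrame:
    """Target genes x condition ('stage:population' columns) 2^-dCT folds."""
    conds = ct.conditions()
    genes = ct.target_genes()
    out = pd.DataFrame(
        index=pd.Index(genes, name="gene"),
        columns=[f"{s}:{p}" for s, p in conds], dtype=float,
    )
    for s, p in conds:
        for g in genes:
            out.loc[g, f"{s}:{p}"] = fold_change(mean_delta_ct(ct, g, s, p))
    return out


def fig3_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Double normalization to relative-abundance fractions.

    Step 1: each gene row divided by its total over every stage/population
    condition (relative expression across stages). Step 2: each condition
    column divided by its total across genes (relative abundance within a
    stage); every output column sums to 1.
    """
    vals = values.astype(float)
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative values are not valid relative expression")
    row_sums = vals.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError(f"all-zero genes: {list(row_sums.index[row_sums == 0])}")
    step1 = vals.div(row_sums, axis=0)
    col_sums = step1.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError(f"all-zero stages: {list(col_sums.index[col_sums == 0])}")
    return step1.div(col_sums, axis=1)


def collapse_groups(
    normalized: pd.DataFrame,
    groups: MarkerGroups,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Sum member-gene fractions per group; optionally renormalize columns to 1."""
    rows = {}
    for name, members in groups.groups.items():
        missing = [m for m in members if m not in normalized.index]
        if missing:
            raise ValueError(f"group {name!r} members absent: {missing}")
        rows[name] = normalized.loc[list(members)].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    if renormalize:
        out = out.div(out.sum(axis=0), axis=1)
    return out


def delta_delta_ct(ct: CtTable, gene: str, stage: str, population: str,
                   ref_stage: str, ref_population: str) -> float:
    """Convenience ddCT (2^-ddCT fold vs a calibrator condition)."""
    return mean_delta_ct(ct, gene, stage, population) - mean_delta_ct(
        ct, gene, ref_stage, ref_population
    )
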