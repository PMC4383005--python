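"""Stage-specific Notch-active (HES5+) and Notch-inactive gene selection.

All samples are first clustered with k-means on ES-subtracted log2
values; per gene and post-ES stage the HES5+/HES5- linear fold ratio
2^(delta_plus - delta_minus) is computed (both populations share the
unsorted ES baseline, which therefore cancels); per-cluster geometric-mean
fold profiles are screened with a dual threshold — average fold exceeding
``hi`` (default 1.4) at exactly one stage and below ``lo`` (default 1.2)
at every other stage — in both population directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign, DEFAULT_DESIGN, POP_PLUS, POP_MINUS
from .matrix import DeltaMatrix, ExpressionMatrix, stage_trajectory_frame
from .temporal_patterns import ClusterResult, kmeans_cluster, subtract_baseline

DIRECTIONS = ("plus_over_minus", "minus_over_plus")


@dataclass(frozen=True)
class SelectionParams:
    hi: float = 1.4  # linear fold a cluster must exceed at its specific stage
    lo: float = 1.2  # linear fold the cluster must stay under elsewhere
    k: int = 100
    seed: int = 0
    n_init: int = 10
    averaging: str = "mean_of_log"

    def __post_init__(self) -> None:
        if not (self.hi > self.lo > 1.0):
            raise ValueError("need hi > lo > 1")
        if self.averaging not in ("mean_of_log", "mean_of_linear"):
            raise ValueError(f"unknown averaging {self.averaging!r}")


@dataclass
class RatioMatrix:
    """Per-gene, per-post-ES-stage linear fold between the two populations."""

    folds: pd.DataFrame  # genes x post-ES stages, strictly positive
    direction: str

    def reciprocal(self) -> "RatioMatrix":
        other = DIRECTIONS[1] if self.direction == DIRECTIONS[0] else DIRECTIONS[0]
        return RatioMatrix(1.0 / self.folds, other)


@dataclass
class NotchSelection:
    """Selected clusters/genes per direction and stage, plus the fold table."""

    selected: dict[str, dict[str, dict]]  # direction -> stage -> {clusters, genes}
    cluster_profiles: dict[str, pd.DataFrame]  # direction -> cluster x stage folds
    clusters: ClusterResult | None = None
    params: SelectionParams | None = None

    def genes(self, direction: str, stage: str) -> list[str]:
        return self.selected.get(direction, {}).get(stage, {}).get("genes", [])


def stage_fold_ratios(
    delta: DeltaMatrix,
    direction: str = "plus_over_minus",
    design: StageDesign = DEFAULT_DESIGN,
) -> RatioMatrix:
    """Linear HES5+/HES5- (or reciprocal) folds from ES-subtracted log2 values."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    plus = stage_trajectory_frame(delta, design, POP_PLUS, include_baseline=False)
    minus = stage_trajectory_frame(delta, design, POP_MINUS, include_baseline=False)
    log_ratio = plus - minus
    if direction == "minus_over_plus":
        log_ratio = -log_ratio
    return RatioMatrix(np.exp2(log_ratio), direction)


def cluster_fold_profile(
    genes: list[str],
    ratios: RatioMatrix,
    averaging: str = "mean_of_log",
) -> pd.Series:
    """Per-stage average fold of a gene set (geometric mean by default)."""
    if len(genes) == 0:
        raise ValueError("empty cluster")
    sub = ratios.folds.loc[list(genes)]
    if averaging == "mean_of_log":
        return np.exp2(np.log2(sub).mean(axis=0))
    if averaging == "mean_of_linear":
        return sub.mean(axis=0)
    raise ValueError(f"unknown averaging {averaging!r}")


def select_specific_clusters(
    profiles: pd.DataFrame,
    params: SelectionParams = SelectionParams(),
) -> dict[int, str]:
    """Clusters whose fold profile exceeds ``hi`` at exactly one stage and stays
    below ``lo`` elsewhere (strict inequalities); returns cluster -> hi stage."""
    if profiles.shape[1] < 2:
        raise ValueError("need profiles over at least 2 stages")
    out: dict[int, str] = {}
    hi_mask = profiles > params.hi
    for cid in profiles.index:
        hits = list(profiles.columns[hi_mask.loc[cid]])
        if len(hits) != 1:
            continue
        stage = hits[0]
        others = profiles.loc[cid].drop(stage)
        if (others < params.lo).all():
            out[cid] = stage
    return out


def run_notch_pipeline(
    em: ExpressionMatrix,
    params: SelectionParams = SelectionParams(),
    design: StageDesign = DEFAULT_DESIGN,
) -> NotchSelection:
    """Full selection pipeline: shared k-means over all ES-subtracted samples,
    fold ratios in both directions, cluster profiles, dual-threshold screen."""
    delta = subtract_baseline(em, design=design)
    result = kmeans_cluster(delta.values, k=params.k, seed=params.seed, n_init=params.n_init)
    members: dict[int, list[str]] = {
        cid: genes
        for cid in result.centroids.index
        if (genes := list(result.assignment.index[result.assignment == cid]))
    }
    selected: dict[str, dict[str, dict]] = {}
    profiles_by_dir: dict[str, pd.DataFrame] = {}
    for direction in DIRECTIONS:
        ratios = stage_fold_ratios(delta, direction, design)
        profiles = pd.DataFrame(
            {cid: cluster_fold_profile(g, ratios, params.averaging)
             for cid, g in members.items()}
        ).T
        profiles.index.name = "cluster"
        profiles_by_dir[direction] = profiles
        picks = select_specific_clusters(profiles, params)
        per_stage: dict[str, dict] = {}
        for cid, stage in picks.items():
            entry = per_stage.setdefault(stage, {"clusters": [], "genes": []})
            entry["clusters"].append(cid)
            entry["genes"].extend(members[cid])
        selected[direction] = per_stage
    return NotchSelection(
        selected=selected, cluster_profiles=profiles_by_dir,
        clusters=result, params=params,
    )
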