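"""Stage-wise clustering and temporal-pattern classification.

Trajectories (per-gene log2 values over ordered stages, ES-subtracted)
are clustered with k-means; each cluster centroid is tested against a
grammar of trit codes over consecutive stage transitions — U (up by at
least theta log2 units), F (flat, |change| < theta), D (down by at least
theta), ``*`` wildcard — and member genes inherit their cluster's code.
The default grammar enumerates every single-onset upregulation: for each
transition a sustained variant (U then flat) and, where a later transition
remains, a transient variant (U then immediately D); for the six-stage
design this yields the eight codes UFFFF, UDFFF, FUFFF, FUDFF, FFUFF,
FFUDF, FFFUF, FFFFU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .design import StageDesign, DEFAULT_DESIGN
from .matrix import DeltaMatrix, ExpressionMatrix, stage_trajectory_frame

PATTERN_ALPHABET = frozenset("UFD*")


@dataclass(frozen=True)
class PatternCode:
    """Trit code over stage transitions with a log2 threshold theta."""

    code: str
    theta: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not set(self.code) <= PATTERN_ALPHABET:
            raise ValueError(f"invalid pattern code {self.code!r}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    def __len__(self) -> int:
        return len(self.code)


def default_pattern_set(design: StageDesign = DEFAULT_DESIGN, theta: float = 1.0) -> list[PatternCode]:
    """Single-onset upregulation grammar for a design's transitions.

    For T transitions: T sustained codes (one U, F elsewhere) plus T-2
    transient codes (U immediately followed by D, with at least one
    trailing F). Codes are pairwise mutually exclusive, so each
    trajectory matches at most one.
    """
    n = len(design.stages) - 1
    if n < 1:
        raise ValueError("design needs at least 2 stages")
    codes: list[PatternCode] = []
    for i in range(n):
        sustained = "F" * i + "U" + "F" * (n - i - 1)
        codes.append(PatternCode(sustained, theta, label=f"onset {design.stages[i + 1]}"))
        if i <= n - 3:
            transient = "F" * i + "UD" + "F" * (n - i - 2)
            codes.append(
                PatternCode(transient, theta, label=f"transient {design.stages[i + 1]}")
            )
    return codes


def subtract_baseline(
    em: ExpressionMatrix,
    baseline_stage: str | None = None,
    baseline_sample: str | None = None,
    design: StageDesign = DEFAULT_DESIGN,
) -> DeltaMatrix:
    """Reference every value to the gene's baseline-stage (ES) level."""
    stage = baseline_stage or design.baseline_stage
    if baseline_sample is None:
        candidates = em.samples_for(stage=stage)
        if len(candidates) == 0:
            raise ValueError(f"no sample for baseline stage {stage!r}")
        if len(candidates) > 1:
            raise ValueError(
                f"baseline stage {stage!r} has {len(candidates)} samples; "
                "designate one with baseline_sample"
            )
        baseline_sample = candidates[0]
    elif baseline_sample not in em.sample_ids:
        raise ValueError(f"baseline sample {baseline_sample!r} not in matrix")
    delta = em.values.sub(em.values[baseline_sample], axis=0)
    return DeltaMatrix(
        delta, em.sample_meta.copy(), baseline_stage=stage, baseline_sample=baseline_sample
    )


def transition_diffs(trajectory: np.ndarray | pd.Series, design: StageDesign = DEFAULT_DESIGN) -> np.ndarray:
    """Consecutive stage-to-stage differences of a stage-ordered trajectory."""
    arr = np.asarray(trajectory, dtype=float)
    if arr.shape[-1] != len(design.stages):
        raise ValueError(
            f"trajectory length {arr.shape[-1]} != number of stages {len(design.stages)}"
        )
    return np.diff(arr, axis=-1)


def match_pattern(diffs: np.ndarray, code: PatternCode) -> bool:
    """Test a transition-difference vector against one trit code."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape[0] != len(code):
        raise ValueError(f"{diffs.shape[0]} diffs vs code of length {len(code)}")
    t = code.theta
    for d, c in zip(diffs, code.code):
        if c == "U" and not d >= t:
            return False
        if c == "D" and not d <= -t:
            return False
        if c == "F" and not abs(d) < t:
            return False
    return True


@dataclass
class ClusterResult:
    """k-means partition: 1-based assignment plus exact member-mean centroids."""

    assignment: pd.Series  # gene -> cluster id in 1..k
    centroids: pd.DataFrame  # cluster id -> mean feature vector
    k: int
    seed: int
    n_init: int
    inertia: float


def kmeans_cluster(
    features: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterResult:
    """Lloyd's k-means (best of ``n_init`` seeded restarts) on a gene x feature frame.

    Centroids are recomputed as the exact mean of each cluster's members so
    the centroid/membership identity holds to numerical precision.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > features.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({features.shape[0]})")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed, max_iter=max_iter, tol=1e-6,
        algorithm="lloyd",
    ).fit(X)
    labels = km.labels_
    # duplicate points can leave a cluster label unused; keep sklearn's center
    centroids = np.vstack([
        X[labels == c].mean(axis=0) if (labels == c).any() else km.cluster_centers_[c]
        for c in range(k)
    ])
    inertia = float(((X - centroids[labels]) ** 2).sum())
    assignment = pd.Series(labels + 1, index=features.index, name="cluster")
    cent = pd.DataFrame(centroids, index=pd.RangeIndex(1, k + 1, name="cluster"),
                        columns=features.columns)
    return ClusterResult(assignment, cent, k=k, seed=seed, n_init=n_init, inertia=inertia)


@dataclass
class PatternAssignment:
    """Cluster-to-code matches, inherited gene codes and pattern families."""

    cluster_pattern: dict[int, str | None]
    gene_pattern: pd.Series  # gene -> code string or None
    n_classified: int
    n_matched_clusters: int
    families: dict[str, list[int]]  # code -> matched cluster ids
    clusters: ClusterResult | None = None

    def classified_genes(self) -> pd.Series:
        return self.gene_pattern.dropna()


def _match_first(diffs: np.ndarray, patterns: list[PatternCode]) -> str | None:
    for p in patterns:
        if match_pattern(diffs, p):
            return p.code
    return None


def classify_clusters(
    delta: DeltaMatrix,
    k: int,
    patterns: list[PatternCode],
    seed: int = 0,
    n_init: int = 10,
    design: StageDesign = DEFAULT_DESIGN,
    population: str = "HES5+",
) -> PatternAssignment:
    """Cluster Notch-active trajectories, then match centroids to codes.

    Features are the ES-subtracted per-stage values of the given population
    (baseline column included, all zeros). A cluster takes the first code
    in list order its centroid's transition diffs satisfy — with the
    mutually exclusive default grammar, order is immaterial — and genes
    inherit their cluster's code; unmatched clusters leave their genes
    unclassified.
    """
    traj = stage_trajectory_frame(delta, design, population=population)
    result = kmeans_cluster(traj, k=k, seed=seed, n_init=n_init)
    cluster_pattern: dict[int, str | None] = {}
    for cid in result.centroids.index:
        diffs = transition_diffs(result.centroids.loc[cid].to_numpy(), design)
        cluster_pattern[cid] = _match_first(diffs, patterns)
    gene_pattern = result.assignment.map(cluster_pattern)
    gene_pattern.name = "pattern"
    families: dict[str, list[int]] = {}
    for cid, code in cluster_pattern.items():
        if code is not None:
            families.setdefault(code, []).append(cid)
    return PatternAssignment(
        cluster_pattern=cluster_pattern,
        gene_pattern=gene_pattern,
        n_classified=int(gene_pattern.notna().sum()),
        n_matched_clusters=sum(v is not None for v in cluster_pattern.values()),
        families=families,
        clusters=result,
    )


def classify_genes_directly(
    delta: DeltaMatrix,
    patterns: list[PatternCode],
    design: StageDesign = DEFAULT_DESIGN,
    population: str = "HES5+",
) -> PatternAssignment:
    """Gene-level classification bypassing k-means (sensitivity mode)."""
    traj = stage_trajectory_frame(delta, design, population=population)
    diffs = np.diff(traj.to_numpy(dtype=float), axis=1)
    codes = [_match_first(d, patterns) for d in diffs]
    gene_pattern = pd.Series(codes, index=traj.index, name="pattern", dtype=object)
    families: dict[str, list[int]] = {}
    for code in gene_pattern.dropna().unique():
        families[code] = []
    return PatternAssignment(
        cluster_pattern={},
        gene_pattern=gene_pattern,
        n_classified=int(gene_pattern.notna().sum()),
        n_matched_clusters=0,
        families=families,
        clusters=None,
    )
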