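"""Synthetic staged two-population expression data with planted ground truth.

Emulates the structure the analysis assumes: six ordered stages, one
unsorted ES sample, one HES5+ and one HES5- sample per later stage
(single replicate per condition), log2 intensities with i.i.d. Gaussian
noise. Three kinds of genes are planted: background (flat baseline),
temporal-pattern genes whose HES5+ trajectory steps by +/- amplitude at
the transitions a trit code dictates (HES5- mirrors it, so pattern and
Notch planting stay orthogonal), and Notch-specific genes carrying an
extra log2 offset on one population at exactly one stage. Probe-level
tables and replicate Ct tables can be derived from a matrix with the same
seeding discipline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign, DEFAULT_DESIGN, POP_PLUS, POP_MINUS
from .matrix import ExpressionMatrix, meta_from_design
from .marker_qpcr import CtTable

# planted genes keep baselines clear of the expression filter's min_level
_PLANTED_BASELINE_FLOOR = 3.5


@dataclass(frozen=True)
class PatternPlant:
    code: str
    count: int
    amplitude: float = 2.0  # log2 step size at U/D transitions


@dataclass(frozen=True)
class NotchPlant:
    stage: str
    count: int
    direction: str = "plus"  # which population carries the offset
    offset: float = 1.0  # log2; linear fold 2**offset


@dataclass(frozen=True)
class SimConfig:
    n_background: int = 400
    planted_patterns: tuple[PatternPlant, ...] = ()
    planted_notch: tuple[NotchPlant, ...] = ()
    noise_sd: float = 0.1  # log2 units, i.i.d. per (gene, sample)
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive uniform range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0 or self.noise_sd < 0:
            raise ValueError("counts and noise_sd must be >= 0")
        for p in self.planted_patterns:
            if p.count < 0 or p.amplitude <= 0:
                raise ValueError("pattern plant needs count >= 0, amplitude > 0")
        for n in self.planted_notch:
            if n.direction not in ("plus", "minus"):
                raise ValueError("notch direction must be 'plus' or 'minus'")


@dataclass
class GroundTruth:
    """Planted structure per gene, consistent with the emitted matrix."""

    pattern: pd.Series  # gene -> code or NaN
    notch_stage: pd.Series  # gene -> stage or NaN
    notch_direction: pd.Series  # gene -> 'plus'/'minus' or NaN

    def pattern_genes(self, code: str | None = None) -> list[str]:
        s = self.pattern.dropna()
        return list(s.index if code is None else s.index[s == code])

    def notch_genes(self, stage: str | None = None, direction: str | None = None) -> list[str]:
        mask = self.notch_stage.notna()
        if stage is not None:
            mask &= self.notch_stage == stage
        if direction is not None:
            mask &= self.notch_direction == direction
        return list(self.notch_stage.index[mask])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pattern": self.pattern,
            "notch_stage": self.notch_stage,
            "notch_direction": self.notch_direction,
        })


def _code_trajectory(code: str, amplitude: float, n_stages: int) -> np.ndarray:
    steps = {"U": amplitude, "D": -amplitude, "F": 0.0}
    if len(code) != n_stages - 1:
        raise ValueError(f"code {code!r} does not fit {n_stages} stages")
    return np.concatenate([[0.0], np.cumsum([steps[c] for c in code])])


def simulate_expression(
    config: SimConfig, design: StageDesign = DEFAULT_DESIGN
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a matrix plus its ground truth; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    sample_ids = design.all_sample_ids()
    meta = meta_from_design(design, sample_ids)
    stages = list(design.stages)
    stage_of = meta["stage"].to_dict()
    pop_of = meta["population"].to_dict()

    names: list[str] = []
    rows: list[np.ndarray] = []
    pattern_gt: dict[str, str] = {}
    notch_gt: dict[str, tuple[str, str]] = {}

    def clean_row(baseline: float, plus_traj: np.ndarray, minus_traj: np.ndarray) -> np.ndarray:
        row = np.empty(len(sample_ids))
        for j, sid in enumerate(sample_ids):
            idx = stages.index(stage_of[sid])
            traj = minus_traj if pop_of[sid] == POP_MINUS else plus_traj
            row[j] = baseline + traj[idx]
        return row

    flat = np.zeros(len(stages))
    for i in range(config.n_background):
        b = rng.normal(config.baseline_mean, config.baseline_sd)
        names.append(f"BG{i + 1:04d}")
        rows.append(clean_row(b, flat, flat))

    for plant in config.planted_patterns:
        traj = _code_trajectory(plant.code, plant.amplitude, len(stages))
        for i in range(plant.count):
            b = max(rng.normal(config.baseline_mean, config.baseline_sd),
                    _PLANTED_BASELINE_FLOOR)
            name = f"PAT_{plant.code}_{i + 1:03d}"
            if name in pattern_gt:
                raise ValueError(f"duplicate pattern planting for {plant.code}")
            names.append(name)
            pattern_gt[name] = plant.code
            rows.append(clean_row(b, traj, traj))  # HES5- mirrors HES5+

    for plant in config.planted_notch:
        if plant.stage not in design.post_baseline_stages:
            raise ValueError(f"notch plant stage {plant.stage!r} not a post-ES stage")
        offset_traj = np.zeros(len(stages))
        offset_traj[stages.index(plant.stage)] = plant.offset
        for i in range(plant.count):
            b = max(rng.normal(config.baseline_mean, config.baseline_sd),
                    _PLANTED_BASELINE_FLOOR)
            name = f"NOTCH_{plant.direction}_{plant.stage}_{i + 1:03d}"
            if name in notch_gt:
                raise ValueError(f"contradictory notch plantings at {plant.stage}")
            names.append(name)
            notch_gt[name] = (plant.stage, plant.direction)
            if plant.direction == "plus":
                rows.append(clean_row(b, offset_traj, flat))
            else:
                rows.append(clean_row(b, flat, offset_traj))

    values = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(sample_ids))),
                          index=pd.Index(names, name="gene"), columns=sample_ids)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    em = ExpressionMatrix(values, meta)
    idx = em.gene_ids
    gt = GroundTruth(
        pattern=pd.Series({g: pattern_gt.get(g) for g in idx}, name="pattern", dtype=object),
        notch_stage=pd.Series({g: notch_gt[g][0] if g in notch_gt else None for g in idx},
                              name="notch_stage", dtype=object),
        notch_direction=pd.Series({g: notch_gt[g][1] if g in notch_gt else None for g in idx},
                                  name="notch_direction", dtype=object),
    )
    return em, gt


def simulate_probe_table(
    em: ExpressionMatrix, config: SimConfig
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expand genes to probes; one faithful probe per gene, extras jittered lower.

    Jittered probes sit strictly below the faithful probe's mean, so
    max-mean collapse inverts the expansion exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    lo, hi = config.probes_per_gene
    probe_rows: list[pd.Series] = []
    probe_map: dict[str, str] = {}
    for gene in em.gene_ids:
        n_probes = int(rng.integers(lo, hi + 1))
        base = em.values.loc[gene]
        for j in range(n_probes):
            pid = f"{gene}_p{j + 1}"
            probe_map[pid] = gene
            if j == 0:
                probe_rows.append(base.rename(pid))
            else:
                jitter = rng.normal(0.0, 0.1, size=len(base))
                drop = 0.5 + abs(rng.normal(0.0, 0.5))
                probe_rows.append((base + jitter - drop).rename(pid))
    probes = pd.DataFrame(probe_rows)
    probes.index.name = "probe"
    return ExpressionMatrix(probes, em.sample_meta.copy()), probe_map


def simulate_ct(
    folds: pd.DataFrame,
    reference: str = "HPRT",
    reference_ct: float = 20.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> CtTable:
    """Replicate Ct table from a gene x 'stage:population' linear-fold frame.

    The reference gene has constant Ct; a target's mean Ct is
    reference_ct - log2(fold), plus Gaussian replicate noise, so 2^-dCT
    recovers the planted fold in expectation.
    """
    rng = np.random.default_rng(seed)
    records = []
    for cond in folds.columns:
        stage, pop = str(cond).split(":", 1)
        for r in range(1, replicates + 1):
            records.append({"gene": reference, "stage": stage, "population": pop,
                            "replicate": r, "ct": reference_ct})
        for gene in folds.index:
            mean_ct = reference_ct - float(np.log2(folds.loc[gene, cond]))
            for r in range(1, replicates + 1):
                ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                records.append({"gene": gene, "stage": stage, "population": pop,
                                "replicate": r, "ct": ct})
    return CtTable(pd.DataFrame.from_records(records), reference=reference)
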