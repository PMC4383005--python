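"""Gene-by-sample expression containers with stage/population annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign

META_COLUMNS = ("stage", "population")


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes in rows, with per-sample (stage, population) metadata.

    ``values`` is a float DataFrame indexed by gene id with sample ids as
    columns; ``sample_meta`` is indexed by sample id with ``stage`` and
    ``population`` columns. Gene and sample ids must be unique, values
    finite, and every sample annotated.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        self.sample_meta = self.sample_meta.loc[self.values.columns, list(META_COLUMNS)]

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_for(self, stage: str | None = None, population: str | None = None) -> list[str]:
        """Sample ids matching the given stage and/or population."""
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if stage is not None:
            mask &= meta["stage"] == stage
        if population is not None:
            mask &= meta["population"] == population
        return list(meta.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.sample_meta.loc[sample_ids].copy()
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.sample_meta.copy())


@dataclass
class DeltaMatrix(ExpressionMatrix):
    """ExpressionMatrix after subtracting each gene's baseline-stage value.

    Baseline-stage columns are identically zero; all other values are
    log2 differences from the baseline (typically the ES sample).
    """

    baseline_stage: str = "ES"
    baseline_sample: str = ""


def meta_from_design(design: StageDesign, sample_ids: list[str]) -> pd.DataFrame:
    """Build sample_meta by parsing ``stage:population`` sample labels."""
    rows = {}
    for sid in sample_ids:
        stage, pop = design.parse_sample_id(sid)
        rows[sid] = {"stage": stage, "population": pop}
    return pd.DataFrame.from_dict(rows, orient="index")


def stage_trajectory_frame(
    em: ExpressionMatrix,
    design: StageDesign,
    population: str,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Genes x stages frame for one population, columns in design stage order.

    The baseline (first) stage usually has only an unsorted sample; when
    ``include_baseline`` is set that sample stands in for either population.
    Exactly one sample must resolve per requested stage.
    """
    cols: dict[str, str] = {}
    stages = design.stages if include_baseline else design.post_baseline_stages
    for stage in stages:
        sids = em.samples_for(stage=stage, population=population)
        if not sids and stage == design.baseline_stage and include_baseline:
            sids = em.samples_for(stage=stage)
        if len(sids) != 1:
            raise ValueError(
                f"need exactly one sample for stage {stage!r}, population "
                f"{population!r}; found {len(sids)}"
            )
        cols[stage] = sids[0]
    out = em.values[[cols[s] for s in stages]].copy()
    out.columns = list(stages)
    return out
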