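"""Variation/expression prefilter applied before all downstream analysis.

A gene is kept when its expression changes by at least ``min_range`` log2
units between some pair of samples (equivalently max - min >= min_range,
pooled over every stage and population) and reaches at least ``min_level``
log2 units in at least one sample. Both comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class FilterParams:
    min_range: float = 1.0  # log2 units
    min_level: float = 3.0  # log2 units

    def __post_init__(self) -> None:
        if self.min_range < 0 or self.min_level < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    n_fail_range: int
    n_fail_level: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_fail_range": self.n_fail_range,
            "n_fail_level": self.n_fail_level,
        }


def variation_filter(
    em: ExpressionMatrix, params: FilterParams = FilterParams()
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the range/level filter; gene order is preserved."""
    if em.n_genes == 0:
        raise ValueError("empty expression matrix")
    vmax = em.values.max(axis=1)
    vmin = em.values.min(axis=1)
    ok_range = (vmax - vmin) >= params.min_range
    ok_level = vmax >= params.min_level
    keep = ok_range & ok_level
    report = FilterReport(
        n_input=em.n_genes,
        n_retained=int(keep.sum()),
        n_fail_range=int((~ok_range).sum()),
        n_fail_level=int((~ok_level).sum()),
    )
    filtered = ExpressionMatrix(em.values.loc[keep].copy(), em.sample_meta.copy())
    return filtered, report
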