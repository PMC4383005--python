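"""Stage/population layout of a staged differentiation time course.

The default design mirrors a six-stage human ES-cell to neural-progenitor
progression — embryonic stem (ES), neuroepithelial (NE), early/mid/late
radial glia (E-RG, M-RG, L-RG) and long-term neural progenitors (LNP) —
where every post-ES stage is FACS-split into Notch-active (HES5+) and
Notch-inactive (HES5-) populations and the ES stage is unsorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_STAGES: tuple[str, ...] = ("ES", "NE", "E-RG", "M-RG", "L-RG", "LNP")
POP_PLUS = "HES5+"
POP_MINUS = "HES5-"
POP_UNSORTED = "unsorted"

# unicode minus / en-dash variants that show up in hand-edited tables
_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def _normalize_label(label: str) -> str:
    for bad, good in _MINUS_VARIANTS.items():
        label = label.replace(bad, good)
    return label.strip()


@dataclass(frozen=True)
class StageDesign:
    """Ordered stages and the populations available at each stage."""

    stages: tuple[str, ...] = DEFAULT_STAGES
    populations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if len(self.stages) < 1:
            raise ValueError("design needs at least one stage")
        if not self.populations:
            pops = {self.stages[0]: frozenset({POP_UNSORTED})}
            for s in self.stages[1:]:
                pops[s] = frozenset({POP_PLUS, POP_MINUS})
            object.__setattr__(self, "populations", pops)
        missing = [s for s in self.stages if s not in self.populations]
        if missing:
            raise ValueError(f"stages without populations: {missing}")

    @property
    def baseline_stage(self) -> str:
        return self.stages[0]

    @property
    def transitions(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.stages[:-1], self.stages[1:]))

    @property
    def post_baseline_stages(self) -> tuple[str, ...]:
        return self.stages[1:]

    def sample_id(self, stage: str, population: str) -> str:
        return f"{stage}:{population}"

    def parse_sample_id(self, label: str) -> tuple[str, str]:
        """Parse a ``stage:population`` sample label against this design."""
        norm = _normalize_label(label)
        if ":" not in norm:
            raise ValueError(
                f"sample label {label!r} is not of the form 'stage:population'"
            )
        stage, population = norm.split(":", 1)
        if stage not in self.populations:
            raise ValueError(f"unknown stage {stage!r} in sample label {label!r}")
        if population not in self.populations[stage]:
            raise ValueError(
                f"population {population!r} not defined for stage {stage!r} "
                f"(known: {sorted(self.populations[stage])})"
            )
        return stage, population

    def all_sample_ids(self) -> list[str]:
        out = []
        for s in self.stages:
            for p in sorted(self.populations[s]):
                out.append(self.sample_id(s, p))
        return out


DEFAULT_DESIGN = StageDesign()
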