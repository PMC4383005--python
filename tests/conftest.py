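import numpy as np
import pandas as pd
import pytest

from stagewise import DEFAULT_DESIGN, ExpressionMatrix
from stagewise.matrix import meta_from_design


@pytest.fixture
def design():
    return DEFAULT_DESIGN


@pytest.fixture
def sample_ids(design):
    return design.all_sample_ids()


def make_matrix(rows: dict[str, list[float]], design=DEFAULT_DESIGN) -> ExpressionMatrix:
    """Build an ExpressionMatrix from gene -> per-sample values (design order)."""
    sids = design.all_sample_ids()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sids, dtype=float)
    df.index.name = "gene"
    return ExpressionMatrix(df, meta_from_design(design, sids))


def trajectory_rows(stage_values: dict[str, list[float]], design=DEFAULT_DESIGN) -> dict:
    """Expand per-stage trajectories (same value for both populations) to samples."""
    out = {}
    for gene, traj in stage_values.items():
        vals = []
        for sid in design.all_sample_ids():
            stage, _pop = design.parse_sample_id(sid)
            vals.append(traj[design.stages.index(stage)])
        out[gene] = vals
    return out


@pytest.fixture
def random_matrix(design):
    rng = np.random.default_rng(42)
    sids = design.all_sample_ids()
    df = pd.DataFrame(rng.normal(5, 2, size=(200, len(sids))),
                      index=[f"g{i}" for i in range(200)], columns=sids)
    return ExpressionMatrix(df, meta_from_design(design, sids))
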