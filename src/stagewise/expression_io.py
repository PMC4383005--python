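"""Reading, writing and probe-collapsing expression tables.

Tables are genes-in-rows TSV/CSV with the first column holding gene (or
probe) ids and headers encoding samples as ``stage:population``; the GEO
Series Matrix text dialect is supported read-only with a user-supplied
sample map. Probe-level matrices are collapsed onto gene symbols, by
default keeping the probe with the highest mean intensity.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import pandas as pd

from .design import StageDesign, DEFAULT_DESIGN
from .matrix import ExpressionMatrix, meta_from_design

logger = logging.getLogger(__name__)

COLLAPSE_METHODS = ("max_mean_probe", "mean", "max_per_sample")


def _read_delimited(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric cell at gene {row!r}, sample {col!r} in {path}"
            )
        df[col] = coerced
    return df


def read_expression_table(
    path: str | Path,
    design: StageDesign = DEFAULT_DESIGN,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a genes-in-rows table whose headers are ``stage:population`` labels."""
    df = _read_delimited(path, sep=sep)
    meta = meta_from_design(design, list(df.columns))
    return ExpressionMatrix(df, meta)


def write_expression_table(em: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the matrix as a delimited table; round-trips with the reader."""
    em.values.to_csv(path, sep=sep, index_label="gene")


def read_geo_series_matrix(
    path: str | Path,
    design: StageDesign = DEFAULT_DESIGN,
    sample_map: dict[str, tuple[str, str]] | None = None,
    strict: bool = True,
) -> ExpressionMatrix:
    """Read the table block of a GEO Series Matrix text file.

    ``sample_map`` renames GEO sample accessions (GSM ids or sample titles)
    to ``(stage, population)`` pairs from the design. Values pass through
    unchanged — the caller knows whether the deposit is already log2.
    Samples absent from the map raise in ``strict`` mode and are dropped
    otherwise.
    """
    if sample_map is None:
        raise ValueError("a GEO sample id -> (stage, population) map is required")
    lines: list[str] = []
    in_table = False
    saw_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                saw_table = True
                continue
            if stripped.lower().startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table and stripped:
                lines.append(stripped)
    if not saw_table or not lines:
        raise ValueError(f"{path}: no series-matrix table block found")
    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
    # GEO quotes sample ids in the header row
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    df.index = [str(i).strip().strip('"') for i in df.index]

    keep, new_names = [], []
    for col in df.columns:
        if col in sample_map:
            stage, pop = sample_map[col]
            new_names.append(design.sample_id(stage, pop))
            keep.append(col)
        elif strict:
            raise ValueError(f"sample {col!r} not present in sample_map")
    df = df[keep]
    df.columns = new_names
    meta = meta_from_design(design, new_names)
    return ExpressionMatrix(df, meta)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe id, gene symbol) -> dict; blank symbols dropped."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "symbol"], dtype=str)
    df = df.dropna(subset=["symbol"])
    return dict(zip(df["probe"], df["symbol"]))


def collapse_probes(
    probes: ExpressionMatrix,
    probe_map: dict[str, str],
    method: str = "max_mean_probe",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix onto gene symbols.

    ``max_mean_probe`` (default) keeps, per symbol, the single probe row
    with the highest mean across samples; ``mean`` averages probe rows;
    ``max_per_sample`` takes the elementwise maximum. Probes without a
    mapped symbol are dropped and counted in the log. The number of output
    genes equals the number of distinct mapped symbols for every method.
    """
    if not probe_map:
        raise ValueError("empty probe map")
    if method not in COLLAPSE_METHODS:
        raise ValueError(f"unknown collapse method {method!r}; one of {COLLAPSE_METHODS}")
    symbols = pd.Series(
        [probe_map.get(p) for p in probes.gene_ids], index=probes.gene_ids, dtype=object
    )
    unmapped = symbols.isna()
    if unmapped.any():
        logger.info("collapse_probes: dropping %d unmapped probes", int(unmapped.sum()))
    vals = probes.values.loc[~unmapped]
    symbols = symbols[~unmapped]

    if method == "max_mean_probe":
        means = vals.mean(axis=1)
        # stable per-symbol argmax: first probe in input order wins ties
        order = pd.DataFrame({"symbol": symbols, "mean": means})
        best = order.groupby("symbol", sort=False)["mean"].idxmax()
        collapsed = vals.loc[best]
        collapsed.index = best.index
    elif method == "mean":
        collapsed = vals.groupby(symbols, sort=False).mean()
    else:  # max_per_sample
        collapsed = vals.groupby(symbols, sort=False).max()
    collapsed.index.name = "gene"
    return ExpressionMatrix(collapsed, probes.sample_meta.copy())
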