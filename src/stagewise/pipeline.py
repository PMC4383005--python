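"""Config-driven end-to-end runs with an auditable manifest.

``run_all`` executes probe collapse (optional) -> variation filter ->
ES-baseline subtraction -> temporal-pattern classification -> stage-
specific Notch selection -> optional marker heatmap, writing every
intermediate as TSV/JSON plus a manifest recording parameters, seeds,
input checksums and per-stage counts. Runs with the same config and seed
produce byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .design import StageDesign, DEFAULT_DESIGN
from .expression_io import (
    collapse_probes,
    read_expression_table,
    read_geo_series_matrix,
    read_probe_map,
    write_expression_table,
)
from .marker_qpcr import MarkerPanel, relative_heatmap
from .matrix import ExpressionMatrix
from .notch_selection import SelectionParams, run_notch_pipeline
from .prefilter import FilterParams, variation_filter
from .temporal_patterns import (
    PatternCode,
    classify_clusters,
    default_pattern_set,
    subtract_baseline,
)

# printed reference counts from the published analysis of GSE65369
GSE65369_PUBLISHED = {
    "gene_level_measurements": 19448,
    "filtered_gene_entries": 6371,
    "classified_genes": 495,
    "matched_clusters": 26,
}


@dataclass
class RunConfig:
    expression_path: str
    out_dir: str
    probe_map_path: str | None = None
    collapse_method: str = "max_mean_probe"
    filter_params: FilterParams = field(default_factory=FilterParams)
    pattern_codes: list[str] | None = None  # None -> default grammar
    theta: float = 1.0
    k: int = 100
    seed: int = 0
    n_init: int = 10
    selection: SelectionParams = field(default_factory=SelectionParams)
    heatmap_genes: list[str] | None = None
    heatmap_mode: str = "max1"
    heatmap_population: str = "HES5+"


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _patterns_for(config: RunConfig, design: StageDesign) -> list[PatternCode]:
    if config.pattern_codes is None:
        return default_pattern_set(design, theta=config.theta)
    return [PatternCode(c, theta=config.theta) for c in config.pattern_codes]


def run_all(config: RunConfig, design: StageDesign = DEFAULT_DESIGN) -> dict:
    """Run the whole pipeline; returns (and writes) the run manifest."""
    in_path = Path(config.expression_path)
    if not in_path.exists():
        raise FileNotFoundError(f"expression table not found: {in_path}")
    if config.probe_map_path and not Path(config.probe_map_path).exists():
        raise FileNotFoundError(f"probe map not found: {config.probe_map_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "design": {"stages": list(design.stages)},
        "inputs": {"expression": {"path": str(in_path), "sha256": _sha256(in_path)}},
        "parameters": {
            "collapse_method": config.collapse_method,
            "filter": {"min_range": config.filter_params.min_range,
                       "min_level": config.filter_params.min_level},
            "theta": config.theta, "k": config.k, "seed": config.seed,
            "n_init": config.n_init,
            "selection": {"hi": config.selection.hi, "lo": config.selection.lo,
                          "k": config.selection.k, "seed": config.selection.seed,
                          "averaging": config.selection.averaging},
        },
        "counts": {}, "outputs": [],
    }

    def stage_guard(name: str):
        class _Guard:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False
        return _Guard()

    with stage_guard("read"):
        em = read_expression_table(in_path, design)
        manifest["counts"]["n_input_rows"] = em.n_genes

    if config.probe_map_path:
        with stage_guard("collapse"):
            pm = read_probe_map(config.probe_map_path)
            manifest["inputs"]["probe_map"] = {
                "path": str(config.probe_map_path), "sha256": _sha256(config.probe_map_path)}
            em = collapse_probes(em, pm, method=config.collapse_method)
    manifest["counts"]["n_genes"] = em.n_genes

    with stage_guard("filter"):
        filtered, report = variation_filter(em, config.filter_params)
        manifest["counts"]["n_retained"] = report.n_retained
        write_expression_table(filtered, out / "filtered.tsv")
        _write_json(report.as_dict(), out / "filter_report.json")
        manifest["outputs"] += ["filtered.tsv", "filter_report.json"]

    with stage_guard("patterns"):
        delta = subtract_baseline(filtered, design=design)
        write_expression_table(delta, out / "delta.tsv")
        patterns = _patterns_for(config, design)
        k_eff = min(config.k, filtered.n_genes)
        assignment = classify_clusters(
            delta, k=k_eff, patterns=patterns, seed=config.seed,
            n_init=config.n_init, design=design,
        )
        tbl = pd.DataFrame({
            "cluster": assignment.clusters.assignment,
            "pattern": assignment.gene_pattern.fillna(""),
        })
        tbl["family"] = tbl["pattern"]
        tbl.index.name = "gene"
        tbl.to_csv(out / "pattern_assignment.tsv", sep="\t")
        manifest["counts"]["pattern_k_effective"] = k_eff
        manifest["counts"]["n_classified"] = assignment.n_classified
        manifest["counts"]["n_matched_clusters"] = assignment.n_matched_clusters
        manifest["outputs"] += ["delta.tsv", "pattern_assignment.tsv"]

    with stage_guard("notch"):
        sel_params = SelectionParams(
            hi=config.selection.hi, lo=config.selection.lo,
            k=min(config.selection.k, filtered.n_genes),
            seed=config.selection.seed, n_init=config.selection.n_init,
            averaging=config.selection.averaging,
        )
        selection = run_notch_pipeline(filtered, sel_params, design)
        sel_json = {
            d: {stage: {"clusters": sorted(e["clusters"]), "genes": sorted(e["genes"])}
                for stage, e in per_stage.items()}
            for d, per_stage in selection.selected.items()
        }
        _write_json(sel_json, out / "notch_selection.json")
        for d, prof in selection.cluster_profiles.items():
            prof.to_csv(out / f"cluster_folds_{d}.tsv", sep="\t")
            manifest["outputs"].append(f"cluster_folds_{d}.tsv")
        manifest["counts"]["notch_selected_genes"] = {
            d: {s: len(e["genes"]) for s, e in per_stage.items()}
            for d, per_stage in sel_json.items()
        }
        manifest["outputs"].append("notch_selection.json")

    if config.heatmap_genes:
        with stage_guard("markers"):
            panel = MarkerPanel(tuple(config.heatmap_genes))
            hm = relative_heatmap(em, panel, config.heatmap_population,
                                  mode=config.heatmap_mode, design=design)
            hm.to_csv(out / "marker_heatmap.tsv", sep="\t")
            manifest["outputs"].append("marker_heatmap.tsv")

    manifest["outputs"] = sorted(manifest["outputs"])
    _write_json(manifest, out / "manifest.json")
    return manifest


def reproduce_gse65369(
    series_matrix_path: str,
    sample_map_path: str,
    out_dir: str,
    probe_map_path: str | None = None,
    design: StageDesign = DEFAULT_DESIGN,
    seed: int = 0,
) -> dict:
    """Run the pipeline with published-analysis defaults on user-fetched
    GSE65369 files and juxtapose computed counts with the printed ones.

    Nothing is downloaded; the caller supplies the Series Matrix, a
    GSM -> (stage, population) map (TSV: sample_id, stage, population) and,
    if the deposit is probe-level, a probe -> symbol map. No equality is
    asserted — k-means is stochastic and the sample map is user-curated.
    """
    missing = [p for p in (series_matrix_path, sample_map_path) if not Path(p).exists()]
    if probe_map_path and not Path(probe_map_path).exists():
        missing.append(probe_map_path)
    if missing:
        raise FileNotFoundError(
            "missing accession artifacts: " + ", ".join(map(str, missing))
            + ". Expected: the GSE65369 Series Matrix text file, a "
            "sample_id<TAB>stage<TAB>population map, and (for probe-level "
            "deposits) a probe<TAB>gene-symbol map."
        )
    smap_df = pd.read_csv(sample_map_path, sep="\t", dtype=str)
    smap = {r.iloc[0]: (r.iloc[1], r.iloc[2]) for _, r in smap_df.iterrows()}
    em = read_geo_series_matrix(series_matrix_path, design, smap)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {"n_input_rows": em.n_genes}
    if probe_map_path:
        em = collapse_probes(em, read_probe_map(probe_map_path))
    counts["gene_level_measurements"] = em.n_genes
    filtered, report = variation_filter(em, FilterParams())
    counts["filtered_gene_entries"] = report.n_retained
    delta = subtract_baseline(filtered, design=design)
    k = min(100, filtered.n_genes)
    assignment = classify_clusters(delta, k=k, patterns=default_pattern_set(design),
                                   seed=seed, design=design)
    counts["classified_genes"] = assignment.n_classified
    counts["matched_clusters"] = assignment.n_matched_clusters
    selection = run_notch_pipeline(
        filtered, SelectionParams(k=min(100, filtered.n_genes), seed=seed), design)
    counts["notch_selected_genes"] = {
        d: sum(len(e["genes"]) for e in per_stage.values())
        for d, per_stage in selection.selected.items()
    }
    report_obj = {
        "parameters": {"min_range": 1.0, "min_level": 3.0, "theta": 1.0,
                       "k": k, "seed": seed, "hi": 1.4, "lo": 1.2},
        "computed": counts,
        "published": GSE65369_PUBLISHED,
        "note": "published counts are shown for juxtaposition only; no equality "
                "is asserted (stochastic clustering, user-supplied sample map)",
    }
    _write_json(report_obj, out / "gse65369_report.json")
    return report_obj
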