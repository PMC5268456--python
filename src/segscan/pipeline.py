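"""End-to-end pipeline: preprocessing, SEG calling, threshold grid, and the
optional enrichment / association stages, driven by one config object and
emitting a machine-readable JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import association, enrichment, matrix_io, preprocess, stability

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("segscan")


@dataclass
class PipelineConfig:
    """Inputs, outputs and parameters of one pipeline run.

    Optional stages (grid, enrichment, association) run only when their
    input paths are given.
    """

    matrix: str
    genes: str
    out_dir: str
    threshold: float = stability.DEFAULT_THRESHOLD
    trim_k: int = stability.DEFAULT_TRIM
    fdr: float = 0.05
    alternative: str = "two-sided"
    grid_thresholds: tuple[float, ...] = stability.DEFAULT_GRID_THRESHOLDS
    grid_trims: tuple[int, ...] = stability.DEFAULT_GRID_TRIMS
    run_grid: bool = True
    gene_sets: str | None = None
    homologs: str | None = None
    lethality: str | None = None
    scores: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be at least 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.trim_k < 0:
            raise ValueError("trim_k must be non-negative")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("grid_thresholds", "grid_trims"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _json_safe(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf" if value > 0 else "-inf"
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write stage outputs plus a
    JSON run report under ``config.out_dir``.

    Stage errors propagate as exceptions whose message names the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": []}

    def stage(name):
        log.info("stage %s: start", name)
        report["stages"].append(name)
        return time.monotonic()

    def done(name, t0):
        log.info("stage %s: done in %.2fs", name, time.monotonic() - t0)

    try:
        t0 = stage("preprocess")
        matrix = matrix_io.read_expression_matrix(config.matrix)
        genes = matrix_io.read_gene_table(config.genes)
        clean, pre_report = preprocess.preprocess_pipeline(matrix, genes)
        matrix_io.write_expression_matrix(clean, out_dir / "clean.tsv")
        report["preprocess"] = pre_report.to_dict()
        done("preprocess", t0)

        t0 = stage("stability")
        calls = stability.call_segs(clean, config.threshold, config.trim_k)
        calls.to_csv(out_dir / "segs.tsv", sep="\t")
        seg_set = set(calls.index[calls["is_seg"]])
        report["stability"] = {
            "threshold": config.threshold,
            "trim_k": config.trim_k,
            "n_genes": int(len(calls)),
            "n_segs": int(len(seg_set)),
        }
        done("stability", t0)

        if config.run_grid:
            t0 = stage("grid")
            grid = stability.seg_grid(clean, config.grid_thresholds, config.grid_trims)
            grid.to_frame().to_csv(out_dir / "grid.tsv", sep="\t")
            report["grid"] = {
                "thresholds": list(grid.thresholds),
                "trims": list(grid.trims),
                "counts": grid.counts.tolist(),
            }
            done("grid", t0)

        if config.gene_sets:
            t0 = stage("enrichment")
            collection = matrix_io.read_gene_sets(config.gene_sets)
            results = enrichment.enrich(seg_set, set(clean.gene_ids), collection)
            with open(out_dir / "enrichment.tsv", "w", encoding="utf-8") as handle:
                handle.write(
                    "set_name\tn_seg_in\tn_seg_out\tn_other_in\tn_other_out\t"
                    "odds_ratio\tp_value\tadjusted_p\n"
                )
                for r in results:
                    handle.write(
                        f"{r.set_name}\t{r.n_seg_in}\t{r.n_seg_out}\t{r.n_other_in}"
                        f"\t{r.n_other_out}\t{r.odds_ratio}\t{r.p_value}"
                        f"\t{r.adjusted_p}\n"
                    )
            report["enrichment"] = {
                "n_sets": len(collection),
                "n_significant": sum(1 for r in results if r.adjusted_p < config.fdr),
                "top": [
                    {
                        "set_name": r.set_name,
                        "odds_ratio": _json_safe(r.odds_ratio),
                        "p_value": r.p_value,
                        "adjusted_p": r.adjusted_p,
                    }
                    for r in results[:10]
                ],
            }
            done("enrichment", t0)

        if config.homologs and (config.lethality or config.scores):
            t0 = stage("association")
            homolog_map = matrix_io.read_two_column_table(
                config.homologs, value_kind="identifier"
            )
            mapped = association.map_homologs(seg_set, homolog_map)
            assoc_report: dict = {
                "n_seg_homologs": len(mapped.mapped),
                "n_seg_unmapped": mapped.n_unmapped,
            }
            if config.lethality:
                phenotype = matrix_io.read_two_column_table(
                    config.lethality, value_kind="boolean"
                )
                table = association.lethality_table(mapped.mapped, phenotype)
                result = association.two_by_two(table)
                assoc_report["lethality"] = {
                    "counts": [table.n_a, table.n_b, table.n_c, table.n_d],
                    "odds_ratio": _json_safe(result.odds_ratio),
                    "ci_low": _json_safe(result.ci_low),
                    "ci_high": _json_safe(result.ci_high),
                    "p_value": result.p_value,
                    "prop1": result.prop1,
                    "prop2": result.prop2,
                }
            if config.scores:
                scores = matrix_io.read_two_column_table(
                    config.scores, value_kind="numeric"
                )
                group = set(mapped.mapped) & scores.keys()
                rank = association.rank_compare(scores, group, config.alternative)
                assoc_report["rank_comparison"] = dataclasses.asdict(rank)
            report["association"] = assoc_report
            done("association", t0)
    except Exception as err:
        failed = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {err}") from err

    with open(out_dir / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    return report
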