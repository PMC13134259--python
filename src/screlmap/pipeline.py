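"""End-to-end orchestration: QC -> normalize -> specificity -> relevance ->
drivers (-> temporal / organs when stage or organ manifests are given).

`RunConfig` mirrors the config-file keys one-to-one; `run_pipeline` writes
every result as a TSV whose header comments echo the master seed, K, bin
counts and QC thresholds for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .dataio import (
    CellExpressionDataset,
    GeneAnnotation,
    load_cakut_gene_set,
    normalize_log1p,
    qc_filter,
    read_gene_lengths,
    read_gene_set,
    read_h5ad_dataset,
    read_mtx_dataset,
    write_result_tsv,
)
from .drivers import gene_score_correlation
from .errors import ConfigError
from .organs import overlap_analysis, top_k_genes
from .relevance import ControlConfig, score_and_associate
from .specificity import kruskal_wallis_specificity, top_type_enrichment
from .temporal import classify_temporal

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.  Keys mirror the YAML config file."""

    input_dir: str | None = None  # MTX bundle directory
    h5ad_path: str | None = None
    gene_set_path: str | None = None  # default: packaged CAKUT fixture
    length_table_path: str | None = None
    out_dir: str = "results/run"
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    target_sum: float = 10_000.0
    n_control_sets: int = 1000
    n_expr_bins: int = 20
    n_len_bins: int = 5
    match_length: bool = False
    exclude_seed_genes: bool = True
    min_cells_per_type: int = 10
    alpha: float = 0.05
    top_k: int = 100
    seed: int = 0
    stage_manifest: list[dict] = field(default_factory=list)
    organ_manifest: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "n_control_sets": self.n_control_sets,
            "n_expr_bins": self.n_expr_bins,
            "n_len_bins": self.n_len_bins,
            "match_length": self.match_length,
            "min_genes_per_cell": self.min_genes_per_cell,
            "min_cells_per_gene": self.min_cells_per_gene,
            "target_sum": self.target_sum,
            "version": __version__,
        }


def _load_dataset(config: RunConfig) -> CellExpressionDataset:
    if config.input_dir:
        d = Path(config.input_dir)
        for p in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "cell_meta.tsv"):
            if not (d / p).exists():
                raise ConfigError(f"missing input file {d / p}")
        return read_mtx_dataset(
            d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "cell_meta.tsv"
        )
    if config.h5ad_path:
        if not Path(config.h5ad_path).exists():
            raise ConfigError(f"missing input file {config.h5ad_path}")
        return read_h5ad_dataset(config.h5ad_path)
    raise ConfigError("config must set input_dir or h5ad_path")


def _load_gene_set(config: RunConfig):
    if config.gene_set_path:
        if not Path(config.gene_set_path).exists():
            raise ConfigError(f"missing gene-set file {config.gene_set_path}")
        return read_gene_set(config.gene_set_path)
    return load_cakut_gene_set()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on one dataset; returns a summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    ds = _load_dataset(config)
    gene_set = _load_gene_set(config)
    lengths: GeneAnnotation | None = None
    if config.length_table_path:
        if not Path(config.length_table_path).exists():
            raise ConfigError(f"missing length table {config.length_table_path}")
        lengths = read_gene_lengths(config.length_table_path)

    ds, qc_report = qc_filter(ds, config.min_genes_per_cell, config.min_cells_per_gene)
    ds = normalize_log1p(ds, config.target_sum)
    mapped, unmapped = gene_set.map_to(ds.gene_ids)

    spec = kruskal_wallis_specificity(
        ds, genes=mapped, alpha=config.alpha, min_cells_per_type=config.min_cells_per_type
    )
    write_result_tsv(spec.table, out / "specificity.tsv", prov, index_label="gene")
    write_result_tsv(spec.mean_expr, out / "mean_expression.tsv", prov, index_label="gene")
    write_result_tsv(spec.detection_rate, out / "detection_rate.tsv", prov, index_label="gene")
    enrich = top_type_enrichment(spec, ds, mapped)
    write_result_tsv(
        enrich.table,
        out / "top_type_enrichment.tsv",
        {**prov, "chi2": enrich.chi2_statistic, "p": enrich.p_value, "dof": enrich.dof},
        index_label="cell_type",
    )

    ccfg = ControlConfig(
        n_control_sets=config.n_control_sets,
        n_expr_bins=config.n_expr_bins,
        n_len_bins=config.n_len_bins,
        match_length=config.match_length,
        exclude_seed_genes=config.exclude_seed_genes,
        seed=config.seed,
    )
    scores, assoc, _ = score_and_associate(
        ds, mapped, ccfg, lengths=lengths, min_cells_per_type=config.min_cells_per_type
    )
    write_result_tsv(scores.table, out / "cell_scores.tsv", prov, index_label="cell")
    write_result_tsv(assoc.table, out / "association.tsv", prov, index_label="cell_type")

    drv = gene_score_correlation(ds, scores, seed_set=mapped)
    write_result_tsv(drv.table, out / "drivers.tsv", prov, index_label="gene")

    summary = {
        "n_cells": ds.n_cells,
        "n_genes": ds.n_genes,
        "qc_cells_removed": qc_report.n_cells_removed,
        "qc_genes_removed": qc_report.n_genes_removed,
        "n_gene_set_mapped": len(mapped),
        "n_gene_set_unmapped": len(unmapped),
        "chi2_statistic": enrich.chi2_statistic,
        "chi2_p": enrich.p_value,
        "min_association_p": float(assoc.table["empirical_p"].min()),
        "top_type": str(assoc.table["empirical_p"].idxmin()),
        **prov,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline complete: %s", json.dumps(summary))
    return summary


def run_organ_overlap(
    driver_tables: dict, gene_set_ids: list[str], k: int = 100
) -> "object":
    """Top-K overlap across organ driver tables (thin helper for the CLI)."""
    per_organ = {organ: top_k_genes(t, k) for organ, t in driver_tables.items()}
    return overlap_analysis(gene_set_ids, per_organ)


def run_temporal(stage_tables: list, stage_labels: list[str], r_early=5, drop_frac=0.10):
    return classify_temporal(stage_tables, stage_labels, r_early, drop_frac)
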