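"""Synthetic single-cell datasets with known ground truth.

The generator emulates the structure the downstream statistics rely on:
several annotated cell types of unequal abundance; negative-binomial counts
with log-normal per-gene baselines and per-cell log-normal library-size
factors; a planted "disease program" — a set of genes over-expressed by a
constant fold in designated cell types; and gene lengths either independent
of expression or rank-coupled to the per-gene baseline mean through a
Gaussian copula (the one-knob length confounder used to exercise the dual
expression+length matched null).  Multi-stage collections are produced by
varying the program fold across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .dataio import CellExpressionDataset, write_mtx_dataset, write_result_tsv
from .errors import ConfigError

# length distribution: log-normal around ~2.4 kb, typical of union-exon lengths
_LENGTH_LOG_MEAN = 7.8
_LENGTH_LOG_SD = 0.7


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``dispersion`` is the negative-binomial size (shape) parameter; variance
    of a count with mean mu is ``mu + mu**2 / dispersion``; ``np.inf`` gives
    the Poisson limit.  ``program_fold`` multiplies the mean of every program
    gene in every program cell type.  ``libsize_log_sd`` is the SD of the
    per-cell log-normal size factor, making library-size normalization
    non-trivial.
    """

    n_genes: int = 2000
    cell_type_sizes: Mapping[str, int] = field(
        default_factory=lambda: {f"type_{i}": 400 for i in range(5)}
    )
    baseline_log_mean: float = -1.5
    baseline_log_sd: float = 1.0
    dispersion: float = 2.0
    program_genes: Sequence[str] = ()
    program_types: Sequence[str] = ()
    program_fold: float = 1.0
    length_model: str = "independent"  # or "expression_correlated"
    length_rho: float = 0.0
    libsize_log_sd: float = 0.3
    seed: int = 0
    dataset_label: str = "synthetic"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if not self.cell_type_sizes or any(n <= 0 for n in self.cell_type_sizes.values()):
            raise ConfigError("cell_type_sizes must be positive")
        if self.program_fold <= 0:
            raise ConfigError(f"program_fold must be > 0, got {self.program_fold}")
        if self.length_model not in ("independent", "expression_correlated"):
            raise ConfigError(f"unknown length_model {self.length_model!r}")
        if not 0.0 <= self.length_rho <= 1.0:
            raise ConfigError("length_rho must lie in [0, 1]")
        universe = {self._gene_id(i) for i in range(self.n_genes)}
        bad = set(self.program_genes) - universe
        if bad:
            raise ConfigError(f"program_genes outside gene universe: {sorted(bad)[:5]}")
        bad_t = set(self.program_types) - set(self.cell_type_sizes)
        if bad_t:
            raise ConfigError(f"program_types not in cell_type_sizes: {sorted(bad_t)}")

    @staticmethod
    def _gene_id(i: int) -> str:
        return f"G{i:05d}"

    def gene_ids(self) -> pd.Index:
        return pd.Index([self._gene_id(i) for i in range(self.n_genes)])


@dataclass
class GroundTruth:
    program_genes: list[str]
    program_types: list[str]
    baseline_means: pd.Series  # gene_id -> baseline NB mean
    lengths: pd.Series  # gene_id -> length (bp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseline_mean": self.baseline_means,
                "length_bp": self.lengths,
                "is_program": self.baseline_means.index.isin(self.program_genes),
            }
        )


def _sample_lengths(
    cfg: SyntheticConfig, baseline: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gene lengths, optionally rank-coupled to baseline expression.

    Gaussian copula: normal scores of the baseline-mean ranks are mixed with
    independent noise at weight ``length_rho`` and mapped through a log-normal
    length marginal, so rho controls the Spearman correlation between length
    and expression without changing either marginal.
    """
    g = cfg.n_genes
    noise = rng.standard_normal(g)
    if cfg.length_model == "expression_correlated" and cfg.length_rho > 0:
        ranks = np.argsort(np.argsort(baseline)) + 1
        scores = norm.ppf((ranks - 0.5) / g)
        z = cfg.length_rho * scores + np.sqrt(1 - cfg.length_rho**2) * noise
    else:
        z = noise
    lengths = np.exp(_LENGTH_LOG_MEAN + _LENGTH_LOG_SD * z)
    return np.maximum(np.round(lengths), 200.0)


def generate_dataset(cfg: SyntheticConfig) -> tuple[CellExpressionDataset, GroundTruth]:
    """Draw one dataset and its ground truth, fully reproducible from seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = cfg.gene_ids()
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    lengths = _sample_lengths(cfg, baseline, rng)

    prog_gene_mask = gene_ids.isin(cfg.program_genes).astype(float)
    fold_vec = 1.0 + (cfg.program_fold - 1.0) * prog_gene_mask

    blocks, cell_ids, cell_types = [], [], []
    for ctype, n_cells in cfg.cell_type_sizes.items():
        mean_g = baseline * (fold_vec if ctype in cfg.program_types else 1.0)
        size_factors = rng.lognormal(0.0, cfg.libsize_log_sd, n_cells)
        mu = size_factors[:, None] * mean_g[None, :]
        if np.isinf(cfg.dispersion):
            block = rng.poisson(mu)
        else:
            r = cfg.dispersion
            block = rng.negative_binomial(r, r / (r + mu))
        blocks.append(sp.csr_matrix(block))
        cell_ids.extend(f"{ctype}_cell{j:05d}" for j in range(n_cells))
        cell_types.extend([ctype] * n_cells)

    obs = pd.DataFrame({"cell_type": cell_types}, index=pd.Index(cell_ids))
    ds = CellExpressionDataset(
        counts=sp.vstack(blocks, format="csr"),
        cell_ids=pd.Index(cell_ids),
        gene_ids=gene_ids,
        obs=obs,
        dataset_label=cfg.dataset_label,
    )
    truth = GroundTruth(
        program_genes=list(cfg.program_genes),
        program_types=list(cfg.program_types),
        baseline_means=pd.Series(baseline, index=gene_ids),
        lengths=pd.Series(lengths, index=gene_ids),
    )
    return ds, truth


def generate_stage_series(
    cfg_list: Sequence[SyntheticConfig], stage_labels: Sequence[str]
) -> tuple[list[CellExpressionDataset], list[GroundTruth]]:
    """One dataset per developmental stage over a shared gene universe.

    Program folds may differ by stage, planting early-peak (fold decreasing
    over stages) or late-rise (fold increasing) genes for the temporal
    classifier to recover.
    """
    if len(cfg_list) != len(stage_labels):
        raise ConfigError("need one config per stage label")
    universes = {cfg.n_genes for cfg in cfg_list}
    if len(universes) != 1:
        raise ConfigError(f"inconsistent gene universes across stages: {universes}")
    datasets, truths = [], []
    for cfg, label in zip(cfg_list, stage_labels):
        ds, truth = generate_dataset(cfg)
        ds.obs["stage"] = label
        ds.dataset_label = f"{cfg.dataset_label}:{label}"
        datasets.append(ds)
        truths.append(truth)
    return datasets, truths


def write_bundle(
    ds: CellExpressionDataset, truth: GroundTruth, cfg: SyntheticConfig, out_dir: str | Path
) -> Path:
    """Write the MTX/TSV bundle the readers consume, plus ground truth."""
    out = write_mtx_dataset(ds, out_dir)
    write_result_tsv(
        truth.to_frame(),
        Path(out) / "ground_truth.tsv",
        params={
            "seed": cfg.seed,
            "n_genes": cfg.n_genes,
            "program_fold": cfg.program_fold,
            "length_model": cfg.length_model,
            "length_rho": cfg.length_rho,
        },
        index_label="gene_id",
    )
    lengths = truth.lengths.rename("length_bp").to_frame()
    write_result_tsv(lengths, Path(out) / "gene_lengths.tsv", index_label="gene_id")
    return out
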