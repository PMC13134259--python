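"""Monte-Carlo matched-control disease-relevance scoring.

The observed statistic is how strongly a disease gene set is over-expressed
in each cell (and, aggregated, in each cell type).  Significance comes from
K random control gene sets in which every member is drawn from its seed
gene's mean-expression bin — optionally the joint (expression, gene-length)
bin, the dual-matched null that guards against long, highly detectable genes
inflating the signal.  Empirical p-values are (r + 1) / (K + 1) where r
counts null statistics at least as large as the observed one; z-scores are
standardized against the control distribution.  A companion heterogeneity
test asks whether the within-type variance of cell scores exceeds its
control null, flagging cell types that hide strongly scoring subpopulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataio import CellExpressionDataset, GeneAnnotation
from .errors import ContractError

logger = logging.getLogger(__name__)

DEFAULT_MIN_CELLS_PER_TYPE = 10


@dataclass
class ControlConfig:
    """Matched-control sampling parameters.

    K control sets (default 1000, the standard Monte-Carlo design for this
    kind of scoring), 20 mean-expression quantile bins, and — when
    ``match_length`` — 5 gene-length quantile bins crossed with them.
    """

    n_control_sets: int = 1000
    n_expr_bins: int = 20
    n_len_bins: int = 5
    match_length: bool = False
    exclude_seed_genes: bool = True
    min_bin_occupancy: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_control_sets < 1:
            raise ContractError("n_control_sets must be >= 1")
        if self.n_expr_bins < 1 or self.n_len_bins < 1:
            raise ContractError("bin counts must be >= 1")


@dataclass
class GeneBins:
    """Bin assignment per gene (expression bins, optionally x length bins)."""

    labels: pd.Series  # gene_id -> bin label (hashable tuple)
    n_expr_bins: int
    match_length: bool

    def members(self) -> dict[object, np.ndarray]:
        return {
            lab: idx.to_numpy()
            for lab, idx in self.labels.groupby(self.labels).groups.items()
        }


@dataclass
class ControlSetCollection:
    """K control gene lists matched bin-by-bin to the seed set."""

    sets: np.ndarray  # K x L array of gene-axis positions
    seed_positions: np.ndarray  # L positions of the mapped seed genes
    seed_bins: pd.Series  # seed gene id -> bin label
    gene_ids: pd.Index
    seed: int
    with_replacement_bins: list[object] = field(default_factory=list)

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def set_gene_ids(self, k: int) -> list[str]:
        return list(self.gene_ids[self.sets[k]])


@dataclass
class CellScoreTable:
    """Per-cell disease-relevance scores against the control null."""

    table: pd.DataFrame  # index cell; raw_score, norm_score, mc_p, sd_zero_flag
    control_raw: np.ndarray  # cells x K raw control scores
    control_norm: np.ndarray  # cells x K control scores standardized per cell

    @property
    def n_controls(self) -> int:
        return self.control_raw.shape[1]


@dataclass
class AssociationResult:
    """Per-cell-type association and heterogeneity statistics.

    Columns mirror the per-type report: observed statistic, control null mean
    and SD, z, one-sided empirical p, and the same for the within-type
    variance (heterogeneity) test.
    """

    table: pd.DataFrame
    n_controls: int
    excluded_types: list[str]


# ---------------------------------------------------------------------------
# binning and control sampling
# ---------------------------------------------------------------------------

def _quantile_codes(values: pd.Series, n_bins: int) -> pd.Series:
    ranks = values.rank(method="first")
    return pd.qcut(ranks, q=min(n_bins, len(values)), labels=False)


def bin_genes(
    mean_expr: pd.Series,
    cfg: ControlConfig,
    lengths: pd.Series | GeneAnnotation | None = None,
) -> GeneBins:
    """Quantile-bin genes by mean expression (and length when matching).

    ``mean_expr`` is the per-gene mean of the log-normalized layer over all
    cells.  Length bins are nested: computed as quantiles *within* each
    expression bin, so that a length-stratified control shares both its seed
    gene's expression stratum and its within-stratum length profile (the
    standard nested design for matching on two correlated covariates).
    Joint bins with fewer than ``min_bin_occupancy`` genes are merged into
    the nearest bin (length-neighbor within the same expression bin first,
    then expression-neighbor), keeping sampling well-defined on small gene
    universes.
    """
    cfg.validate()
    if isinstance(lengths, GeneAnnotation):
        lengths = lengths.lengths
    expr_codes = _quantile_codes(mean_expr, cfg.n_expr_bins)
    if not cfg.match_length:
        labels = pd.Series(
            [(int(e), 0) for e in expr_codes], index=mean_expr.index, dtype=object
        )
        return _merge_small_bins(labels, cfg.min_bin_occupancy, cfg.n_expr_bins)
    if lengths is None:
        raise ContractError("match_length=True requires gene lengths")
    missing = mean_expr.index.difference(lengths.index)
    if len(missing) > 0:
        raise ContractError(
            f"lengths missing for {len(missing)} genes, e.g. {list(missing[:5])}"
        )
    lengths = lengths.loc[mean_expr.index]
    len_codes = pd.Series(0, index=mean_expr.index)
    for e in expr_codes.unique():
        in_bin = expr_codes == e
        n_sub = min(cfg.n_len_bins, int(in_bin.sum()))
        len_codes[in_bin] = _quantile_codes(lengths[in_bin], n_sub)
    labels = pd.Series(
        [(int(e), int(l)) for e, l in zip(expr_codes, len_codes)],
        index=mean_expr.index,
        dtype=object,
    )
    return _merge_small_bins(labels, cfg.min_bin_occupancy, cfg.n_expr_bins)


def _merge_small_bins(labels: pd.Series, min_occupancy: int, n_expr_bins: int) -> GeneBins:
    """Repeatedly merge the smallest under-occupied bin into its nearest
    neighbor (length distance within the same expression bin counts less
    than expression distance; ties go to the lower label)."""
    labels = labels.copy()
    while True:
        counts = labels.value_counts()
        if len(counts) <= 1:
            break
        small = counts[counts < min_occupancy]
        if small.empty:
            break
        lab = small.sort_values().index[0]
        others = [b for b in counts.index if b != lab]
        dist = lambda b: (abs(b[0] - lab[0]), abs(b[1] - lab[1]), b)
        target = min(others, key=dist)
        labels = pd.Series(
            [target if b == lab else b for b in labels],
            index=labels.index,
            dtype=object,
        )
    match_length = any(b[1] != 0 for b in labels.unique())
    return GeneBins(labels=labels, n_expr_bins=n_expr_bins, match_length=match_length)


def sample_control_sets(
    gene_set_ids: list[str],
    bins: GeneBins,
    cfg: ControlConfig,
    gene_ids: pd.Index,
) -> ControlSetCollection:
    """Draw K control sets, one bin-matched control per seed gene.

    Within one control set, draws are without replacement inside a bin while
    its pool allows; an exhausted bin falls back to with-replacement and is
    logged.  Reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    seed_ids = [g for g in gene_set_ids if g in bins.labels.index]
    if len(seed_ids) == 0:
        raise ContractError("no gene-set members present in the binned universe")
    seed_bins = bins.labels.loc[seed_ids]
    pos = pd.Series(np.arange(len(gene_ids)), index=gene_ids)
    seed_positions = pos.loc[seed_ids].to_numpy()
    exclude = set(seed_ids) if cfg.exclude_seed_genes else set()

    members = bins.labels.groupby(bins.labels).groups  # label -> Index of gene ids
    sets = np.empty((cfg.n_control_sets, len(seed_ids)), dtype=np.int64)
    wr_bins: list[object] = []
    slot_of_seed = {g: i for i, g in enumerate(seed_ids)}
    for lab, seed_group in seed_bins.groupby(seed_bins).groups.items():
        pool_ids = [g for g in members[lab] if g not in exclude]
        if len(pool_ids) < 2:
            # a bin saturated by seed genes: exclusion is best-effort, so
            # fall back to the full bin membership rather than failing
            logger.warning(
                "bin %s has %d non-seed genes; control pool includes seed genes",
                lab,
                len(pool_ids),
            )
            pool_ids = list(members[lab])
        pool = pos.loc[pool_ids].to_numpy()
        slots = [slot_of_seed[g] for g in seed_group]
        need = len(slots)
        replace = need > len(pool)
        if replace:
            logger.warning(
                "bin %s exhausted (%d seeds, %d controls): sampling with replacement",
                lab,
                need,
                len(pool),
            )
            wr_bins.append(lab)
        for k in range(cfg.n_control_sets):
            draw = rng.choice(pool, size=need, replace=replace)
            sets[k, slots] = draw
    return ControlSetCollection(
        sets=sets,
        seed_positions=seed_positions,
        seed_bins=seed_bins,
        gene_ids=gene_ids,
        seed=cfg.seed,
        with_replacement_bins=wr_bins,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _set_score_matrix(N: sp.csr_matrix, sets: np.ndarray) -> np.ndarray:
    """cells x K matrix of mean expression over each control set's genes."""
    k, length = sets.shape
    rows = sets.ravel()
    cols = np.repeat(np.arange(k), length)
    weights = sp.csr_matrix(
        (np.full(rows.size, 1.0 / length), (rows, cols)), shape=(N.shape[1], k)
    )
    return np.asarray((N @ weights).todense())


def score_cells(
    ds: CellExpressionDataset,
    gene_set_ids: list[str],
    controls: ControlSetCollection,
) -> CellScoreTable:
    """Per-cell disease scores standardized against the K control sets.

    raw_score(i) is the mean log-normalized expression of the set genes in
    cell i; norm_score(i) standardizes it by the mean and SD of the K control
    raw scores of the same cell; mc_p(i) = (1 + #{k: control_k >= raw}) /
    (K + 1).  Cells whose control SD is zero get norm_score 0 and a flag.
    """
    N = ds.require_normalized()
    idx = ds.gene_indexer(gene_set_ids)
    # observed score goes through the same product path as the controls so
    # that a control set identical to the gene set scores bitwise equal
    raw = _set_score_matrix(N, idx[None, :])[:, 0]
    control_raw = _set_score_matrix(N, controls.sets)
    mu = control_raw.mean(axis=1)
    sd = control_raw.std(axis=1, ddof=1)
    # identical control columns can leave sd ~1 ulp above zero; treat
    # negligible spread (relative to the control-mean scale) as degenerate
    sd_zero = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
    if sd_zero.any():
        logger.warning("%d cells have zero control-score SD", int(sd_zero.sum()))
    safe_sd = np.where(sd_zero, 1.0, sd)
    norm = np.where(sd_zero, 0.0, (raw - mu) / safe_sd)
    control_norm = (control_raw - mu[:, None]) / safe_sd[:, None]
    k = control_raw.shape[1]
    mc_p = (1 + (control_raw >= raw[:, None]).sum(axis=1)) / (k + 1)
    table = pd.DataFrame(
        {
            "raw_score": raw,
            "norm_score": norm,
            "mc_p": mc_p,
            "sd_zero_flag": sd_zero,
        },
        index=ds.cell_ids.rename("cell"),
    )
    return CellScoreTable(table=table, control_raw=control_raw, control_norm=control_norm)


def empirical_p_and_z(observed: float, null_values) -> tuple[float, float]:
    """One-sided empirical p (enrichment direction) and z against a null.

    p = (1 + #{null >= observed}) / (n + 1); z = (observed - mean) / sd with
    the sample SD.  With a single null value or zero SD the z is undefined
    and returned as NaN; p is still valid.
    """
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size == 0:
        raise ContractError("empirical_p_and_z needs a non-empty null sample")
    p = float((1 + (nulls >= observed).sum()) / (nulls.size + 1))
    if nulls.size < 2:
        return p, float("nan")
    sd = nulls.std(ddof=1)
    if sd == 0:
        return p, float("nan")
    return p, float((observed - nulls.mean()) / sd)


def _per_type_stats(
    values: np.ndarray,
    control_values: np.ndarray,
    cell_types: pd.Series,
    min_cells_per_type: int,
    aggregator,
) -> tuple[pd.DataFrame, list[str]]:
    ct = cell_types.to_numpy()
    rows = []
    excluded = []
    for t in pd.unique(ct):
        mask = ct == t
        if mask.sum() < min_cells_per_type:
            excluded.append(str(t))
            continue
        obs = aggregator(values[mask])
        nulls = aggregator(control_values[mask], axis=0)
        p, z = empirical_p_and_z(obs, nulls)
        rows.append(
            {
                "cell_type": t,
                "n_cells": int(mask.sum()),
                "observed": float(obs),
                "null_mean": float(nulls.mean()),
                "null_sd": float(nulls.std(ddof=1)) if nulls.size > 1 else float("nan"),
                "z": z,
                "empirical_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type"), excluded


def celltype_association(
    scores: CellScoreTable,
    cell_types: pd.Series,
    min_cells_per_type: int = DEFAULT_MIN_CELLS_PER_TYPE,
) -> AssociationResult:
    """Type-level association and heterogeneity against the control null.

    Association: observed statistic is the mean norm_score over the type's
    cells; the k-th null statistic applies the same mean to control set k's
    per-cell standardized scores.  Heterogeneity: the statistic is the
    within-type variance of norm_score, nulls likewise.  Both one-sided
    (enrichment / excess-dispersion direction), p = (r + 1) / (K + 1).
    """
    if len(cell_types) != len(scores.table):
        raise ContractError("cell_types length does not match score table")
    values = scores.table["norm_score"].to_numpy()
    assoc, excluded = _per_type_stats(
        values, scores.control_norm, cell_types, min_cells_per_type, np.mean
    )
    var = lambda x, axis=None: np.var(x, axis=axis, ddof=1)
    het, _ = _per_type_stats(
        values, scores.control_norm, cell_types, min_cells_per_type, var
    )
    table = assoc.join(
        het[["observed", "z", "empirical_p"]].rename(
            columns={
                "observed": "heterogeneity_statistic",
                "z": "heterogeneity_z",
                "empirical_p": "heterogeneity_p",
            }
        )
    )
    if excluded:
        logger.warning("types excluded (fewer than %d cells): %s", min_cells_per_type, excluded)
    return AssociationResult(
        table=table, n_controls=scores.n_controls, excluded_types=excluded
    )


def score_and_associate(
    ds: CellExpressionDataset,
    gene_set_ids: list[str],
    cfg: ControlConfig,
    lengths: pd.Series | GeneAnnotation | None = None,
    min_cells_per_type: int = DEFAULT_MIN_CELLS_PER_TYPE,
) -> tuple[CellScoreTable, AssociationResult, ControlSetCollection]:
    """Convenience wrapper: bin genes, sample controls, score, associate."""
    N = ds.require_normalized()
    mean_expr = pd.Series(np.asarray(N.mean(axis=0)).ravel(), index=ds.gene_ids)
    bins = bin_genes(mean_expr, cfg, lengths=lengths)
    controls = sample_control_sets(gene_set_ids, bins, cfg, ds.gene_ids)
    mapped = [g for g in gene_set_ids if g in bins.labels.index]
    scores = score_cells(ds, mapped, controls)
    assoc = celltype_association(scores, ds.cell_type, min_cells_per_type)
    return scores, assoc, controls
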