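"""Per-gene cell-type specificity statistics and the top-type enrichment test.

For each gene, a tie-corrected Kruskal–Wallis test asks whether the
distribution of log-normalized expression differs between annotated cell
types (H0: identical distributions across types); Benjamini–Hochberg controls
the FDR across the tested gene list.  Alongside the test, per-type mean
expression and detection-rate matrices describe where each gene is expressed,
and a chi-squared goodness-of-fit test asks whether "top-expressing cell
type" assignments over a gene set deviate from the background cell-type
abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, rankdata
from statsmodels.stats.multitest import multipletests

from .dataio import CellExpressionDataset
from .errors import ContractError

logger = logging.getLogger(__name__)

DEFAULT_MIN_CELLS_PER_TYPE = 10


@dataclass
class SpecificityResult:
    """Per-gene specificity table plus the per-type summary matrices."""

    table: pd.DataFrame  # index gene; kw_statistic, p_value, fdr, significant, top_cell_type
    mean_expr: pd.DataFrame  # genes x types, log-normalized units
    detection_rate: pd.DataFrame  # genes x types, in [0, 1]
    alpha: float
    excluded_types: list[str]


@dataclass
class TopTypeEnrichment:
    """Observed vs expected counts of top-expressing-type assignments."""

    table: pd.DataFrame  # index type; observed, expected, oe_ratio
    chi2_statistic: float
    p_value: float
    dof: int
    pooled_types: list[str]


def _resolve_genes(ds: CellExpressionDataset, genes) -> list[str]:
    if genes is None or (isinstance(genes, str) and genes == "all"):
        return list(ds.gene_ids)
    wanted = list(genes)
    present = [g for g in wanted if g in ds.gene_ids]
    missing = sorted(set(wanted) - set(present))
    if missing:
        logger.warning("excluding %d unmapped genes: %s...", len(missing), missing[:5])
    return present


def _type_groups(ds: CellExpressionDataset) -> dict[str, np.ndarray]:
    ct = ds.cell_type.to_numpy()
    return {t: np.flatnonzero(ct == t) for t in pd.unique(ct)}


def mean_expression_by_type(ds: CellExpressionDataset, genes="all") -> pd.DataFrame:
    """Gene x type matrix of mean log-normalized expression."""
    N = ds.require_normalized()
    sel = _resolve_genes(ds, genes)
    idx = ds.gene_indexer(sel)
    groups = _type_groups(ds)
    cols = {}
    for t, rows in groups.items():
        if len(rows) == 0:
            logger.warning("cell type %r has no cells; excluded", t)
            continue
        cols[t] = np.asarray(N[rows][:, idx].mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=pd.Index(sel, name="gene"))


def detection_rate_by_type(ds: CellExpressionDataset, genes="all") -> pd.DataFrame:
    """Gene x type matrix of the fraction of cells with nonzero counts."""
    sel = _resolve_genes(ds, genes)
    idx = ds.gene_indexer(sel)
    detected = (ds.counts > 0).astype(float)
    groups = _type_groups(ds)
    cols = {
        t: np.asarray(detected[rows][:, idx].mean(axis=0)).ravel()
        for t, rows in groups.items()
        if len(rows) > 0
    }
    return pd.DataFrame(cols, index=pd.Index(sel, name="gene"))


def _kruskal_wallis_matrix(
    values: np.ndarray, group_codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected KW over the columns of ``values``.

    Returns (H, p).  Columns where every value is identical (tie-correction
    denominator zero) get H=0, p=1 by convention.
    """
    n, g = values.shape
    ranks = rankdata(values, axis=0)
    onehot = np.zeros((n_groups, n), dtype=float)
    onehot[group_codes, np.arange(n)] = 1.0
    group_sizes = onehot.sum(axis=1)  # (k,)
    rank_sums = onehot @ ranks  # k x g
    h = 12.0 / (n * (n + 1)) * ((rank_sums**2) / group_sizes[:, None]).sum(axis=0) - 3.0 * (
        n + 1
    )
    # tie correction per column
    corr = np.empty(g)
    for j in range(g):
        _, counts = np.unique(values[:, j], return_counts=True)
        corr[j] = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    degenerate = corr <= 0
    h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, corr))
    h = np.maximum(h, 0.0)
    p = chi2.sf(h, df=n_groups - 1)
    p = np.where(degenerate, 1.0, p)
    return h, p


def kruskal_wallis_specificity(
    ds: CellExpressionDataset,
    genes="all",
    alpha: float = 0.05,
    min_cells_per_type: int = DEFAULT_MIN_CELLS_PER_TYPE,
) -> SpecificityResult:
    """Tie-corrected KW test per gene, BH adjustment across the tested list.

    Types with fewer than ``min_cells_per_type`` cells are excluded from the
    test (and flagged); at least two eligible types are required.  The
    ``top_cell_type`` is the type maximizing mean log-normalized expression,
    ties broken by larger detection rate, then lexicographic type name.
    """
    N = ds.require_normalized()
    sel = _resolve_genes(ds, genes)
    idx = ds.gene_indexer(sel)

    groups = _type_groups(ds)
    eligible = {t: rows for t, rows in groups.items() if len(rows) >= min_cells_per_type}
    excluded = sorted(set(groups) - set(eligible))
    if excluded:
        logger.warning(
            "excluding %d cell types below %d cells: %s",
            len(excluded),
            min_cells_per_type,
            excluded,
        )
    if len(eligible) < 2:
        raise ContractError(
            f"Kruskal-Wallis needs >= 2 cell types with >= {min_cells_per_type} "
            f"cells; found {len(eligible)}"
        )
    types = sorted(eligible)
    rows = np.concatenate([eligible[t] for t in types])
    codes = np.concatenate(
        [np.full(len(eligible[t]), k) for k, t in enumerate(types)]
    )
    values = np.asarray(N[rows][:, idx].todense())
    h, p = _kruskal_wallis_matrix(values, codes, len(types))
    fdr = multipletests(p, method="fdr_bh")[1]

    mean_expr = mean_expression_by_type(ds, sel)
    det = detection_rate_by_type(ds, sel)
    top = _top_cell_type(mean_expr, det)

    table = pd.DataFrame(
        {
            "kw_statistic": h,
            "p_value": p,
            "fdr": fdr,
            "significant": fdr < alpha,
            "top_cell_type": top.loc[sel].to_numpy(),
        },
        index=pd.Index(sel, name="gene"),
    )
    return SpecificityResult(
        table=table,
        mean_expr=mean_expr,
        detection_rate=det,
        alpha=alpha,
        excluded_types=excluded,
    )


def _top_cell_type(mean_expr: pd.DataFrame, detection: pd.DataFrame) -> pd.Series:
    """Argmax type per gene; ties by detection rate, then type name."""
    types = list(mean_expr.columns)
    out = []
    me = mean_expr.to_numpy()
    de = detection[types].to_numpy()
    for i in range(me.shape[0]):
        best = me[i].max()
        cand = [j for j in range(len(types)) if me[i, j] == best]
        if len(cand) > 1:
            best_det = max(de[i, j] for j in cand)
            cand = [j for j in cand if de[i, j] == best_det]
            if len(cand) > 1:
                logger.debug("top-type tie for gene %s", mean_expr.index[i])
        out.append(min((types[j] for j in cand)))
    return pd.Series(out, index=mean_expr.index)


def top_type_enrichment(
    spec: SpecificityResult,
    ds: CellExpressionDataset,
    gene_set: list[str],
    min_expected: float = 1.0,
) -> TopTypeEnrichment:
    """Chi-squared GOF of top-type counts against cell-type abundances.

    expected[c] = |set| * n_cells(c) / n_cells.  Types with expected count
    below ``min_expected`` are pooled into an "other" category before the
    test (classical validity rule); observed/expected ratios are reported
    unpooled.
    """
    genes = [g for g in gene_set if g in spec.table.index]
    if len(genes) == 0:
        raise ContractError("empty gene set for top-type enrichment")
    counts = ds.cell_type.value_counts()
    types = list(spec.mean_expr.columns)
    n_total = int(counts.loc[types].sum())
    observed = (
        spec.table.loc[genes, "top_cell_type"].value_counts().reindex(types).fillna(0.0)
    )
    expected = counts.loc[types] / n_total * len(genes)
    table = pd.DataFrame(
        {
            "observed": observed.astype(float),
            "expected": expected.astype(float),
            "oe_ratio": observed / expected,
        }
    )
    table.index.name = "cell_type"

    pool_mask = expected < min_expected
    pooled_types = sorted(expected.index[pool_mask])
    obs_cells = observed[~pool_mask].to_list()
    exp_cells = expected[~pool_mask].to_list()
    if pool_mask.any():
        obs_cells.append(float(observed[pool_mask].sum()))
        exp_cells.append(float(expected[pool_mask].sum()))
    obs_arr, exp_arr = np.asarray(obs_cells), np.asarray(exp_cells)
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    dof = len(obs_arr) - 1
    p = float(chi2.sf(stat, df=dof)) if dof > 0 else 1.0
    return TopTypeEnrichment(
        table=table, chi2_statistic=stat, p_value=p, dof=dof, pooled_types=pooled_types
    )
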