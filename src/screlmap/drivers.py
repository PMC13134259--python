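"""Driver-gene ranking: correlation of expression with per-cell disease scores.

Genes whose expression tracks the standardized disease-relevance score across
cells are the candidates driving a cell-type enrichment signal.  Rankings
from two datasets (e.g. embryonic vs adult kidney) are compared gene-by-gene
with quadrant labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataio import CellExpressionDataset
from .errors import ContractError
from .relevance import CellScoreTable

logger = logging.getLogger(__name__)

DEFAULT_QUADRANT_MARGIN = 0.05


@dataclass
class DriverTable:
    """Per-gene correlation with the disease score and the resulting rank."""

    table: pd.DataFrame  # index gene; pearson_r, rank, in_seed_set
    excluded_genes: list[str]  # zero-variance genes
    label: str = ""

    def __len__(self) -> int:
        return len(self.table)


def gene_score_correlation(
    ds: CellExpressionDataset,
    scores: CellScoreTable,
    genes="all",
    seed_set: list[str] | None = None,
    method: str = "pearson",
) -> DriverTable:
    """Correlate each gene's log-normalized expression with norm_score.

    Correlation is against the standardized score (invariant to control-set
    location/scale).  Constant genes are excluded and listed.  Ranks are
    1 = highest r, ties broken by gene ID.  ``method`` is ``pearson``
    (default) or ``spearman`` for heavy-tailed expression.
    """
    N = ds.require_normalized()
    if len(scores.table) != ds.n_cells:
        raise ContractError("score table does not match dataset cells")
    if genes is None or (isinstance(genes, str) and genes == "all"):
        sel = list(ds.gene_ids)
    else:
        sel = [g for g in genes if g in ds.gene_ids]
    idx = ds.gene_indexer(sel)
    X = np.asarray(N[:, idx].todense())
    s = scores.table["norm_score"].to_numpy().astype(float)
    if method == "spearman":
        X = rankdata(X, axis=0)
        s = rankdata(s)
    elif method != "pearson":
        raise ContractError(f"unknown correlation method {method!r}")
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    sc = s - s.mean()
    sx = xc.std(axis=0)
    ss = sc.std()
    if ss == 0:
        raise ContractError("disease score vector is constant")
    var_ok = sx > 0
    r = np.full(len(sel), np.nan)
    r[var_ok] = (xc[:, var_ok].T @ sc) / (n * sx[var_ok] * ss)
    excluded = [g for g, ok in zip(sel, var_ok) if not ok]
    if excluded:
        logger.info("excluding %d constant genes from driver ranking", len(excluded))
    kept = [g for g, ok in zip(sel, var_ok) if ok]
    table = pd.DataFrame(
        {"pearson_r": r[var_ok]}, index=pd.Index(kept, name="gene")
    )
    # descending r; ties broken by ascending gene id
    order = table.reset_index().sort_values(
        ["pearson_r", "gene"], ascending=[False, True], kind="mergesort"
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order["gene"])
    table["rank"] = ranks.loc[table.index].to_numpy()
    seed = set(seed_set or [])
    table["in_seed_set"] = table.index.isin(seed)
    return DriverTable(table=table, excluded_genes=excluded, label=ds.dataset_label)


def compare_rankings(
    table_a: DriverTable,
    table_b: DriverTable,
    margin: float = DEFAULT_QUADRANT_MARGIN,
) -> pd.DataFrame:
    """Per-gene comparison of two driver tables with quadrant labels.

    Genes farther than ``margin`` (in r units) from the diagonal are labeled
    ``a_specific`` / ``b_specific``; on-diagonal genes are labeled by joint
    sign (``both_positive`` / ``both_negative`` / ``mixed``).  Swapping the
    inputs swaps the a/b-specific labels.
    """
    common = table_a.table.index.intersection(table_b.table.index)
    if len(common) == 0:
        raise ContractError("driver tables share no genes")
    logger.info("comparing rankings on %d shared genes", len(common))
    ra = table_a.table.loc[common, "pearson_r"]
    rb = table_b.table.loc[common, "pearson_r"]
    diff = ra - rb
    label = np.where(
        diff > margin,
        "a_specific",
        np.where(
            diff < -margin,
            "b_specific",
            np.where(
                (ra > 0) & (rb > 0),
                "both_positive",
                np.where((ra < 0) & (rb < 0), "both_negative", "mixed"),
            ),
        ),
    )
    return pd.DataFrame(
        {"r_a": ra, "r_b": rb, "quadrant": label}, index=common.rename("gene")
    )
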