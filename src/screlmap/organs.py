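"""Cross-organ overlap prioritization.

Per organ, the top-K genes of a ranking table are intersected with the
disease gene set; members found in exactly one organ's intersection are
organ-specific candidates, and members found in every organ's intersection
are shared cross-organ candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .drivers import DriverTable
from .errors import ContractError

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 100


@dataclass
class OverlapResult:
    top_k: dict[str, list[str]]  # organ -> top-K gene list
    overlap_with_set: dict[str, list[str]]  # organ -> top-K ∩ disease set
    organ_specific_candidates: dict[str, list[str]]
    shared_all_organs: list[str]
    k: int

    def counts(self) -> pd.DataFrame:
        rows = [
            {
                "organ": organ,
                "n_top": len(self.top_k[organ]),
                "n_overlap": len(self.overlap_with_set[organ]),
                "n_specific": len(self.organ_specific_candidates[organ]),
            }
            for organ in self.top_k
        ]
        return pd.DataFrame(rows).set_index("organ")


def top_k_genes(table: DriverTable | pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """First K genes by rank; rank ties broken by gene ID (logged).

    If the table holds fewer than K genes, all are returned with a warning.
    """
    df = table.table if isinstance(table, DriverTable) else table
    if "rank" not in df.columns:
        raise ContractError("ranking table lacks a 'rank' column")
    if len(df) < k:
        logger.warning("requested top %d of %d genes; returning all", k, len(df))
        k = len(df)
    order = df.reset_index().sort_values(
        ["rank", df.index.name or "index"], kind="mergesort"
    )
    return order[df.index.name or "index"].head(k).tolist()


def overlap_analysis(
    gene_set_ids: Sequence[str],
    per_organ_top: Mapping[str, Sequence[str]],
) -> OverlapResult:
    """Set algebra over per-organ top lists against the disease set."""
    if len(per_organ_top) == 0:
        raise ContractError("need at least one organ top list")
    gene_set = list(dict.fromkeys(gene_set_ids))
    overlaps = {
        organ: [g for g in gene_set if g in set(top)]
        for organ, top in per_organ_top.items()
    }
    organs = list(per_organ_top)
    membership = {
        g: [o for o in organs if g in set(overlaps[o])] for g in gene_set
    }
    specific = {
        o: [g for g in overlaps[o] if len(membership[g]) == 1] for o in organs
    }
    shared = [g for g in gene_set if len(membership[g]) == len(organs)]
    return OverlapResult(
        top_k={o: list(t) for o, t in per_organ_top.items()},
        overlap_with_set=overlaps,
        organ_specific_candidates=specific,
        shared_all_organs=shared,
        k=max((len(t) for t in per_organ_top.values()), default=0),
    )
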