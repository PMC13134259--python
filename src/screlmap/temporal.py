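"""Temporal classification of genes across ordered developmental stages.

Given driver-rank tables for ordered stages (e.g. embryonic, fetal, adult),
genes are labeled ``early_peak`` when they rank near the top at the first
stage and fall substantially by the last, ``late_rise`` for the mirrored
pattern, and ``stable`` otherwise.  Labels depend only on ranks, so any
strictly monotone transform of the underlying correlation leaves them
unchanged, and reversing the stage order swaps early_peak and late_rise
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .drivers import DriverTable
from .errors import ContractError

DEFAULT_R_EARLY = 5
DEFAULT_DROP_FRAC = 0.10


@dataclass
class TemporalClassification:
    table: pd.DataFrame  # index gene; rank_<stage> columns, rank_drop, label
    stage_labels: list[str]
    r_early: int
    drop_frac: float


def _reranked(table: DriverTable, genes: pd.Index) -> pd.Series:
    """Ranks recomputed within the shared gene universe (1 = highest r)."""
    sub = table.table.loc[genes]
    order = sub.reset_index().sort_values(
        ["pearson_r", "gene"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(np.arange(1, len(order) + 1), index=order["gene"]).loc[genes]


def classify_temporal(
    stage_tables: Sequence[DriverTable],
    stage_labels: Sequence[str] | None = None,
    r_early: int = DEFAULT_R_EARLY,
    drop_frac: float = DEFAULT_DROP_FRAC,
) -> TemporalClassification:
    """Label genes early_peak / late_rise / stable from per-stage ranks.

    ``early_peak``: rank at the first stage <= ``r_early`` and rank worsens
    by at least ``drop_frac * G`` by the last stage (G = shared gene count);
    ``late_rise`` is the mirror; everything else is ``stable``.  The defaults
    (top 5, 10% of the list) are one documented configuration — both knobs
    are explicit parameters.
    """
    if len(stage_tables) < 2:
        raise ContractError("temporal classification needs >= 2 stages")
    labels = list(stage_labels or [f"stage_{i}" for i in range(len(stage_tables))])
    if len(labels) != len(stage_tables):
        raise ContractError("one label per stage table required")
    common = stage_tables[0].table.index
    for t in stage_tables[1:]:
        common = common.intersection(t.table.index)
    if len(common) == 0:
        raise ContractError("stage tables share no genes")
    common = common.sort_values()
    g = len(common)
    ranks = {lab: _reranked(t, common) for lab, t in zip(labels, stage_tables)}
    first, last = ranks[labels[0]], ranks[labels[-1]]
    drop = last - first
    threshold = drop_frac * g
    early = (first <= r_early) & (drop >= threshold)
    late = (last <= r_early) & (-drop >= threshold)
    label = np.where(early, "early_peak", np.where(late, "late_rise", "stable"))
    table = pd.DataFrame({f"rank_{lab}": ranks[lab] for lab in labels})
    table["rank_drop"] = drop.astype(int)
    table["label"] = label
    table.index = common.rename("gene")
    return TemporalClassification(
        table=table, stage_labels=labels, r_early=r_early, drop_frac=drop_frac
    )
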