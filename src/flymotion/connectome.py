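"""Connectome synapse-table summarization.

Consumes exported synapse tables (pre_type, pre_cell_id, post_type,
post_cell_id, n_synapses, proofread) and produces partner-type percentage
summaries: per reference cell, the percentage of its synaptic budget in a
direction going to each partner type, then mean +/- SEM across reference
cells. Rows whose proofread flag is missing are dropped first, then
connections with fewer than 3 synapses; partner types connected to fewer
than 70% of the reference cells are hidden from the display table but kept
in the normalization (percentages describe each cell's full budget).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synth import SYNAPSE_TABLE_COLUMNS

log = logging.getLogger(__name__)

MIN_SYNAPSES = 3
MIN_CELL_FRACTION = 0.7

__all__ = [
    "SynapseTableError",
    "filter_synapse_table",
    "partner_percentages",
]


class SynapseTableError(ValueError):
    """Synapse table is malformed."""


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SYNAPSE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SynapseTableError(f"missing columns: {missing}")
    counts = pd.to_numeric(table["n_synapses"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise SynapseTableError(
            f"row {row}: n_synapses {table['n_synapses'].iloc[row]!r} is not "
            "a non-negative integer"
        )
    out = table.copy()
    out["n_synapses"] = counts.astype(int)
    return out


def filter_synapse_table(
    table: pd.DataFrame, min_synapses: int = MIN_SYNAPSES
) -> pd.DataFrame:
    """Apply the proofreading and synapse-count filters, preserving row order.

    Rows with a missing proofread flag are removed first, then rows with
    fewer than ``min_synapses`` synapses.
    """
    table = _validate(table)
    proofread = table["proofread"]
    n_unproofread = int(proofread.isna().sum())
    if n_unproofread:
        log.info("dropping %d rows without proofread flag", n_unproofread)
    out = table[proofread.notna()]
    out = out[out["n_synapses"] >= min_synapses]
    return out.reset_index(drop=True)


def partner_percentages(
    table: pd.DataFrame,
    reference_type: str,
    direction: str = "output",
    min_cell_fraction: float = MIN_CELL_FRACTION,
    strict: bool = False,
) -> pd.DataFrame:
    """Partner-type percentage summary for one reference cell type.

    For each reference cell, the percentage per partner type is
    100 * (synapses with that type) / (all its synapses in ``direction``);
    the summary reports mean +/- SEM across reference cells, plus the
    fraction of reference cells connected to each partner. Partner types
    connected to fewer than ``min_cell_fraction`` of the reference cells are
    dropped from the display (``strict`` uses > instead of >=), but every
    partner stays in the normalization. Reference cells without synapses in
    the direction are excluded from the mean (logged).
    """
    if direction not in ("output", "input"):
        raise ValueError("direction must be 'output' or 'input'")
    ref_col, ref_id = ("pre_type", "pre_cell_id") if direction == "output" \
        else ("post_type", "post_cell_id")
    partner_col = "post_type" if direction == "output" else "pre_type"

    sub = table[table[ref_col] == reference_type]
    cells = sorted(sub[ref_id].unique())
    if not cells:
        raise ValueError(
            f"no {reference_type} cells on the {direction} side of the table"
        )
    pivot = sub.pivot_table(
        index=ref_id, columns=partner_col, values="n_synapses",
        aggfunc="sum", fill_value=0,
    )
    totals = pivot.sum(axis=1)
    empty = totals == 0
    if empty.any():
        log.info("excluding %d reference cells with zero %s synapses",
                 int(empty.sum()), direction)
        pivot = pivot[~empty]
        totals = totals[~empty]
    pct = pivot.div(totals, axis=0) * 100.0

    n_cells = len(pct)
    connected = (pivot > 0).sum(axis=0) / n_cells
    mean = pct.mean(axis=0)
    sem = pct.std(axis=0, ddof=1) / np.sqrt(n_cells) if n_cells > 1 else \
        pd.Series(0.0, index=pct.columns)
    summary = pd.DataFrame({
        "partner_type": pct.columns,
        "direction": direction,
        "percent_mean": mean.to_numpy(),
        "percent_sem": sem.to_numpy(),
        "fraction_cells_connected": connected.to_numpy(),
        "n_reference_cells": n_cells,
    })
    keep = summary["fraction_cells_connected"] > min_cell_fraction if strict \
        else summary["fraction_cells_connected"] >= min_cell_fraction
    summary = summary[keep]
    return summary.sort_values(
        "percent_mean", ascending=False
    ).reset_index(drop=True)
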