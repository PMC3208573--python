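"""Differential-expression input: read calls and apply significance thresholds.

The tool consumes an already-called differential-expression table (one row
per measured transcript: identifier, log2 fold-change, adjusted p-value);
upstream preprocessing and testing are out of scope. A transcript is called
significant when ``adj_p < p_cutoff`` and ``|fold change| >= fc_cutoff``
(the fold-change cutoff is on the linear scale, e.g. 1.3).
"""

from __future__ import annotations

import math

import pandas as pd

from .types import DOWN, UP, ObservedChanges

EXPRESSION_COLUMNS = ("gene_id", "log2fc", "adj_p")


def call_changes(table: pd.DataFrame, p_cutoff: float = 0.05,
                 fc_cutoff: float = 1.3) -> ObservedChanges:
    """Turn a differential-expression table into :class:`ObservedChanges`.

    ``table`` needs columns ``gene_id``, ``log2fc``, ``adj_p``. Direction is
    the sign of ``log2fc`` for significant rows.
    """
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].head(3).tolist()
        raise ValueError(f"duplicate gene ids in expression table, e.g. {dups}")
    log2_cut = math.log2(fc_cutoff)
    sig = (table["adj_p"] < p_cutoff) & (table["log2fc"].abs() >= log2_cut)
    direction = {
        str(g): (UP if fc > 0 else DOWN)
        for g, fc in zip(table.loc[sig, "gene_id"], table.loc[sig, "log2fc"])
    }
    return ObservedChanges(universe=frozenset(str(g) for g in table["gene_id"]),
                           direction=direction, thresholds=(p_cutoff, fc_cutoff))


def read_expression_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def read_changes(path, p_cutoff: float = 0.05, fc_cutoff: float = 1.3) -> ObservedChanges:
    """Read a TSV differential-expression table and apply thresholds."""
    return call_changes(read_expression_table(path), p_cutoff, fc_cutoff)
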