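"""Inverted-frontier and composite efficiency ranking.

The inverted frontier is obtained by exchanging the roles of inputs and
outputs and re-running the same DEA model: a score of 1 on the inverted
run marks the *anti-frontier* of worst observed practice.  Combining
both sides sharpens discrimination among units that the standard
frontier alone cannot separate:

    composed   = (standard + (1 - inverted)) / 2
    composed*  = composed / max(composed)        (so max composed* = 1)

Units are ranked by composed* descending, ties broken by ascending id.
A unit on both frontiers (standard = inverted = 1) receives composed
0.5 and is flagged as ambiguously efficient: it excels on some variable
mix and is among the worst on another.
"""

from __future__ import annotations

import pandas as pd

from .data import DMUTable
from .dea import EFFICIENT_TOL, ModelSpec, scores


def invert_table(table: DMUTable) -> DMUTable:
    """Swap input and output roles; ids and column names are preserved."""
    return DMUTable(
        frame=table.frame.loc[:, list(table.output_names) + list(table.input_names)],
        input_names=table.output_names,
        output_names=table.input_names,
    )


def composite_analysis(table: DMUTable, model: ModelSpec | None = None) -> pd.DataFrame:
    """Standard, inverted, composed and normalised-composed scores.

    The same model family and orientation (default CRS, input-oriented)
    is used on both frontier sides.  Returns a frame indexed by DMU id
    with columns ``standard``, ``inverted``, ``composed``,
    ``composed_star``, ``rank`` and the boolean ``ambiguous`` flag.
    """
    if model is None:
        model = ModelSpec("crs", "input")
    standard = scores(table, model)
    inverted = scores(invert_table(table), model)
    composed = (standard + (1.0 - inverted)) / 2.0
    composed_star = composed / composed.max()

    out = pd.DataFrame(
        {
            "standard": standard,
            "inverted": inverted,
            "composed": composed,
            "composed_star": composed_star,
        }
    )
    # rank by composed* descending, ties by ascending id
    order = out.assign(_id=out.index).sort_values(
        ["composed_star", "_id"], ascending=[False, True]
    )
    rank = pd.Series(range(1, len(order) + 1), index=order.index)
    out["rank"] = rank
    out["ambiguous"] = (standard >= 1.0 - EFFICIENT_TOL) & (inverted >= 1.0 - EFFICIENT_TOL)
    out.index.name = "dmu"
    return out
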