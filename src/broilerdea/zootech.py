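"""Zootechnical performance indicators and benchmark-gap reporting.

Industry panel for a broiler batch:

* viability        = 100 * (1 - mortality)           [%]  higher is better
* feed conversion  = feed / total_weight             [-]  lower is better
* daily weight gain (DWG): average grams gained per surviving bird per
  production day = total_weight[g] / (housing * (1 - mortality)) / age
* production efficiency factor (European convention):
  PEF = viability[%] * DWG[g/day] / (10 * feed conversion)

DWG divides by the *surviving* bird population, the convention under
which the packaged dataset's published panel is reproduced.  The
``mass_unit_to_grams`` factor converts the table's mass unit to grams
(default 1e6, i.e. tonnes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DMUTable
from .dea import EFFICIENT_TOL, EfficiencyResult

#: direction of improvement per indicator
HIGHER_IS_BETTER = {"viability": True, "dwg": True, "feed_conversion": False, "pef": True}


def indicators(table: DMUTable, mass_unit_to_grams: float = 1e6) -> pd.DataFrame:
    """Viability, DWG, feed conversion and PEF per DMU.

    Requires the canonical broiler schema.  Raises on a batch with no
    survivors (mortality = 1), where DWG is undefined.
    """
    if mass_unit_to_grams <= 0:
        raise ValueError("mass_unit_to_grams must be positive")
    f = table.frame
    for col in ("housing", "age", "feed", "mortality", "total_weight"):
        if col not in f.columns:
            raise KeyError(f"indicator panel requires column {col!r}")
    survivors = f["housing"] * (1.0 - f["mortality"])
    if (survivors <= 0).any():
        dead = f.index[survivors <= 0][0]
        raise ZeroDivisionError(f"DMU {dead}: no surviving birds, DWG undefined")
    viability = 100.0 * (1.0 - f["mortality"])
    fcr = f["feed"] / f["total_weight"]
    dwg = (f["total_weight"] * mass_unit_to_grams) / survivors / f["age"]
    pef = viability * dwg / (10.0 * fcr)
    out = pd.DataFrame(
        {"viability": viability, "dwg": dwg, "feed_conversion": fcr, "pef": pef}
    )
    out.index.name = "dmu"
    return out


def gap_report(
    indicator_panel: pd.DataFrame,
    efficiency: list[EfficiencyResult] | pd.Series,
    benchmark_id,
) -> pd.DataFrame:
    """Signed indicator gaps of every DMU to an efficient benchmark.

    Gaps are ``indicator - benchmark indicator``; a metric is flagged
    (``<name>_worse``) when the DMU is on the wrong side of the
    benchmark for that metric's direction (viability/DWG/PEF higher is
    better, feed conversion lower is better).  Rows are ordered by
    descending efficiency score, ties by ascending id; the benchmark
    has zero gaps to itself.
    """
    if isinstance(efficiency, pd.Series):
        eff = efficiency.astype(float)
    else:
        eff = pd.Series({r.dmu_id: r.score for r in efficiency})
    if benchmark_id not in indicator_panel.index or benchmark_id not in eff.index:
        raise KeyError(f"unknown benchmark DMU id {benchmark_id!r}")
    if eff.loc[benchmark_id] < 1.0 - EFFICIENT_TOL:
        raise ValueError(
            f"benchmark DMU {benchmark_id} is not efficient "
            f"(score {eff.loc[benchmark_id]:.6f})"
        )
    bench = indicator_panel.loc[benchmark_id]
    out = indicator_panel.copy()
    out["efficiency"] = eff
    for name, higher in HIGHER_IS_BETTER.items():
        gap = indicator_panel[name] - bench[name]
        out[f"{name}_gap"] = gap
        worse = gap < 0 if higher else gap > 0
        out[f"{name}_worse"] = np.where(np.abs(gap) < 1e-12, False, worse)
    out = out.assign(_id=out.index).sort_values(
        ["efficiency", "_id"], ascending=[False, True]
    ).drop(columns="_id")
    return out
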