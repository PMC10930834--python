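"""Radial DEA models: CCR (constant returns) and BCC (variable returns).

Efficiency of a unit is measured against the piecewise-linear frontier
enveloping all observed input-output points.  The envelopment LP for
unit *o* in input orientation is

    min  theta
    s.t. X lam <= theta * x_o      (inputs contract radially)
         Y lam >= y_o              (outputs at least maintained)
         sum(lam) = 1  under VRS   (convexity)
         lam >= 0,

and in output orientation the expansion factor phi is maximised with
inputs held fixed.  Output-oriented scores are reported as 1/phi so
every published score lives in (0, 1].

The non-Archimedean weight bound of the multiplier form is realised by
two-phase solving: phase 1 fixes the radial score, phase 2 maximises
the slack sum at that score, so radial scores are epsilon-independent.
An explicit-epsilon single-phase mode (``ModelSpec(epsilon=1e-6)``) is
provided for comparability with solvers that embed the constant.

Multiplier weights (virtual input/output prices) are recovered from the
phase-1 LP duals; with alternate optima they are one optimal choice
among possibly many and are flagged accordingly.

Columns are mean-normalised before LP assembly purely for numerical
conditioning (housing ~1e6 against cost ~4); radial scores are
invariant to positive column scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .data import DMUTable

#: a score within this distance of 1 counts as efficient
EFFICIENT_TOL = 1e-6
#: intensities above this are reported as benchmark peers
PEER_TOL = 1e-6
#: LP primal/dual feasibility tolerance handed to HiGHS
LP_TOL = 1e-9


class SolverError(RuntimeError):
    """The LP terminated without an optimal solution."""


@dataclass(frozen=True)
class ModelSpec:
    """One DEA run: returns-to-scale, orientation and frontier side.

    ``epsilon=None`` selects two-phase solving (radial phase, then slack
    maximisation at the fixed radial score).  An explicit epsilon must
    be a positive real <= 1e-4 and is applied as the slack premium of
    the single-phase non-Archimedean objective.
    """

    returns_to_scale: Literal["crs", "vrs"] = "crs"
    orientation: Literal["input", "output"] = "input"
    frontier_side: Literal["standard", "inverted"] = "standard"
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.returns_to_scale not in ("crs", "vrs"):
            raise ValueError(f"returns_to_scale must be 'crs' or 'vrs', got {self.returns_to_scale!r}")
        if self.orientation not in ("input", "output"):
            raise ValueError(f"orientation must be 'input' or 'output', got {self.orientation!r}")
        if self.frontier_side not in ("standard", "inverted"):
            raise ValueError(f"frontier_side must be 'standard' or 'inverted', got {self.frontier_side!r}")
        if self.epsilon is not None and not 0 < self.epsilon <= 1e-4:
            raise ValueError(f"explicit epsilon must lie in (0, 1e-4], got {self.epsilon!r}")

    @property
    def label(self) -> str:
        side = "" if self.frontier_side == "standard" else "-inverted"
        return f"{self.returns_to_scale}-{self.orientation}{side}"


@dataclass(frozen=True)
class EfficiencyResult:
    """Full LP solution for one DMU under one :class:`ModelSpec`.

    ``score`` is the reported radial efficiency in (0, 1]; for output
    orientation the raw expansion factor phi >= 1 is kept in
    ``expansion`` and ``score = 1/phi``.  ``intensities`` are the peer
    weights lambda; ``benchmarks`` the peers with lambda above
    tolerance.  Slacks and targets are in the original data units.
    """

    dmu_id: int
    model: ModelSpec
    score: float
    expansion: float
    input_weights: pd.Series
    output_weights: pd.Series
    u_free: float
    intensities: pd.Series
    input_slacks: pd.Series
    output_slacks: pd.Series
    target_inputs: pd.Series
    target_outputs: pd.Series
    benchmarks: tuple
    weights_unique: bool
    solver_status: str

    @property
    def is_efficient(self) -> bool:
        return self.score >= 1.0 - EFFICIENT_TOL


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL, "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status != 0:
        raise SolverError(f"LP terminated with status {res.status}: {res.message}")
    return res


def solve_dmu(table: DMUTable, model: ModelSpec, dmu_id) -> EfficiencyResult:
    """Solve the envelopment LP for one DMU and assemble the full result."""
    if dmu_id not in table.frame.index:
        raise KeyError(f"unknown DMU id {dmu_id!r}")
    if model.frontier_side == "inverted":
        from .composite import invert_table

        table = invert_table(table)
        model = replace(model, frontier_side="standard")

    X = table.inputs.to_numpy(float)          # (H, n_in)
    Y = table.outputs.to_numpy(float)         # (H, n_out)
    ids = table.ids
    o = ids.index(dmu_id)
    H, n_in = X.shape
    n_out = Y.shape[1]

    # mean-normalise for conditioning; scores are invariant to this
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    Xn, Yn = X / cx, Y / cy
    xo, yo = Xn[o], Yn[o]
    vrs = model.returns_to_scale == "vrs"
    input_oriented = model.orientation == "input"

    # ---- phase 1: radial factor -----------------------------------------
    # variables: [factor, lam_1..H] (+ slacks in explicit-epsilon mode)
    n_slack = (n_in + n_out) if model.epsilon is not None else 0
    n_var = 1 + H + n_slack
    c = np.zeros(n_var)
    c[0] = 1.0 if input_oriented else -1.0
    if n_slack:
        c[1 + H:] = model.epsilon if input_oriented else -model.epsilon

    rows, rhs = [], []
    for j in range(n_in):
        row = np.zeros(n_var)
        row[1:1 + H] = Xn[:, j]
        if input_oriented:
            row[0] = -xo[j]
            b = 0.0
        else:
            b = xo[j]
        if n_slack:
            row[1 + H + j] = 1.0
        rows.append(row)
        rhs.append(b)
    for i in range(n_out):
        row = np.zeros(n_var)
        row[1:1 + H] = -Yn[:, i]
        if input_oriented:
            b = -yo[i]
        else:
            row[0] = yo[i]
            b = 0.0
        if n_slack:
            row[1 + H + n_in + i] = 1.0
        rows.append(row)
        rhs.append(b)
    if n_slack:
        A_eq_rows = [np.array(r) for r in rows]
        A_eq1 = np.vstack(A_eq_rows)
        b_eq1 = np.array(rhs)
        A_ub1, b_ub1 = None, None
    else:
        A_ub1 = np.vstack(rows)
        b_ub1 = np.array(rhs)
        A_eq1, b_eq1 = None, None
    if vrs:
        conv = np.zeros(n_var)
        conv[1:1 + H] = 1.0
        if A_eq1 is None:
            A_eq1, b_eq1 = conv[None, :], np.array([1.0])
        else:
            A_eq1 = np.vstack([A_eq1, conv])
            b_eq1 = np.append(b_eq1, 1.0)
    bounds = [(None, None)] + [(0, None)] * (H + n_slack)
    res1 = _solve(c, A_ub1, b_ub1, A_eq1, b_eq1, bounds)
    factor = float(res1.x[0])

    # multiplier weights from the phase-1 duals (inequality-mode only;
    # the explicit-epsilon equality form carries slack duals instead)
    if n_slack == 0:
        marg = np.asarray(res1.ineqlin.marginals)
        v_n = -marg[:n_in]
        mu_n = -marg[n_in:n_in + n_out]
        u_free = float(np.asarray(res1.eqlin.marginals)[0]) if vrs else 0.0
    else:
        marg = np.asarray(res1.eqlin.marginals)
        v_n = -marg[:n_in]
        mu_n = -marg[n_in:n_in + n_out]
        u_free = float(marg[n_in + n_out]) if vrs else 0.0
    # de-normalise: weights per original data unit
    input_weights = pd.Series(np.maximum(v_n, 0.0) / cx, index=table.input_names)
    output_weights = pd.Series(np.maximum(mu_n, 0.0) / cy, index=table.output_names)

    # ---- phase 2: maximise slack sum at the fixed radial factor ----------
    # variables: [lam_1..H, s_in_1..n, s_out_1..m]
    n_var2 = H + n_in + n_out
    c2 = np.zeros(n_var2)
    c2[H:] = -1.0  # maximise
    A_eq2, b_eq2 = [], []
    for j in range(n_in):
        row = np.zeros(n_var2)
        row[:H] = Xn[:, j]
        row[H + j] = 1.0
        A_eq2.append(row)
        b_eq2.append((factor * xo[j]) if input_oriented else xo[j])
    for i in range(n_out):
        row = np.zeros(n_var2)
        row[:H] = Yn[:, i]
        row[H + n_in + i] = -1.0
        A_eq2.append(row)
        b_eq2.append(yo[i] if input_oriented else factor * yo[i])
    if vrs:
        row = np.zeros(n_var2)
        row[:H] = 1.0
        A_eq2.append(row)
        b_eq2.append(1.0)
    res2 = _solve(c2, None, None, np.vstack(A_eq2), np.array(b_eq2),
                  [(0, None)] * n_var2)
    lam = np.where(np.abs(res2.x[:H]) > PEER_TOL, res2.x[:H], 0.0)
    s_in = np.maximum(res2.x[H:H + n_in], 0.0) * cx
    s_out = np.maximum(res2.x[H + n_in:], 0.0) * cy

    if input_oriented:
        score = min(factor, 1.0)  # theta <= 1 mathematically; clamp numerics
        expansion = 1.0 / factor
        target_in = factor * X[o] - s_in
        target_out = Y[o] + s_out
    else:
        expansion = max(factor, 1.0)  # phi >= 1 mathematically
        score = 1.0 / expansion
        target_in = X[o] - s_in
        target_out = factor * Y[o] + s_out

    intensities = pd.Series(lam, index=ids)
    benchmarks = tuple(i for i, l in intensities.items() if l > PEER_TOL)
    return EfficiencyResult(
        dmu_id=dmu_id,
        model=model,
        score=float(score),
        expansion=float(expansion),
        input_weights=input_weights,
        output_weights=output_weights,
        u_free=u_free,
        intensities=intensities,
        input_slacks=pd.Series(s_in, index=table.input_names),
        output_slacks=pd.Series(s_out, index=table.output_names),
        target_inputs=pd.Series(target_in, index=table.input_names),
        target_outputs=pd.Series(target_out, index=table.output_names),
        benchmarks=benchmarks,
        weights_unique=False,  # alternate optima are common in DEA
        solver_status="optimal",
    )


def solve_all(table: DMUTable, model: ModelSpec) -> list[EfficiencyResult]:
    """Solve one LP per DMU, preserving table order (deterministic)."""
    results = []
    for dmu_id in table.ids:
        try:
            results.append(solve_dmu(table, model, dmu_id))
        except SolverError as err:
            raise SolverError(f"DMU {dmu_id}: {err}") from err
    return results


def scores(table: DMUTable, model: ModelSpec) -> pd.Series:
    """Radial scores only, indexed by DMU id."""
    return pd.Series(
        {r.dmu_id: r.score for r in solve_all(table, model)}, name=model.label
    )


def projection_targets(result: EfficiencyResult, table: DMUTable,
                       model: ModelSpec | None = None) -> pd.Series:
    """Frontier projection of a solved DMU, as one labelled vector.

    Input orientation: (score * x - s_minus, y + s_plus); output
    orientation: (x - s_minus, phi * y + s_plus).  The projection
    coincides with the lambda-combination of the benchmark peers within
    LP tolerance.
    """
    return pd.concat([result.target_inputs, result.target_outputs])


def score_table(table: DMUTable, specs: Sequence[ModelSpec] | None = None) -> pd.DataFrame:
    """Raw data plus one score column per model, in publication layout."""
    if specs is None:
        specs = [
            ModelSpec("crs", "input"),
            ModelSpec("crs", "output"),
            ModelSpec("vrs", "input"),
            ModelSpec("vrs", "output"),
        ]
    out = table.frame.copy()
    for spec in specs:
        out[spec.label] = scores(table, spec)
    return out
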