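"""Synthetic DMU tables: realistic farm batches and planted frontiers.

Two generators, both fully determined by one integer seed:

``generate_farms``
    Emulates the statistical structure of a Brazilian integrated
    broiler operation: ~31 batches, housing log-normal around 513,000
    birds (CV ~56%), slaughter age 42 +/- 1 days, mortality on
    (3%, 9.2%), per-bird daily gain ~72 g/day, feed conversion ~1.55,
    unit cost ~4.33 with a weak negative association to batch
    performance.  Output mass is built from the biology —
    total_weight = housing * (1 - mortality) * dwg * age / scale —
    and feed = fcr * total_weight, so feed, weight and housing are
    nearly collinear exactly as in real integrated production.

``generate_planted_frontier``
    Validation harness with analytically known efficiencies: efficient
    units are drawn on a random supporting hyperplane of the
    technology, inefficient units are conic (CRS) or convex (VRS)
    combinations of them with inputs inflated by 1/theta, so theta is
    each unit's exact input-oriented radial score (certified by the
    dual feasibility of the hyperplane weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DMUTable


class SimulationSpecError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class FarmSimSpec:
    """Distributional laws for one simulated integration, one batch per DMU.

    Defaults reproduce the structure of the packaged 31-batch dataset.
    ``mass_unit_scale`` converts grams to the table's mass unit
    (1e6 = tonnes).  ``cost_pef_slope`` couples unit cost negatively to
    the production efficiency factor (standardised), with residual
    normal noise so the association is weak, not deterministic.
    """

    n_dmus: int = 31
    seed: int = 0
    housing_mean: float = 513_000.0
    housing_cv: float = 0.56
    age_mean: float = 42.0
    age_sd: float = 1.0
    age_bounds: tuple[float, float] = (40.0, 45.0)
    mortality_bounds: tuple[float, float] = (0.03, 0.092)
    mortality_beta: tuple[float, float] = (2.0, 3.9)
    dwg_mean: float = 72.0
    dwg_sd: float = 3.0
    fcr_mean: float = 1.55
    fcr_sd: float = 0.05
    cost_mean: float = 4.33
    cost_sd: float = 0.10
    cost_pef_slope: float = -0.5
    mass_unit_scale: float = 1e6

    def __post_init__(self) -> None:
        if self.n_dmus < 2:
            raise SimulationSpecError(f"n_dmus must be >= 2, got {self.n_dmus}")
        for name in ("housing_mean", "housing_cv", "age_sd", "dwg_mean", "dwg_sd",
                     "fcr_mean", "fcr_sd", "cost_sd", "mass_unit_scale"):
            if getattr(self, name) <= 0:
                raise SimulationSpecError(f"{name} must be positive")
        lo, hi = self.mortality_bounds
        if not 0 < lo < hi < 1:
            raise SimulationSpecError("mortality_bounds must satisfy 0 < lo < hi < 1")
        a, b = self.mortality_beta
        if a <= 0 or b <= 0:
            raise SimulationSpecError("mortality_beta shapes must be positive")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds a few sd wide: cheap)."""
    out = rng.normal(mean, sd, size)
    while True:
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())


def generate_farms(spec: FarmSimSpec) -> DMUTable:
    """Draw one batch per DMU under the laws of ``spec`` (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_dmus

    sigma2 = np.log1p(spec.housing_cv**2)
    mu = np.log(spec.housing_mean) - sigma2 / 2.0
    housing = np.round(rng.lognormal(mu, np.sqrt(sigma2), n))
    housing = np.maximum(housing, 1.0)

    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_bounds, size=n)
    lo, hi = spec.mortality_bounds
    mortality = lo + (hi - lo) * rng.beta(*spec.mortality_beta, n)
    dwg = np.maximum(_truncated_normal(rng, spec.dwg_mean, spec.dwg_sd,
                                       spec.dwg_mean - 4 * spec.dwg_sd,
                                       spec.dwg_mean + 4 * spec.dwg_sd, size=n), 1.0)
    fcr = _truncated_normal(rng, spec.fcr_mean, spec.fcr_sd,
                            0.6, 4.5, size=n)

    total_weight = housing * (1.0 - mortality) * dwg * age / spec.mass_unit_scale
    feed = fcr * total_weight

    viability = 100.0 * (1.0 - mortality)
    pef = viability * dwg / (10.0 * fcr)
    pef_z = (pef - pef.mean()) / pef.std() if pef.std() > 0 else np.zeros(n)
    noise = rng.normal(0.0, 1.0, n)
    rho = np.clip(spec.cost_pef_slope, -1.0, 1.0)
    cost = spec.cost_mean + spec.cost_sd * (rho * pef_z + np.sqrt(1 - rho**2) * noise)
    cost = np.maximum(cost, 0.5 * spec.cost_mean)

    frame = pd.DataFrame(
        {
            "housing": housing,
            "age": age,
            "feed": feed,
            "mortality": mortality,
            "cost": cost,
            "total_weight": total_weight,
        },
        index=pd.RangeIndex(1, n + 1, name="dmu"),
    )
    return DMUTable(frame=frame)


@dataclass(frozen=True)
class PlantedFrontierSpec:
    """A technology with known scores for solver validation.

    ``theta_range`` bounds the planted input-oriented scores of the
    inefficient units.  Under VRS at least 2 efficient units are
    recommended so the frontier has extent.
    """

    n_efficient: int = 10
    n_inefficient: int = 20
    n_inputs: int = 3
    n_outputs: int = 1
    returns_to_scale: str = "crs"
    theta_range: tuple[float, float] = (0.5, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_efficient < 1:
            raise SimulationSpecError("need at least one efficient DMU")
        if self.n_inefficient < 0 or self.n_inputs < 1 or self.n_outputs < 1:
            raise SimulationSpecError("counts must be positive")
        lo, hi = self.theta_range
        if not 0 < lo <= hi < 1:
            raise SimulationSpecError("theta_range must lie strictly inside (0, 1)")
        if self.returns_to_scale not in ("crs", "vrs"):
            raise SimulationSpecError("returns_to_scale must be 'crs' or 'vrs'")


def generate_planted_frontier(spec: PlantedFrontierSpec) -> tuple[DMUTable, pd.Series]:
    """Build a table whose true input-oriented scores are known exactly.

    Efficient units satisfy y = w.x (CRS) or y = w.x + c (VRS) for a
    hidden positive weight vector w; every unit lies on or below that
    hyperplane, which certifies it as a supporting hyperplane of the
    technology, so each inefficient unit's radial score is exactly the
    theta used to inflate its inputs.  Multi-output instances put the
    hyperplane on a fixed positive combination of the outputs.

    Returns the table and the per-DMU true scores (1 for the planted
    frontier units).
    """
    rng = np.random.default_rng(spec.seed)
    vrs = spec.returns_to_scale == "vrs"
    n_in, n_out = spec.n_inputs, spec.n_outputs

    w = rng.uniform(0.5, 2.0, n_in)          # hidden input prices
    q = rng.uniform(0.5, 2.0, n_out)          # fixed output aggregator
    c = rng.uniform(0.1, 1.0) if vrs else 0.0

    X_eff = rng.uniform(1.0, 10.0, (spec.n_efficient, n_in))
    # split the aggregate frontier output q.y = w.x + c across outputs
    agg = X_eff @ w + c
    shares = rng.dirichlet(np.ones(n_out), spec.n_efficient)
    Y_eff = (agg[:, None] * shares) / q[None, :]

    rows_X, rows_Y, theta_true = [X_eff], [Y_eff], [1.0] * spec.n_efficient
    for _ in range(spec.n_inefficient):
        lam = rng.dirichlet(np.ones(spec.n_efficient))
        if spec.returns_to_scale == "crs":
            lam = lam * rng.uniform(0.5, 2.0)  # conic combination
        x_bar = lam @ X_eff
        y_bar = lam @ Y_eff
        theta = rng.uniform(*spec.theta_range)
        rows_X.append((x_bar / theta)[None, :])
        rows_Y.append(y_bar[None, :])
        theta_true.append(theta)

    X = np.vstack(rows_X)
    Y = np.vstack(rows_Y)
    in_names = tuple(f"x{j+1}" for j in range(n_in))
    out_names = tuple(f"y{i+1}" for i in range(n_out))
    frame = pd.DataFrame(
        np.hstack([X, Y]),
        columns=list(in_names) + list(out_names),
        index=pd.RangeIndex(1, len(X) + 1, name="dmu"),
    )
    table = DMUTable(frame=frame, input_names=in_names, output_names=out_names)
    true_scores = pd.Series(theta_true, index=frame.index, name="true_score")
    return table, true_scores
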