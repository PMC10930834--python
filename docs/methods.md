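# Methods

## The efficiency model

Each decision-making unit (DMU) is one closed broiler batch described
by five inputs — birds housed, age at slaughter (days), feed consumed,
mortality (stored as a fraction), unit cost — and one output, total
live weight delivered. Efficiency is *relative*: a unit is compared
only against the piecewise-linear frontier enveloping the observed
units, with no parametric production function. The four classical
radial models are provided: constant returns to scale (CCR) and
variable returns (BCC, convexity constraint `Σλ = 1` plus a sign-free
scale dual), each in input orientation (contract all inputs
proportionally at fixed outputs) and output orientation (expand outputs
at fixed inputs). Output-oriented expansion factors φ ≥ 1 are reported
as 1/φ so all published scores share the (0, 1] scale; under constant
returns the two orientations report identical scores (reciprocity),
which the tests assert.

All LPs are solved in envelopment form with `scipy.optimize.linprog`
(HiGHS, feasibility tolerances 1e-9). Multiplier weights (virtual
input/output prices) are read off the phase-1 dual values and
de-normalised to per-original-unit scale. DEA multiplier weights are
frequently non-unique at the optimum; results carry a
`weights_unique=False` flag and weight values are checked in tests only
through the invariant virtual-input = 1, virtual-output = score.

### Non-Archimedean slack handling

The classical formulation bounds all weights away from zero by an
infinitesimal ε. An explicit finite ε distorts radial scores at
roughly its own magnitude, so the default here is the standard
two-phase scheme: phase 1 computes the radial score alone; phase 2
maximises the slack sum with the radial score fixed. Radial scores are
then ε-independent, which is what published score tables report. An
explicit-ε single-phase mode (`ModelSpec(epsilon=...)`, capped at
1e-4) exists for comparability with tools that embed the constant; on
the packaged dataset the two modes agree to better than 5e-6, asserted
in the tests.

### Numerical choices

- Columns are divided by their means before LP assembly. Housing is
  O(10^6) against cost O(1); mean-scaling keeps the basis matrices well
  conditioned. Radial scores are invariant to positive column scaling
  (units invariance, tested to 1e-9 drift).
- "Efficient" means score ≥ 1 − 1e-6 at full precision, not after
  display rounding. Peers with intensity λ > 1e-6 form the benchmark
  set.
- Input-oriented θ cannot exceed 1 and output-oriented φ cannot fall
  below 1 (the unit itself is feasible); solver round-off beyond those
  bounds is clamped.
- Targets are `(θx − s⁻, y + s⁺)` in input orientation and
  `(x − s⁻, φy + s⁺)` in output orientation; they coincide with the
  λ-combination of peers within LP tolerance (tested).
- Ranking ties in the composite table break by ascending DMU id.
  Degenerate inputs: tables need ≥ 2 units (a relative frontier is
  meaningless otherwise), correlations ≥ 3 units and no constant
  column; identical duplicated units are legal and sit on both
  frontiers ("ambiguously efficient", composed score exactly 0.5).

## Inverted frontier and composite score

The inverted run exchanges the roles of inputs and outputs and re-runs
the same model family and orientation (CRS, input-oriented by default).
A score of 1 there marks the anti-frontier of worst observed practice.
The composite score `(standard + (1 − inverted))/2` and its
max-normalised version `composed* = composed / max(composed)` rank
units by combined closeness to the frontier and distance from the
anti-frontier. The composite formula is the established double-frontier
convention; it reproduces the published composite panel arithmetic
(e.g. (1 + 1 − 0.902093)/2 = 0.548953 after rounding), including the
normalisation by the maximum.

## Zootechnical panel

- viability = 100 × (1 − mortality), percent of housed birds surviving;
- FCR = feed / total_weight (same mass unit for both, dimensionless;
  lower is better);
- DWG = total_weight[g] / (housing × (1 − mortality)) / age, grams per
  surviving bird per day. The surviving-bird denominator is the
  convention under which the packaged dataset's published panel is
  reproduced;
- PEF = viability × DWG / (10 × FCR), the standard European production
  efficiency factor. The `mass_unit_to_grams` factor (default 1e6,
  i.e. tonnes) is the only unit assumption in the package; DEA scores
  themselves are units-invariant.

The gap report compares every unit's panel to a chosen efficient
benchmark, signing gaps by each metric's direction of improvement
(FCR lower-is-better, the rest higher-is-better).

## Summary statistics

`descriptive_stats` reports mean, median, sd, CV (sd/mean in %), max
and min per column. The standard deviation defaults to the population
(n) convention — the convention under which the packaged dataset's
published CVs are reproduced to within 0.03 percentage points — with
`ddof=1` available for the sample convention. Correlations are plain
Pearson product-moment coefficients.

## Synthetic data

`generate_farms` emulates the structure of one real integration:
housing log-normal with mean 513,000 birds and CV 56 %; age normal
(42, 1) truncated to [40, 45] days; mortality a beta(2, 3.9) law scaled
onto (3 %, 9.2 %) so its mean sits near the observed 5.1 %; per-bird
daily gain normal(72, 3) g/day; feed conversion normal(1.55, 0.05);
cost normal(4.33, 0.10) coupled negatively (default correlation −0.5)
to the batch's production efficiency factor, reflecting the observed
association between good husbandry and low unit cost without asserting
a fitted relationship. Weight is built from the biology
(`housing × survival × DWG × age`) and feed as `FCR × weight`, so
feed, weight and housing are nearly collinear exactly as in the real
data. One integer seed drives a dedicated `numpy` generator; no global
random state is touched.

What the generator does *not* emulate: seasonality and multi-batch
dynamics, disease outbreaks, heterogeneous housing technology, and any
genuine inefficiency structure — its batches differ by biology-driven
noise, not by management quality. Passing tests on generated farms
therefore validate plumbing and statistical calibration, not frontier
recovery.

Frontier recovery is validated by `generate_planted_frontier`:
efficient units are drawn on a random supporting hyperplane
(`q·y = w·x + c`, `c = 0` under CRS) with positive hidden prices
`w, q`; inefficient units are conic (CRS) or convex (VRS) combinations
of them with inputs inflated by 1/θ. Because every unit lies on or
below the hyperplane, the hyperplane weights are a feasible multiplier
solution certifying each planted θ as the *exact* radial score, with no
solver in the loop. The acceptance property re-solves 50 seeded
instances (10 efficient + 20 inefficient units, 3 inputs, 1 output) and
requires max |recovered − planted| < 1e-5.

As a second, structurally different check, tiny CRS instances are
scored by exhaustive dual-vertex enumeration (all active-constraint
bases of the multiplier polyhedron solved with dense linear algebra)
and compared to the LP route at 1e-6.

## Reproduction tolerances and known data anomalies

The packaged dataset's published score tables derive from unrounded
source data, while the raw-data table itself prints feed and weight
rounded to whole tonnes. Recomputation from the printed data therefore
tracks the published scores to ~1.5e-3 (standard frontier) and ~2.4e-3
(inverted), the deviation growing as batch size shrinks — exactly the
propagation one expects from half-unit input rounding. Concretely:

- batch 31's CRS score recomputes as 0.884163 against a published
  0.885687, and batch 3 lands on the other side of the 2 dp rounding
  boundary;
- the ninth unit of the published variable-returns frontier (batch 14)
  recomputes as 0.999665 — efficient only after 2 dp rounding;
- batch 7's feed conversion recomputes 0.0022 away from the printed
  value, and printed viability for batches 17 and 23 differs by
  0.13 / 0.05 from what their own printed mortality implies.

The acceptance tests state the published values at their printed
precision and are allowed to fail on exactly these cells rather than
widening tolerances; the package's own correctness rests on the
dual-certified planted-frontier and vertex-enumeration checks above.
DWG and PEF are asserted at 1 % relative tolerance for the same reason.

## Problem sizes

The full pipeline on the packaged data — 124 LPs for the four model
runs plus 31 inverted LPs, each with 31 units and 6 variables — plus
the 50-instance recovery study (3,000 small LPs) completes in well
under a minute on one CPU; all defaults in the test-suite and
acceptance script are the study's own sizes, not scaled-down stand-ins.

## Limitations

- Radial technical efficiency only: no super-efficiency, slack-based
  or network models, no Malmquist indices, no bootstrap confidence
  intervals, and no second-stage regressions of scores on covariates.
- Scores are relative to the sample; an efficient unit here may be
  dominated in a larger pool.
- Weight restrictions (assurance regions) are not applied in any
  standard run.
- The indicator panel covers the classical zootechnical levers;
  welfare, biosecurity quality and environmental load are outside the
  data.
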