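# broilerdea

Relative-efficiency benchmarking of integrated broiler production units
with Data Envelopment Analysis (DEA).

In integrated poultry production, contract farmers rear chicks supplied
by an agro-industry and are paid by performance. Which batches make the
best use of their resources, and what exactly should the others change?
`broilerdea` answers this for a table of producer batches (decision-
making units, DMUs) with five inputs — birds housed, age at slaughter,
feed consumed, mortality, unit cost of production — and one output, the
total live weight delivered. It is aimed at production analysts in
agro-industry and at researchers applying DEA to animal-production data.

## The models

For unit *o* with inputs `x_o` and outputs `y_o`, the input-oriented
envelopment LP is

```
min  θ
s.t. X λ ≤ θ x_o,   Y λ ≥ y_o,   λ ≥ 0,   (Σ λ = 1 under VRS)
```

where the columns of `X, Y` are all observed units. Under constant
returns to scale (the CCR model) θ is the classic radial technical
efficiency; adding the convexity constraint gives the variable-returns
BCC model. Output orientation maximises the expansion factor φ at fixed
inputs; scores are reported as 1/φ so every score lies in (0, 1].
Slacks are maximised in a second phase at the fixed radial score, and
multiplier weights (virtual prices) are recovered from the LP duals.

Beyond the four classical runs, the package computes the **inverted
frontier** (inputs and outputs exchanged; score 1 marks worst observed
practice) and the **composite efficiency**

```
composed  = (standard + (1 − inverted)) / 2,
composed* = composed / max(composed),
```

which ranks units by being close to the efficient frontier *and* far
from the anti-frontier. A zootechnical panel — viability,
daily weight gain (DWG), feed conversion ratio (FCR) and the European
production efficiency factor `PEF = viability × DWG / (10 × FCR)` —
links the DEA scores back to the husbandry levers a farm can act on.

## Worked example

```python
>>> import broilerdea as bd
>>> table = bd.load_broiler31()          # packaged 31-batch dataset
>>> comp = bd.composite_analysis(table)  # CRS input-oriented, both frontiers
>>> comp.round(6).head(4)
     standard  inverted  composed  composed_star  rank  ambiguous
dmu
1    0.959469  0.956590  0.501439       0.912463    19      False
2    0.973199  0.920379  0.526410       0.957901     6      False
3    0.934841  0.969577  0.482632       0.878239    27      False
4    1.000000  0.900910  0.549545       1.000000     1      False
```

Batch 4 is on the efficient frontier (`standard = 1`) and, with the
lowest anti-frontier score, tops the composite ranking — it is the
benchmark the other producers should emulate. The smallest batch, 31,
is the opposite pole:

```python
>>> r = bd.solve_dmu(table, bd.ModelSpec("crs", "input"), 31)
>>> round(r.score, 6), r.benchmarks
(0.884163, (4, 23))
```

It could produce its 195 t with ~11.6 % less of every input, moving to
a target mix formed by its peers 4 and 23. Only those two batches are
CRS-efficient; they also post the best production-efficiency factors
(≈490) and the lowest unit costs, so the frontier picked out by the LP
coincides with what a zootechnician would flag by eye:

```python
>>> bd.indicators(table).loc[[4, 31]].round(3)
     viability     dwg  feed_conversion      pef
dmu
4        96.51  76.228            1.502  489.954
31       93.35  64.268            1.667  359.967
```

The same pipeline runs from the shell:

```sh
broilerdea run --fixture --out reports/      # Tables: stats, scores, ranking, gaps
broilerdea simulate --n-dmus 31 --seed 7     # synthetic farms with realistic structure
broilerdea fixture --out broiler31.csv       # dump the packaged dataset
```

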