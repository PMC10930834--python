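"""Reading, validating and summarising decision-making-unit (DMU) tables.

A DMU table is the universe against which every efficiency score is
relative: one row per producer batch, a set of input columns ("the
smaller, the better") and at least one output column ("the bigger, the
better").  The canonical broiler schema has five inputs — ``housing``
(birds placed), ``age`` (days at slaughter), ``feed`` (feed mass
consumed), ``mortality`` (fraction of birds lost), ``cost`` (unit cost
of production) — and one output, ``total_weight`` (total live mass
delivered, same mass unit as ``feed``).

Mortality is stored internally as a fraction in (0, 1); percent strings
such as ``"4.58%"`` are parsed on read and rendered back as percent on
write.  Thousands separators are stripped on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INPUT_COLUMNS = ("housing", "age", "feed", "mortality", "cost")
OUTPUT_COLUMNS = ("total_weight",)

#: sanity band for feed mass per unit of live mass produced
FEED_CONVERSION_BAND = (0.5, 5.0)

_PERCENT_COLUMNS = frozenset({"mortality"})


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """A cell violates a domain invariant (named DMU and field)."""


class DatasetSizeError(ValueError):
    """Fewer than two DMUs: relative efficiency is undefined."""


@dataclass(frozen=True)
class DMURecord:
    """One producer batch in the canonical broiler schema."""

    id: int
    housing: float
    age: float
    feed: float
    mortality: float  # fraction in (0, 1)
    cost: float
    total_weight: float

    def validate(self) -> None:
        for name in ("housing", "age", "feed", "cost", "total_weight"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(
                    f"DMU {self.id}: field {name!r} must be strictly positive, got {value!r}"
                )
        if not 0 < self.mortality < 1:
            raise ValidationError(
                f"DMU {self.id}: mortality must lie strictly in (0, 1), got {self.mortality!r}"
            )
        fcr = self.feed / self.total_weight
        lo, hi = FEED_CONVERSION_BAND
        if not lo < fcr < hi:
            warnings.warn(
                f"DMU {self.id}: feed/total_weight = {fcr:.3f} outside the sane band "
                f"({lo}, {hi}); check units",
                stacklevel=3,
            )


@dataclass(frozen=True)
class DMUTable:
    """An ordered collection of DMUs with named input and output columns.

    ``frame`` is indexed by the integer DMU id; its columns are exactly
    ``input_names + output_names`` in that order.  The table is generic:
    any strictly positive numeric columns are accepted, so synthetic and
    role-swapped (inverted-frontier) tables share the container.
    """

    frame: pd.DataFrame
    input_names: tuple[str, ...] = INPUT_COLUMNS
    output_names: tuple[str, ...] = OUTPUT_COLUMNS

    def __post_init__(self) -> None:
        if len(self.output_names) < 1:
            raise SchemaError("at least one output column is required")
        expected = list(self.input_names) + list(self.output_names)
        missing = [c for c in expected if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        frame = self.frame.loc[:, expected].astype(float)
        if frame.index.duplicated().any():
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValidationError(f"duplicate DMU id(s): {dupes}")
        if len(frame) < 2:
            raise DatasetSizeError(
                f"need at least 2 DMUs for a relative frontier, got {len(frame)}"
            )
        bad = (frame <= 0) | ~np.isfinite(frame)
        if bad.any().any():
            dmu = frame.index[bad.any(axis=1)][0]
            col = frame.columns[bad.loc[dmu].values][0]
            raise ValidationError(
                f"DMU {dmu}: field {col!r} must be strictly positive and finite, "
                f"got {frame.loc[dmu, col]!r}"
            )
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "output_names", tuple(self.output_names))

    # -- accessors -------------------------------------------------------

    @property
    def ids(self) -> list:
        return list(self.frame.index)

    @property
    def n_dmus(self) -> int:
        return len(self.frame)

    @property
    def inputs(self) -> pd.DataFrame:
        return self.frame.loc[:, list(self.input_names)]

    @property
    def outputs(self) -> pd.DataFrame:
        return self.frame.loc[:, list(self.output_names)]

    @property
    def records(self) -> list[DMURecord]:
        """Rows as :class:`DMURecord` (canonical broiler schema only)."""
        if tuple(self.input_names) != INPUT_COLUMNS or tuple(self.output_names) != OUTPUT_COLUMNS:
            raise SchemaError("records view requires the canonical broiler schema")
        return [
            DMURecord(id=int(i), **{c: float(row[c]) for c in self.frame.columns})
            for i, row in self.frame.iterrows()
        ]


def _parse_cell(raw, column: str):
    """Strip thousands separators and percent suffixes; percent -> fraction."""
    if isinstance(raw, str):
        text = raw.strip().replace(",", "").replace("−", "-")
        if text.endswith("%"):
            return float(text[:-1]) / 100.0
        value = float(text)
    else:
        value = float(raw)
    if column in _PERCENT_COLUMNS and value >= 1.0:
        # bare numeric percent (e.g. 4.58 meaning 4.58%)
        value /= 100.0
    return value


def load_table(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    input_names: Sequence[str] = INPUT_COLUMNS,
    output_names: Sequence[str] = OUTPUT_COLUMNS,
    id_column: str = "dmu",
) -> DMUTable:
    """Read a delimited DMU table (comma default, tab accepted).

    ``column_mapping`` maps names found in the file to canonical names,
    e.g. ``{"lodging": "housing"}``.  Mortality cells may be percent
    strings (``"4.58%"``) or bare percent numbers; both are stored as
    fractions.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if column_mapping:
        raw = raw.rename(columns=dict(column_mapping))
    raw.columns = [c.strip().lower() for c in raw.columns]
    expected = [id_column, *input_names, *output_names]
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    if len(raw) < 2:
        raise DatasetSizeError(f"{path.name}: need at least 2 rows, got {len(raw)}")

    parsed = {}
    for col in expected:
        if col == id_column:
            parsed[col] = [int(_parse_cell(v, col)) for v in raw[col]]
        else:
            parsed[col] = [_parse_cell(v, col) for v in raw[col]]
    frame = pd.DataFrame(parsed).set_index(id_column)
    frame.index.name = "dmu"
    table = DMUTable(
        frame=frame, input_names=tuple(input_names), output_names=tuple(output_names)
    )
    if tuple(input_names) == INPUT_COLUMNS and tuple(output_names) == OUTPUT_COLUMNS:
        for record in table.records:
            record.validate()
    return table


def write_table(table: DMUTable, path: str | Path) -> Path:
    """Write a DMU table back to delimited text (round-trip safe).

    Mortality is rendered as a percent string with full precision so
    ``load_table(write_table(t))`` reproduces every cell exactly.
    """
    path = Path(path)
    out = table.frame.copy()
    for col in out.columns:
        if col in _PERCENT_COLUMNS:
            out[col] = [f"{v * 100:.12g}%" for v in out[col]]
        else:
            out[col] = [f"{v:.12g}" for v in out[col]]
    out.to_csv(path)
    return path


def load_broiler31() -> DMUTable:
    """The packaged 31-batch integrated-broiler dataset.

    Five inputs (housing, age at slaughter, feed consumed, mortality,
    unit cost) and one output (total available weight) for 31 producer
    batches closed between January 2021 and October 2022.  Housing is a
    bird count; feed and total weight share one mass unit (tonnes) —
    the interpretation under which the feed-conversion ratios cohere.
    DEA scores are units-invariant, so unit choices do not affect them.
    """
    source = resources.files("broilerdea.datasets") / "broiler31.csv"
    with resources.as_file(source) as path:
        return load_table(path)


def descriptive_stats(table: DMUTable, ddof: int = 0) -> pd.DataFrame:
    """Per-column mean, median, sd, CV (%), max and min.

    The standard deviation uses the population (``ddof=0``) convention
    by default — the convention under which the packaged dataset's
    published coefficients of variation are reproduced.  The CV is
    sd/mean expressed in percent.  A single-record table reports sd 0
    with a warning; a constant column reports CV 0.
    """
    frame = table.frame
    if len(frame) < 2:
        warnings.warn("single-record table: standard deviation undefined, reported as 0")
        sd = pd.Series(0.0, index=frame.columns)
    else:
        sd = frame.std(ddof=ddof)
    mean = frame.mean()
    stats = pd.DataFrame(
        {
            "mean": mean,
            "median": frame.median(),
            "sd": sd,
            "cv_pct": 100.0 * sd / mean,
            "max": frame.max(),
            "min": frame.min(),
        }
    ).T
    stats.index.name = "statistic"
    return stats


def correlation_matrix(table: DMUTable) -> pd.DataFrame:
    """Pearson product-moment correlations over all table columns."""
    frame = table.frame
    if len(frame) < 3:
        raise DatasetSizeError("need at least 3 DMUs for a correlation matrix")
    constant = frame.columns[frame.std(ddof=0) == 0]
    if len(constant):
        raise ValidationError(
            f"correlation undefined for constant column(s): {', '.join(constant)}"
        )
    return frame.corr(method="pearson")
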