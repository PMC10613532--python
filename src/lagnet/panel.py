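"""Wide-format panel tables: loading, validation, slicing, and year interpolation.

A *panel* here is a set of areal units (e.g. counties) measured on a set of
variables at a handful of annual time slices.  On disk the canonical layout is
a wide CSV with one identifier column and one column per ``(variable, year)``
pair, named ``<variable><sep><year>`` (default separator ``_``).  In memory the
panel is a :class:`pandas.DataFrame` with a two-level column index
``(variable, time)`` wrapped in :class:`PanelDataset`.

The grid of observed ``(variable, year)`` pairs need not be complete — the
outcome of a study is typically measured one year later than its predictors —
but every observed cell must be finite.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateIntervalError,
    EmptyDataError,
    PanelFormatError,
    TemporalOrderError,
)

logger = logging.getLogger(__name__)


class Node(NamedTuple):
    """A ``(variable, time)`` pair — one column of the panel, one network node."""

    variable: str
    time: int

    def label(self) -> str:
        return f"{self.variable}@{self.time}"


@dataclass(frozen=True)
class TemporalOrdering:
    """Total rank over nodes: a node's rank is the index of its time slice.

    Nodes measured in the same year share a rank; edges may only point from a
    lower rank to a strictly higher one.
    """

    times: tuple[int, ...]

    def __post_init__(self):
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("times must be strictly increasing")

    def rank(self, node: Node) -> int:
        try:
            return self.times.index(node.time)
        except ValueError:
            raise KeyError(f"time {node.time} not in ordering {self.times}") from None


@dataclass
class PanelDataset:
    """Units x (variable, time) measurements with explicit temporal ordering.

    ``frame`` is indexed by unit id and has a two-level ``(variable, time)``
    column index.  All cells are finite; at least two time slices and two
    variables are present.
    """

    frame: pd.DataFrame
    units_meta: dict | None = field(default=None)

    def __post_init__(self):
        cols = self.frame.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError("frame must have a (variable, time) MultiIndex")
        self.frame.columns = pd.MultiIndex.from_tuples(
            [(str(v), int(t)) for v, t in cols], names=["variable", "time"]
        )
        if len(self.times) < 2:
            raise ValueError("panel needs at least 2 time slices")
        if len(self.variables) < 2:
            raise ValueError("panel needs at least 2 variables")
        values = self.frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("panel contains non-finite cells")

    # -- basic views -------------------------------------------------------
    @property
    def unit_ids(self) -> list:
        return list(self.frame.index)

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for v, _ in self.frame.columns:
            seen.setdefault(v, None)
        return list(seen)

    @property
    def times(self) -> list[int]:
        return sorted({t for _, t in self.frame.columns})

    @property
    def n_units(self) -> int:
        return len(self.frame)

    def nodes(self) -> list[Node]:
        return [Node(v, t) for v, t in self.frame.columns]

    def has_node(self, node: Node) -> bool:
        return (node.variable, int(node.time)) in set(self.frame.columns)

    def series(self, node: Node) -> np.ndarray:
        if not self.has_node(node):
            raise KeyError(f"node {node!r} not in panel")
        return self.frame[(node.variable, int(node.time))].to_numpy(dtype=float)

    def variables_at(self, time: int) -> list[str]:
        return [v for v, t in self.frame.columns if t == time]

    def ordering(self) -> TemporalOrdering:
        return TemporalOrdering(tuple(self.times))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        a, b = self.frame, other.frame
        return (
            list(a.index) == list(b.index)
            and list(a.columns) == list(b.columns)
            and np.array_equal(a.to_numpy(float), b.to_numpy(float))
        )


# ---------------------------------------------------------------------------
# wide-CSV I/O


def _parse_header(col: str, sep: str, pattern: str | None) -> Node:
    if pattern is not None:
        m = re.fullmatch(pattern, col)
        if m is None or "variable" not in m.groupdict() or "year" not in m.groupdict():
            raise PanelFormatError(
                f"column {col!r} does not match schema pattern {pattern!r}"
            )
        return Node(m.group("variable"), int(m.group("year")))
    var, _, year = col.rpartition(sep)
    if not var or not year.lstrip("-").isdigit():
        raise PanelFormatError(
            f"column {col!r} does not follow '<variable>{sep}<year>'"
        )
    return Node(var, int(year))


def read_panel(
    path,
    id_column: str | None = None,
    sep: str = "_",
    pattern: str | None = None,
    na_policy: str = "drop",
) -> PanelDataset:
    """Read a wide CSV into a :class:`PanelDataset`.

    Parameters
    ----------
    id_column:
        Identifier column; defaults to the first column.
    sep:
        Separator between variable name and year in headers.  A variable name
        may itself contain ``sep``: the *last* separator splits off the year.
    pattern:
        Optional regex schema with named groups ``variable`` and ``year``;
        overrides ``sep``.
    na_policy:
        ``"drop"`` (complete-case: drop units with any missing cell, logging
        the count) or ``"error"``.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    if raw.shape[1] < 2:
        raise PanelFormatError("need an id column plus at least one data column")
    idc = id_column if id_column is not None else raw.columns[0]
    if idc not in raw.columns:
        raise PanelFormatError(f"id column {idc!r} not found")
    nodes = [_parse_header(c, sep, pattern) for c in raw.columns if c != idc]

    data = raw.set_index(idc)
    data.columns = pd.MultiIndex.from_tuples(
        [tuple(n) for n in nodes], names=["variable", "time"]
    )
    incomplete = data.isna().any(axis=1)
    if incomplete.any():
        if na_policy == "error":
            raise EmptyDataError(f"{int(incomplete.sum())} rows have missing cells")
        logger.info("read_panel: dropped %d incomplete units", int(incomplete.sum()))
        data = data.loc[~incomplete]
    if len(data) == 0:
        raise EmptyDataError("no complete rows after applying na_policy")
    return PanelDataset(frame=data.astype(float))


def write_panel(panel: PanelDataset, path, sep: str = "_") -> None:
    """Write the panel back to the wide-CSV dialect (lossless round-trip).

    Floats are written with Python's shortest-round-trip repr, so
    ``read_panel(write_panel(p))`` reproduces every cell bit-for-bit.
    """
    out = panel.frame.copy()
    out.columns = [f"{v}{sep}{t}" for v, t in out.columns]
    out.index.name = out.index.name or "id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# utilities


def interpolate_measure(
    value_a: float, year_a: float, value_b: float, year_b: float, target: float
) -> float:
    """Linear interpolation/extension of a measure between two reference years.

    Used for sparsely measured variables (e.g. deriving a 2016 value from 2010
    and 2015 measurements).  The line through ``(year_a, value_a)`` and
    ``(year_b, value_b)`` is evaluated at ``target``, which may lie outside
    the interval.
    """
    if year_a == year_b:
        raise DegenerateIntervalError("year_a and year_b must differ")
    if year_a > year_b:
        raise DegenerateIntervalError("year_a must precede year_b")
    return value_a + (target - year_a) / (year_b - year_a) * (value_b - value_a)


def slice_design(
    panel: PanelDataset, response: Node, predictor_time: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix of *all* variables at ``predictor_time`` plus the response.

    The predictor set includes the response variable's own earlier measurement;
    rows follow the panel's unit order.  Columns of the returned frame are
    :class:`Node` tuples.
    """
    response = Node(*response)
    if not panel.has_node(response):
        raise KeyError(f"response node {response!r} not in panel")
    if predictor_time >= response.time:
        raise TemporalOrderError(
            f"predictor_time {predictor_time} is not earlier than response "
            f"time {response.time}"
        )
    pred_vars = panel.variables_at(predictor_time)
    if not pred_vars:
        raise KeyError(f"no variables measured at {predictor_time}")
    cols = [Node(v, predictor_time) for v in pred_vars]
    X = pd.DataFrame(
        {c: panel.series(c) for c in cols}, index=panel.frame.index
    )
    y = pd.Series(panel.series(response), index=panel.frame.index, name=response)
    return X, y
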