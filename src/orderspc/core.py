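"""Shared domain types and file I/O.

The whole package operates on a single kind of input: a small univariate
data set of logically comparable measurements (for example annual percentage
compliance per hospital ward), tagged with whether the records carry an
inherent order (a time series does; a set of wards does not).  Percentages
are always stored on the 0-100 scale, never as fractions.

Internal computation is full precision; display rounding (3 significant
figures, round half to even) is applied only when text is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Context, Decimal
from enum import Enum
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "OrderSpcError",
    "InsufficientDataError",
    "ObservationReadError",
    "ChartKind",
    "ObservationSet",
    "ControlLimits",
    "read_observations",
    "write_observations",
    "round_half_even",
    "round_sig",
    "format_sig",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OrderSpcError(ValueError):
    """Base class for all validation and computation errors in this package."""


class InsufficientDataError(OrderSpcError):
    """Raised when a computation requires at least two observations."""


class ObservationReadError(OrderSpcError):
    """A CSV input failed validation.

    ``reason`` identifies the failure: ``"malformed"``, ``"missing_value"``,
    ``"non_numeric"``, ``"duplicate_label"`` or ``"too_few"``.
    """

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ChartKind(str, Enum):
    X_INDIVIDUALS = "x_individuals"
    MOVING_RANGE = "moving_range"
    P = "p"
    NP = "np"
    C = "c"
    U = "u"
    AVERAGE_SD = "average_sd"


@dataclass(frozen=True)
class ObservationSet:
    """Labelled univariate measurements with an ordered/unordered flag.

    ``values`` keeps the row order of the source; for data with an inherent
    order that order is meaningful, otherwise it is merely the "original"
    ordering in which the records happened to arrive.
    """

    labels: tuple[str, ...]
    values: tuple[float, ...]
    has_inherent_order: bool = False
    unit_label: str = ""

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        if len(labels) != len(values):
            raise OrderSpcError("labels and values must have equal length")
        if len(values) < 2:
            raise InsufficientDataError("at least 2 observations are required")
        if len(set(labels)) != len(labels):
            raise OrderSpcError("labels must be unique")
        if not all(math.isfinite(v) for v in values):
            raise OrderSpcError("values must be finite reals")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ControlLimits:
    """Centre line and control limits for one chart.

    ``width`` is always the pre-clipping ``upper - lower``.  When a lower
    limit falls below zero on data that cannot be negative (percentages,
    counts) the raw value is retained and ``lower_clipped_at_zero`` is set;
    the interpretive lower bound is then 0.
    """

    chart_kind: ChartKind
    center: float
    lower: float
    upper: float
    lower_clipped_at_zero: bool = False
    width: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.width is None:
            object.__setattr__(self, "width", self.upper - self.lower)
        if not (self.lower <= self.center + 1e-12 and
                self.center <= self.upper + 1e-12):
            raise OrderSpcError(
                f"limits must bracket the centre: "
                f"{self.lower} <= {self.center} <= {self.upper}")

    @property
    def interpretive_lower(self) -> float:
        return 0.0 if self.lower_clipped_at_zero else self.lower


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_observations(path: Union[str, Path],
                      ordered_flag: bool = False,
                      unit_label: str = "") -> ObservationSet:
    """Read a ``label,value`` CSV into an :class:`ObservationSet`.

    Row order is preserved exactly as the file's "original" ordering.
    Validation failures raise :class:`ObservationReadError` with a distinct
    ``reason`` per failure mode.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise ObservationReadError("malformed", f"cannot parse CSV {path}: {exc}")
    if list(frame.columns) != ["label", "value"]:
        raise ObservationReadError(
            "malformed", f"expected header 'label,value', got {list(frame.columns)}")
    labels = [str(l).strip() for l in frame["label"]]
    raw = [str(v).strip() for v in frame["value"]]
    values = []
    for lab, cell in zip(labels, raw):
        if cell == "":
            raise ObservationReadError("missing_value", f"missing value for label {lab!r}")
        try:
            values.append(float(cell))
        except ValueError:
            raise ObservationReadError("non_numeric", f"non-numeric value {cell!r} for label {lab!r}")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ObservationReadError("duplicate_label", f"duplicate labels: {dupes}")
    if len(values) < 2:
        raise ObservationReadError("too_few", f"need at least 2 data rows, got {len(values)}")
    return ObservationSet(tuple(labels), tuple(values), ordered_flag, unit_label)


def write_observations(obs: ObservationSet, path: Union[str, Path]) -> None:
    """Write an :class:`ObservationSet` as a ``label,value`` CSV, preserving order."""
    frame = pd.DataFrame({"label": obs.labels, "value": obs.values})
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Display rounding
# ---------------------------------------------------------------------------

# Floats are snapped to 12 significant digits before quantisation so that
# desk arithmetic on printed decimals rounds the way the decimals themselves
# would (e.g. (75 - 16.7)/22 displays as 2.6, not 2.7 via float noise).
def _as_decimal(x: float) -> Decimal:
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(f"{float(x):.12g}")


def round_half_even(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimal places with round-half-to-even."""
    q = _as_decimal(x).quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_EVEN)
    return float(q)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures with round-half-to-even."""
    if x == 0:
        return 0.0
    ctx = Context(prec=sig, rounding=ROUND_HALF_EVEN)
    return float(ctx.plus(_as_decimal(x)))


def format_sig(x: float, sig: int = 3) -> str:
    """Render ``x`` at ``sig`` significant figures for text reports."""
    return f"{round_sig(x, sig):.{sig}g}"
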