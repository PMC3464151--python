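"""Individuals and moving-range (XmR) chart computations.

The XmR chart estimates dispersion from the average moving range

    mR_bar = (1/(n-1)) * sum_j |y_{j+1} - y_j|

over the *supplied ordering* y of the data, and places individuals-chart
limits at ``mean +/- E2 * mR_bar`` with the conventional Shewhart constant
E2 = 2.66 (3/d2 with d2 = 1.128 for subgroups of size 2).  Because mR_bar
depends on the ordering, these limits are only meaningful for data with an
inherent order; quantifying how badly they move under reordering is the
point of the :mod:`orderspc.extrema` and :mod:`orderspc.resampling` modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ChartKind, ControlLimits, InsufficientDataError

__all__ = [
    "XMR_CONSTANT",
    "MR_CHART_UPPER_CONSTANT",
    "MovingRangeSummary",
    "moving_ranges",
    "mr_bar",
    "xmr_limits",
    "detect_signals",
]

# E2 = 3/d2, d2 = 1.128 for moving ranges of span 2.
XMR_CONSTANT: float = 2.66
# D4 for the moving-range chart's upper limit.
MR_CHART_UPPER_CONSTANT: float = 3.267


@dataclass(frozen=True)
class MovingRangeSummary:
    """The n-1 absolute successive differences of an ordering and their mean."""

    moving_ranges: tuple[float, ...]
    mr_bar: float
    n: int


def moving_ranges(ordered_values: Sequence[float]) -> MovingRangeSummary:
    """Moving ranges |y_{j+1} - y_j| of the supplied ordering, with their mean."""
    y = np.asarray(ordered_values, dtype=float)
    if y.size < 2:
        raise InsufficientDataError("insufficient data: need n >= 2 for moving ranges")
    mrs = np.abs(np.diff(y))
    # fsum: exactly-rounded, so mR_bar is identical for an ordering and its
    # reversal (same multiset of moving ranges) regardless of summation order
    mean = math.fsum(mrs) / (y.size - 1)
    return MovingRangeSummary(tuple(float(m) for m in mrs), mean, int(y.size))


def mr_bar(ordered_values: Sequence[float]) -> float:
    """The average moving range of the supplied ordering."""
    return moving_ranges(ordered_values).mr_bar


def xmr_limits(ordered_values: Sequence[float],
               mr_bar_override: Optional[float] = None,
               constant: float = XMR_CONSTANT,
               clip_lower_at_zero: bool = True,
               ) -> tuple[ControlLimits, ControlLimits]:
    """Control limits for the individuals chart and the moving-range chart.

    ``mr_bar_override`` substitutes an externally supplied average moving
    range (for example mR_bar_min or mR_bar_max from the extremal analysis)
    for the one computed from the ordering.

    Returns ``(individuals_limits, moving_range_limits)``.  A negative lower
    individuals limit is retained raw but flagged as clipped at zero when
    ``clip_lower_at_zero`` (the usual practice for percentage or count data).
    """
    summary = moving_ranges(ordered_values)
    mrb = summary.mr_bar if mr_bar_override is None else float(mr_bar_override)
    if mrb < 0:
        raise ValueError("mr_bar_override must be non-negative")
    center = float(np.mean(np.asarray(ordered_values, dtype=float)))
    half_width = constant * mrb
    individuals = ControlLimits(
        chart_kind=ChartKind.X_INDIVIDUALS,
        center=center,
        lower=center - half_width,
        upper=center + half_width,
        lower_clipped_at_zero=bool(clip_lower_at_zero and center - half_width < 0),
    )
    mr_chart = ControlLimits(
        chart_kind=ChartKind.MOVING_RANGE,
        center=mrb,
        lower=0.0,
        upper=MR_CHART_UPPER_CONSTANT * mrb,
    )
    return individuals, mr_chart


def detect_signals(ordered_values: Sequence[float],
                   limits: ControlLimits) -> frozenset[int]:
    """Indices of points strictly outside the (pre-clipping) control limits.

    Implements only the beyond-limits rule; points exactly on a limit are
    not flagged.
    """
    y = np.asarray(ordered_values, dtype=float)
    outside = (y < limits.lower) | (y > limits.upper)
    return frozenset(int(i) for i in np.nonzero(outside)[0])
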