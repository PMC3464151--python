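"""Order-free special-cause detection for data without inherent order.

When a data set has no natural ordering, the XmR chart's dispersion
estimate is ambiguous and special-cause detection becomes an outlier
problem.  Two simple order-free methods are provided:

* Tukey's fences at ``Q1 - k*IQR`` and ``Q3 + k*IQR`` (k = 1.5 gives the
  inner fences, k = 3 the outer fences).  The default quartile convention
  is Tukey's hinges — medians of the lower and upper halves of the sorted
  data, the halves including the overall median when n is odd — with a
  linear-interpolation alternative selectable by configuration.
* The 3-sigma rule, i.e. an average-and-standard-deviation chart:
  ``mean +/- n_sigma * sample SD`` (n-1 denominator).

Both depend only on the multiset of values, never on their order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence, Union

import numpy as np

from .core import ChartKind, ControlLimits, InsufficientDataError

__all__ = [
    "QuartileMethod",
    "FenceKind",
    "Fences",
    "quartiles",
    "tukey_fences",
    "sigma_limits",
    "flag_outliers",
]


class QuartileMethod(str, Enum):
    HINGES = "hinges"
    INTERPOLATION = "interpolation"


class FenceKind(str, Enum):
    INNER = "inner"
    OUTER = "outer"
    CUSTOM = "custom"


@dataclass(frozen=True)
class Fences:
    q1: float
    q3: float
    iqr: float
    k: float
    lower: float
    upper: float
    kind: FenceKind


def quartiles(values: Sequence[float],
              method: Union[QuartileMethod, str] = QuartileMethod.HINGES,
              ) -> tuple[float, float]:
    """Lower and upper quartiles under the configured convention."""
    xs = np.sort(np.asarray(values, dtype=float))
    if xs.size < 2:
        raise InsufficientDataError("need n >= 2 for quartiles")
    method = QuartileMethod(method)
    if method is QuartileMethod.INTERPOLATION:
        q1, q3 = np.percentile(xs, [25, 75], method="linear")
        return float(q1), float(q3)
    half = (xs.size + 1) // 2  # halves include the median when n is odd
    return float(np.median(xs[:half])), float(np.median(xs[xs.size - half:]))


def tukey_fences(values: Sequence[float],
                 k: float = 1.5,
                 method: Union[QuartileMethod, str] = QuartileMethod.HINGES,
                 ) -> Fences:
    """Fences at Q1 - k*IQR and Q3 + k*IQR."""
    if k < 0:
        raise ValueError("k must be non-negative")
    q1, q3 = quartiles(values, method)
    iqr = q3 - q1
    kind = (FenceKind.INNER if k == 1.5
            else FenceKind.OUTER if k == 3
            else FenceKind.CUSTOM)
    return Fences(q1=q1, q3=q3, iqr=iqr, k=float(k),
                  lower=q1 - k * iqr, upper=q3 + k * iqr, kind=kind)


def sigma_limits(values: Sequence[float], n_sigma: float = 3.0) -> ControlLimits:
    """Average-and-SD chart limits: mean +/- n_sigma * sample SD."""
    xs = np.asarray(values, dtype=float)
    if xs.size < 2:
        raise InsufficientDataError("need n >= 2 for sigma limits")
    mean = float(xs.mean())
    sd = float(xs.std(ddof=1))
    return ControlLimits(
        chart_kind=ChartKind.AVERAGE_SD,
        center=mean,
        lower=mean - n_sigma * sd,
        upper=mean + n_sigma * sd,
    )


def flag_outliers(values: Sequence[float],
                  bounds: Union[Fences, ControlLimits]) -> frozenset[int]:
    """Indices strictly outside [bounds.lower, bounds.upper]."""
    xs = np.asarray(values, dtype=float)
    outside = (xs < bounds.lower) | (xs > bounds.upper)
    return frozenset(int(i) for i in np.nonzero(outside)[0])
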