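"""Extremes of the average moving range over all orderings of a data set.

For data x_1 <= x_2 <= ... <= x_n with gaps delta_j = x_{j+1} - x_j, every
ordering y induces a sum of moving ranges S(y) = sum_j |y_{j+1} - y_j| that
can be written as sum_j c_j(y) * delta_j, where c_j(y) counts how many
consecutive pairs of y straddle the j-th gap.  Over the n!/2 essentially
distinct orderings (reversal leaves S unchanged):

* S_min = x_n - x_1: the sorted order crosses each gap exactly once, so
  mR_bar_min = (x_n - x_1)/(n - 1).
* S_max is attained by a zigzag that alternates between the lower and upper
  halves of the sorted data.  Its coefficient vector rises 2, 4, ... from
  both ends and peaks at n-1:
    - n even: (2, 4, ..., n-2, n-1, n-2, ..., 4, 2), peak on the middle gap;
    - n odd:  outer coefficients (2, 4, ..., n-3) on each side; the two
      central gaps get (n-2, n-1) when the upper central gap is at least the
      lower one, and (n-1, n-2) otherwise (the larger coefficient goes on
      the larger gap; when the central gaps are equal the two variants
      coincide).
* S_max - S_min = sum_j (c_j - 1) * delta_j, since S_min carries coefficient
  1 on every gap.

The closed forms are stated without proof in the source literature; this
module therefore carries an exhaustive brute-force oracle (n <= 9) and the
constructed maximising ordering is always verified against the closed form
rather than trusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Sequence

import numpy as np

from .core import InsufficientDataError, OrderSpcError

__all__ = [
    "ParityCase",
    "DeltaVector",
    "ExtremalResult",
    "deltas",
    "max_coefficients",
    "s_min",
    "s_max",
    "extremal_orderings",
    "compute_extrema",
    "brute_force_extrema",
    "mr_bar_range",
    "BRUTE_FORCE_MAX_N",
    "OracleSizeError",
    "MaxOrderingError",
]

BRUTE_FORCE_MAX_N = 9  # 9!/2 = 181,440 orderings; 10! is past the quick-test budget


class OracleSizeError(OrderSpcError):
    """Raised when the exhaustive oracle is asked for more than 9 points."""


class MaxOrderingError(OrderSpcError):
    """The constructed maximising ordering failed verification (a bug, never silent)."""


class ParityCase(str, Enum):
    ODD_CASE_I_A = "odd_case_I_a"    # n odd, upper central gap >= lower
    ODD_CASE_I_B = "odd_case_I_b"    # n odd, lower central gap > upper
    EVEN_CASE_II = "even_case_II"    # n even
    DEGENERATE_N2 = "degenerate_n2"  # n = 2: only one ordering up to reversal


@dataclass(frozen=True)
class DeltaVector:
    """Sorted values and their n-1 successive gaps delta_j = x_{j+1} - x_j."""

    sorted_values: tuple[float, ...]
    deltas: tuple[float, ...]


@dataclass(frozen=True)
class ExtremalResult:
    s_min: float
    s_max: float
    mr_bar_min: float
    mr_bar_max: float
    min_ordering: tuple[float, ...]
    max_ordering: tuple[float, ...]
    n: int
    parity_case: ParityCase


def deltas(values: Sequence[float]) -> DeltaVector:
    """Sort the values non-descending and return the successive gaps."""
    xs = np.sort(np.asarray(values, dtype=float))
    if xs.size < 2:
        raise InsufficientDataError("need n >= 2 for gap analysis")
    return DeltaVector(tuple(float(v) for v in xs),
                       tuple(float(d) for d in np.diff(xs)))


def _classify(dv: DeltaVector) -> ParityCase:
    n = len(dv.sorted_values)
    if n == 2:
        return ParityCase.DEGENERATE_N2
    if n % 2 == 0:
        return ParityCase.EVEN_CASE_II
    # 1-based central gaps: delta_{(n-1)/2} and delta_{(n+1)/2}
    lower_central = dv.deltas[(n - 1) // 2 - 1]
    upper_central = dv.deltas[(n + 1) // 2 - 1]
    if upper_central >= lower_central:
        return ParityCase.ODD_CASE_I_A
    return ParityCase.ODD_CASE_I_B


def max_coefficients(dv: DeltaVector) -> tuple[int, ...]:
    """The coefficient vector c with S_max = sum_j c_j * delta_j.

    Palindromic for n even; for n odd palindromic except at the two central
    positions, where the larger coefficient (n-1) sits on the larger gap.
    """
    n = len(dv.sorted_values)
    case = _classify(dv)
    if case is ParityCase.DEGENERATE_N2:
        return (1,)
    if case is ParityCase.EVEN_CASE_II:
        rising = list(range(2, n - 1, 2))            # 2, 4, ..., n-2
        return tuple(rising + [n - 1] + rising[::-1])
    rising = list(range(2, n - 2, 2))                # 2, 4, ..., n-3
    if case is ParityCase.ODD_CASE_I_A:
        central = [n - 2, n - 1]
    else:
        central = [n - 1, n - 2]
    return tuple(rising + central + rising[::-1])


def s_min(values: Sequence[float]) -> tuple[float, float]:
    """``(S_min, mR_bar_min)``: S_min = x_n - x_1, attained by the sorted order."""
    dv = deltas(values)
    s = dv.sorted_values[-1] - dv.sorted_values[0]
    return float(s), float(s / (len(dv.sorted_values) - 1))


def s_max(values: Sequence[float]) -> tuple[float, float, ParityCase]:
    """``(S_max, mR_bar_max, parity_case)`` from the closed-form coefficients."""
    dv = deltas(values)
    n = len(dv.sorted_values)
    coeffs = max_coefficients(dv)
    s = float(np.dot(coeffs, dv.deltas))
    return s, s / (n - 1), _classify(dv)


# ---------------------------------------------------------------------------
# Maximising ordering: zigzag construction, always verified
# ---------------------------------------------------------------------------

def _zigzag(xs: Sequence[float], split: int) -> list[float]:
    """Alternate between the top of the lower block and the top/bottom of the
    upper block: start at the largest of the lower block, then repeatedly take
    the largest remaining upper value and the smallest remaining lower value."""
    lower = list(xs[:split])
    upper = list(xs[split:])
    seq = [lower.pop()]
    take_upper = True
    while lower or upper:
        if take_upper and upper:
            seq.append(upper.pop())
        elif lower:
            seq.append(lower.pop(0))
        else:
            seq.append(upper.pop())
        take_upper = not take_upper
    return seq


def _zigzag_candidates(xs: tuple[float, ...]) -> list[tuple[float, ...]]:
    n = len(xs)
    cands = []
    for split in {n // 2, (n + 1) // 2}:
        if 0 < split < n:
            cands.append(tuple(_zigzag(xs, split)))
            # Mirror: reflect values, zigzag, reflect back — swaps which
            # central gap receives the peak coefficient in the odd case.
            reflected = tuple(-v for v in reversed(xs))
            mirrored = _zigzag(reflected, split)
            cands.append(tuple(-v for v in mirrored))
    return cands


def _sum_moving_ranges(ordering: Sequence[float]) -> float:
    return float(np.abs(np.diff(np.asarray(ordering, dtype=float))).sum())


def extremal_orderings(values: Sequence[float]) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Orderings attaining mR_bar_min and mR_bar_max.

    The minimising ordering is the sorted order.  The maximising ordering is
    the best zigzag candidate, verified against the closed-form S_max at
    1e-12 relative tolerance; on a verification failure the exhaustive
    search is used for n <= 9 and :class:`MaxOrderingError` is raised beyond.
    """
    dv = deltas(values)
    xs = dv.sorted_values
    target, _, _ = s_max(values)
    best = max(_zigzag_candidates(xs), key=_sum_moving_ranges)
    achieved = _sum_moving_ranges(best)
    tol = 1e-12 * max(1.0, abs(target))
    if abs(achieved - target) <= tol:
        return xs, best
    if len(xs) <= BRUTE_FORCE_MAX_N:
        res = brute_force_extrema(values)
        return xs, res.max_ordering
    raise MaxOrderingError(
        f"max ordering construction failed: built S={achieved}, closed form S={target}")


def compute_extrema(values: Sequence[float]) -> ExtremalResult:
    """Full extremal analysis: S and mR_bar extremes plus achieving orderings."""
    smn, mr_min = s_min(values)
    smx, mr_max, case = s_max(values)
    min_ord, max_ord = extremal_orderings(values)
    n = len(min_ord)
    return ExtremalResult(smn, smx, mr_min, mr_max, min_ord, max_ord, n, case)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _half_permutations(n: int) -> np.ndarray:
    """All index permutations of range(n) with first index < last index —
    one representative per reversal pair."""
    perms = np.array([p for p in itertools.permutations(range(n)) if p[0] < p[-1]],
                     dtype=np.int8)
    return perms


def brute_force_extrema(values: Sequence[float]) -> ExtremalResult:
    """Exact extrema of mR_bar by enumerating all orderings (2 <= n <= 9).

    Enumerates one ordering per reversal pair (n!/2 evaluations) since the
    average moving range is reversal-invariant.
    """
    dv = deltas(values)
    xs = np.asarray(dv.sorted_values)
    n = xs.size
    if n > BRUTE_FORCE_MAX_N:
        raise OracleSizeError(
            f"instance too large for exhaustive oracle: n={n} > {BRUTE_FORCE_MAX_N}")
    perms = _half_permutations(n)
    arranged = xs[perms]
    sums = np.abs(np.diff(arranged, axis=1)).sum(axis=1)
    i_min = int(np.argmin(sums))
    i_max = int(np.argmax(sums))
    smn = float(sums[i_min])
    smx = float(sums[i_max])
    return ExtremalResult(
        s_min=smn,
        s_max=smx,
        mr_bar_min=smn / (n - 1),
        mr_bar_max=smx / (n - 1),
        min_ordering=tuple(float(v) for v in arranged[i_min]),
        max_ordering=tuple(float(v) for v in arranged[i_max]),
        n=int(n),
        parity_case=_classify(dv),
    )


def mr_bar_range(values: Sequence[float]) -> float:
    """mR_bar_max - mR_bar_min, with the coefficient-reduction identity asserted.

    Because S_min carries coefficient 1 on every gap, S_max - S_min equals
    sum_j (c_j - 1) * delta_j; the identity is recomputed here as an internal
    consistency check before the range is returned.
    """
    dv = deltas(values)
    smn, mr_min = s_min(values)
    smx, mr_max, _ = s_max(values)
    reduced = float(np.dot(np.asarray(max_coefficients(dv)) - 1, dv.deltas))
    if abs((smx - smn) - reduced) > 1e-9 * max(1.0, abs(smx)):
        raise OrderSpcError("coefficient-reduction identity violated (internal error)")
    # divide the S difference once: identical to mr_max - mr_min analytically,
    # and exact on integer data
    return (smx - smn) / (len(dv.sorted_values) - 1)
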