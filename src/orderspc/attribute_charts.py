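"""Minimal p-, np-, c- and u-chart limits.

Attribute charts derive their limits from a pooled rate and the binomial
(p, np) or Poisson (c, u) variance, so the limits depend only on the
multiset of (count, size) pairs — permuting the subgroups cannot change
them.  That permutation invariance is the reason this module exists; it is
implemented only to the depth needed to exercise it, with conventional
Shewhart 3-sigma limits and lower limits floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ChartKind, ControlLimits, OrderSpcError

__all__ = ["AttributeSample", "attribute_limits"]


@dataclass(frozen=True)
class AttributeSample:
    """Counts of events/faults per subgroup, with subgroup sizes where needed.

    ``sizes`` is required for p, np and u charts and must be absent for c
    charts.  For p/np each count may not exceed its subgroup size.
    """

    kind: ChartKind
    counts: tuple[float, ...]
    sizes: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        kind = ChartKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "counts", tuple(float(c) for c in self.counts))
        if self.sizes is not None:
            object.__setattr__(self, "sizes", tuple(float(s) for s in self.sizes))
        if kind not in (ChartKind.P, ChartKind.NP, ChartKind.C, ChartKind.U):
            raise OrderSpcError(f"not an attribute chart kind: {kind}")
        if not self.counts:
            raise OrderSpcError("counts must be non-empty")
        if any(c < 0 for c in self.counts):
            raise OrderSpcError("counts must be non-negative")
        if kind is ChartKind.C:
            if self.sizes is not None:
                raise OrderSpcError("c-charts take no subgroup sizes")
            return
        if self.sizes is None:
            raise OrderSpcError(f"{kind.value}-charts require subgroup sizes")
        if len(self.sizes) != len(self.counts):
            raise OrderSpcError("counts and sizes must have equal length")
        if any(s <= 0 for s in self.sizes):
            raise OrderSpcError("sizes must be positive")
        if kind in (ChartKind.P, ChartKind.NP):
            if any(c > s for c, s in zip(self.counts, self.sizes)):
                raise OrderSpcError("count exceeds subgroup size")
        if kind is ChartKind.NP and len(set(self.sizes)) != 1:
            raise OrderSpcError("np-charts require a constant subgroup size")


def _floored(kind: ChartKind, center: float, half: float) -> ControlLimits:
    lower = center - half
    return ControlLimits(chart_kind=kind, center=center, lower=lower,
                         upper=center + half,
                         lower_clipped_at_zero=lower < 0)


def attribute_limits(sample: AttributeSample) -> list[ControlLimits]:
    """3-sigma limits: one set per subgroup for p/u, a single set for np/c.

    The limits are functions of the pooled totals only, so any permutation
    of the subgroups yields identical limits (up to per-subgroup pairing for
    stair-step p/u limits, which follow their subgroup's size).
    """
    counts = np.asarray(sample.counts)
    if sample.kind is ChartKind.C:
        c_bar = float(counts.mean())
        return [_floored(ChartKind.C, c_bar, 3.0 * math.sqrt(c_bar))]
    sizes = np.asarray(sample.sizes)
    if sample.kind is ChartKind.NP:
        size = float(sizes[0])
        p_bar = float(counts.sum() / sizes.sum())
        half = 3.0 * math.sqrt(size * p_bar * (1.0 - p_bar))
        return [_floored(ChartKind.NP, size * p_bar, half)]
    if sample.kind is ChartKind.P:
        p_bar = float(counts.sum() / sizes.sum())
        return [_floored(ChartKind.P, p_bar,
                         3.0 * math.sqrt(p_bar * (1.0 - p_bar) / float(s)))
                for s in sizes]
    # u-chart: average faults per unit, Poisson variance u_bar / size
    u_bar = float(counts.sum() / sizes.sum())
    return [_floored(ChartKind.U, u_bar, 3.0 * math.sqrt(u_bar / float(s)))
            for s in sizes]
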