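"""Shuffling experiment: the empirical distribution of mR_bar over orderings.

Each resample is a complete, uniformly random permutation of all n values
(every datum appears exactly once per ordering); orderings are drawn with
replacement from the population of n! possible orderings.  The permutations
come from numpy's PCG64 generator seeded explicitly, so identical
``(values, n_resamples, seed)`` give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import InsufficientDataError, OrderSpcError

__all__ = [
    "DEFAULT_N_RESAMPLES",
    "ResampleDistribution",
    "sample_orderings",
    "summarize_distribution",
    "histogram_bins",
]

DEFAULT_N_RESAMPLES = 16_383


@dataclass(frozen=True)
class ResampleDistribution:
    """mR_bar values over sampled orderings, with summary statistics.

    ``summary`` holds mean, standard_error, median, standard_deviation
    (n-1 denominator), range, minimum, maximum and count;
    ``central_interval`` is the central ``coverage`` percentile interval
    (linear interpolation between order statistics).
    """

    seed: int
    n_resamples: int
    mr_values: tuple[float, ...]
    summary: dict = field(default_factory=dict)
    central_interval: tuple[float, float] = (float("nan"), float("nan"))
    coverage: float = 0.95
    degenerate_sd: bool = False


def _summary_stats(mr: np.ndarray, coverage: float) -> tuple[dict, tuple[float, float], bool]:
    if mr.size == 0:
        raise OrderSpcError("empty distribution")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    degenerate = mr.size < 2
    sd = 0.0 if degenerate else float(mr.std(ddof=1))
    if degenerate:
        warnings.warn("standard deviation of a single-element distribution "
                      "reported as 0", stacklevel=3)
    lo_q = 100 * (1 - coverage) / 2
    interval = np.percentile(mr, [lo_q, 100 - lo_q], method="linear")
    summary = {
        "mean": float(mr.mean()),
        "standard_error": sd / float(np.sqrt(mr.size)),
        "median": float(np.median(mr)),
        "standard_deviation": sd,
        "range": float(mr.max() - mr.min()),
        "minimum": float(mr.min()),
        "maximum": float(mr.max()),
        "count": int(mr.size),
    }
    return summary, (float(interval[0]), float(interval[1])), degenerate


def sample_orderings(values: Sequence[float],
                     n_resamples: int = DEFAULT_N_RESAMPLES,
                     seed: int = 0,
                     coverage: float = 0.95) -> ResampleDistribution:
    """Draw ``n_resamples`` random orderings and compute mR_bar for each."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("need n >= 2 to shuffle")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(vals, (int(n_resamples), 1)), axis=1)
    mr = np.abs(np.diff(shuffled, axis=1)).mean(axis=1)
    summary, interval, degenerate = _summary_stats(mr, coverage)
    return ResampleDistribution(
        seed=int(seed),
        n_resamples=int(n_resamples),
        mr_values=tuple(float(v) for v in mr),
        summary=summary,
        central_interval=interval,
        coverage=float(coverage),
        degenerate_sd=degenerate,
    )


def summarize_distribution(dist: ResampleDistribution,
                           coverage: float = 0.95) -> ResampleDistribution:
    """Recompute the summary and central interval at a new coverage level."""
    mr = np.asarray(dist.mr_values, dtype=float)
    summary, interval, degenerate = _summary_stats(mr, coverage)
    return ResampleDistribution(dist.seed, dist.n_resamples, dist.mr_values,
                                summary, interval, float(coverage), degenerate)


def histogram_bins(dist: ResampleDistribution,
                   n_bins: int) -> list[tuple[float, float, int]]:
    """Equal-width bins over [min, max]; right-open except the last bin.

    Degenerate all-equal distributions collapse to a single zero-width bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mr = np.asarray(dist.mr_values, dtype=float)
    if mr.min() == mr.max():
        return [(float(mr.min()), float(mr.max()), int(mr.size))]
    counts, edges = np.histogram(mr, bins=int(n_bins))
    return [(float(edges[i]), float(edges[i + 1]), int(counts[i]))
            for i in range(len(counts))]
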