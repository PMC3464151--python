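"""The ambiguity report: the ordering-dependence argument as one computation.

For a data set without inherent order the report assembles, in one object:
the summary statistics; the closed-form extrema of the average moving range
over all orderings; the XmR control limits those extrema imply and the
difference in their widths (also expressed as a multiple of the data
range); the exact count of possible orderings n! and the n!/2 bound on
distinct mR_bar values; the points flagged under five schemes (XmR limits
from mR_bar_min and from mR_bar_max, inner and outer Tukey fences, and the
3-sigma / average-and-SD chart); an optional resampling distribution; and a
recommendation — XmR for data with an inherent order, an order-free outlier
method otherwise.  The report always records the constants, quartile
convention and seed used, so any analysis it describes can be restated
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (InsufficientDataError, ObservationSet, OrderSpcError,
                   format_sig)
from .extrema import ExtremalResult, ParityCase, compute_extrema
from .outliers import QuartileMethod, flag_outliers, sigma_limits, tukey_fences
from .resampling import ResampleDistribution, sample_orderings
from .xmr import XMR_CONSTANT, xmr_limits

__all__ = [
    "Recommendation",
    "AmbiguityReport",
    "orderings_count",
    "build_report",
    "write_report",
    "load_report",
    "chart_export",
]

FLAG_SCHEMES = ("xmr_min_limits", "xmr_max_limits", "inner_fences",
                "outer_fences", "three_sigma")


class Recommendation(str, Enum):
    USE_XMR = "use_xmr"
    USE_OUTLIER_METHODS = "use_outlier_methods"


def orderings_count(n: int) -> tuple[int, int]:
    """Exact (n!, n!/2): total orderings and the bound on distinct mR_bar values.

    Arbitrary-precision integers throughout — no floating-point factorials.
    """
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    total = math.factorial(n)
    return total, total // 2


@dataclass(frozen=True)
class AmbiguityReport:
    n: int
    data_summary: dict
    extremal: ExtremalResult
    width_min: float
    width_max: float
    width_difference: float
    width_difference_over_range: Optional[float]
    orderings_total: int
    orderings_distinct_upper_bound: int
    flagged_counts: dict
    recommendation: Recommendation
    config: dict
    resample: Optional[ResampleDistribution] = None

    def __post_init__(self):
        if self.width_difference < -1e-9:
            raise OrderSpcError("width_difference must be non-negative")
        if abs(self.width_difference - (self.width_max - self.width_min)) > 1e-9:
            raise OrderSpcError("width_difference inconsistent with widths")
        if self.orderings_distinct_upper_bound * 2 != self.orderings_total:
            raise OrderSpcError("orderings bound must be exactly n!/2")
        if self.flagged_counts["xmr_max_limits"] > self.flagged_counts["xmr_min_limits"]:
            raise OrderSpcError("wider limits cannot flag more points")


def _data_summary(values: Sequence[float]) -> dict:
    xs = np.asarray(values, dtype=float)
    return {
        "mean": float(xs.mean()),
        "median": float(np.median(xs)),
        "sd": float(xs.std(ddof=1)),
        "range": float(xs.max() - xs.min()),
        "min": float(xs.min()),
        "max": float(xs.max()),
        "count": int(xs.size),
    }


def build_report(data: ObservationSet,
                 resample: Optional[tuple[int, int]] = None,
                 quartile_method: Union[QuartileMethod, str] = QuartileMethod.HINGES,
                 limit_constant: float = XMR_CONSTANT) -> AmbiguityReport:
    """Assemble the full ambiguity report for one data set.

    ``resample`` is an optional ``(n_resamples, seed)`` pair enabling the
    shuffling experiment; the extremal analysis itself is closed-form and
    always present.
    """
    values = data.values
    n = data.n
    ext = compute_extrema(values)
    x_min, _ = xmr_limits(values, mr_bar_override=ext.mr_bar_min,
                          constant=limit_constant)
    x_max, _ = xmr_limits(values, mr_bar_override=ext.mr_bar_max,
                          constant=limit_constant)
    summary = _data_summary(values)
    data_range = summary["range"]
    width_diff = x_max.width - x_min.width
    qm = QuartileMethod(quartile_method)
    inner = tukey_fences(values, k=1.5, method=qm)
    outer = tukey_fences(values, k=3.0, method=qm)
    sigma = sigma_limits(values, n_sigma=3.0)
    flagged = {
        "xmr_min_limits": len(flag_outliers(values, x_min)),
        "xmr_max_limits": len(flag_outliers(values, x_max)),
        "inner_fences": len(flag_outliers(values, inner)),
        "outer_fences": len(flag_outliers(values, outer)),
        "three_sigma": len(flag_outliers(values, sigma)),
    }
    total, distinct = orderings_count(n)
    dist = None
    if resample is not None:
        n_resamples, seed = resample
        dist = sample_orderings(values, n_resamples=n_resamples, seed=seed)
    # mean > median on bounded percentage data suggests right skew, for which
    # the fences (not the symmetric 3-sigma rule) are the appropriate method.
    skew_advisory = summary["mean"] > summary["median"]
    config = {
        "limit_constant": float(limit_constant),
        "quartile_method": qm.value,
        "resample_seed": None if resample is None else int(resample[1]),
        "n_resamples": None if resample is None else int(resample[0]),
        "unit_label": data.unit_label,
        "has_inherent_order": bool(data.has_inherent_order),
        "skewed_mean_above_median": bool(skew_advisory),
    }
    return AmbiguityReport(
        n=n,
        data_summary=summary,
        extremal=ext,
        width_min=x_min.width,
        width_max=x_max.width,
        width_difference=width_diff,
        width_difference_over_range=(width_diff / data_range if data_range > 0 else None),
        orderings_total=total,
        orderings_distinct_upper_bound=distinct,
        flagged_counts=flagged,
        recommendation=(Recommendation.USE_XMR if data.has_inherent_order
                        else Recommendation.USE_OUTLIER_METHODS),
        config=config,
        resample=dist,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _report_to_dict(report: AmbiguityReport) -> dict:
    ext = report.extremal
    d = {
        "n": report.n,
        "data_summary": dict(report.data_summary),
        "extremal": {
            "s_min": ext.s_min, "s_max": ext.s_max,
            "mr_bar_min": ext.mr_bar_min, "mr_bar_max": ext.mr_bar_max,
            "min_ordering": list(ext.min_ordering),
            "max_ordering": list(ext.max_ordering),
            "n": ext.n, "parity_case": ext.parity_case.value,
        },
        "width_min": report.width_min,
        "width_max": report.width_max,
        "width_difference": report.width_difference,
        "width_difference_over_range": report.width_difference_over_range,
        "orderings_total": report.orderings_total,
        "orderings_distinct_upper_bound": report.orderings_distinct_upper_bound,
        "flagged_counts": dict(report.flagged_counts),
        "recommendation": report.recommendation.value,
        "config": dict(report.config),
        "resample": None,
    }
    if report.resample is not None:
        r = report.resample
        d["resample"] = {
            "seed": r.seed, "n_resamples": r.n_resamples,
            "mr_values": list(r.mr_values),
            "summary": dict(r.summary),
            "central_interval": list(r.central_interval),
            "coverage": r.coverage,
            "degenerate_sd": r.degenerate_sd,
        }
    return d


def _report_from_dict(d: dict) -> AmbiguityReport:
    e = d["extremal"]
    ext = ExtremalResult(
        s_min=e["s_min"], s_max=e["s_max"],
        mr_bar_min=e["mr_bar_min"], mr_bar_max=e["mr_bar_max"],
        min_ordering=tuple(e["min_ordering"]),
        max_ordering=tuple(e["max_ordering"]),
        n=e["n"], parity_case=ParityCase(e["parity_case"]),
    )
    dist = None
    if d.get("resample") is not None:
        r = d["resample"]
        dist = ResampleDistribution(
            seed=r["seed"], n_resamples=r["n_resamples"],
            mr_values=tuple(r["mr_values"]),
            summary=dict(r["summary"]),
            central_interval=(r["central_interval"][0], r["central_interval"][1]),
            coverage=r["coverage"], degenerate_sd=r["degenerate_sd"],
        )
    return AmbiguityReport(
        n=d["n"], data_summary=dict(d["data_summary"]), extremal=ext,
        width_min=d["width_min"], width_max=d["width_max"],
        width_difference=d["width_difference"],
        width_difference_over_range=d["width_difference_over_range"],
        orderings_total=d["orderings_total"],
        orderings_distinct_upper_bound=d["orderings_distinct_upper_bound"],
        flagged_counts=dict(d["flagged_counts"]),
        recommendation=Recommendation(d["recommendation"]),
        config=dict(d["config"]), resample=dist,
    )


def _flatten(prefix: str, obj, rows: list):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple)):
        pass  # sequences (orderings, raw resample values) stay in the JSON form
    else:
        rows.append((prefix, obj))


def write_report(report: AmbiguityReport, path: Union[str, Path],
                 format: str = "json") -> None:
    """Serialise the report as JSON (lossless), CSV (one row per named
    statistic) or text (display-rounded to 3 significant figures)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_report_to_dict(report), indent=2))
    elif format == "csv":
        rows: list = []
        _flatten("", _report_to_dict(report), rows)
        pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(path, index=False)
    elif format == "text":
        path.write_text(render_text(report))
    else:
        raise ValueError(f"unknown report format: {format}")


def load_report(path: Union[str, Path]) -> AmbiguityReport:
    """Parse a JSON report back into an :class:`AmbiguityReport`."""
    return _report_from_dict(json.loads(Path(path).read_text()))


def render_text(report: AmbiguityReport) -> str:
    """Plain-text report; statistics display-rounded to 3 significant figures."""
    f = format_sig
    s = report.data_summary
    lines = [
        "Ordering-ambiguity report",
        "=========================",
        f"n = {report.n}  (orderings: {report.orderings_total} = {report.n}!,"
        f" distinct mR values <= {report.orderings_distinct_upper_bound})",
        "",
        "Data summary (3 sf): "
        f"mean {f(s['mean'])}, median {f(s['median'])}, SD {f(s['sd'])}, "
        f"min {f(s['min'])}, max {f(s['max'])}, range {f(s['range'])}",
        "",
        f"Average moving range over all orderings: "
        f"min {f(report.extremal.mr_bar_min)}, max {f(report.extremal.mr_bar_max)}",
        f"XmR limit widths: {f(report.width_min)} (from mR_min) to "
        f"{f(report.width_max)} (from mR_max); difference {f(report.width_difference)}"
        + ("" if report.width_difference_over_range is None else
           f" = {f(report.width_difference_over_range)} x the data range"),
        "",
        "Flagged points by scheme: " + ", ".join(
            f"{k}={report.flagged_counts[k]}" for k in FLAG_SCHEMES),
        "",
        f"Recommendation: {report.recommendation.value}",
    ]
    if report.resample is not None:
        r = report.resample
        lines.insert(-1, (
            f"Resampled mR (n={r.n_resamples}, seed={r.seed}): "
            f"mean {f(r.summary['mean'])}, SD {f(r.summary['standard_deviation'])}, "
            f"min {f(r.summary['minimum'])}, max {f(r.summary['maximum'])}, "
            f"central {int(r.coverage * 100)}% in "
            f"({f(r.central_interval[0])}, {f(r.central_interval[1])})"))
        lines.insert(-1, "")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Chart export
# ---------------------------------------------------------------------------

def chart_export(data: ObservationSet, report: AmbiguityReport,
                 path: Union[str, Path],
                 png_path: Optional[Union[str, Path]] = None) -> None:
    """Write a plot-ready CSV: one row per point, one column per bound.

    For percentage data (a ``%`` in the unit label) bounds outside [0, 100]
    are additionally marked as clipped, mirroring the practice of not
    plotting limits outside the percentage scale.  ``png_path`` optionally
    renders a basic chart via matplotlib if it is available.
    """
    values = data.values
    ext = report.extremal
    constant = report.config["limit_constant"]
    x_min, _ = xmr_limits(values, mr_bar_override=ext.mr_bar_min, constant=constant)
    x_max, _ = xmr_limits(values, mr_bar_override=ext.mr_bar_max, constant=constant)
    qm = report.config["quartile_method"]
    inner = tukey_fences(values, k=1.5, method=qm)
    outer = tukey_fences(values, k=3.0, method=qm)
    sigma = sigma_limits(values, n_sigma=3.0)
    bounds = {
        "xmr_min_lower": x_min.lower, "xmr_min_upper": x_min.upper,
        "xmr_max_lower": x_max.lower, "xmr_max_upper": x_max.upper,
        "inner_fence_lower": inner.lower, "inner_fence_upper": inner.upper,
        "outer_fence_lower": outer.lower, "outer_fence_upper": outer.upper,
        "three_sigma_lower": sigma.lower, "three_sigma_upper": sigma.upper,
    }
    percent_scale = "%" in (data.unit_label or "")
    frame = pd.DataFrame({
        "index": range(len(values)),
        "label": data.labels,
        "value": values,
    })
    for name, bound in bounds.items():
        frame[name] = bound
        if percent_scale:
            frame[f"{name}_clipped"] = not (0.0 <= bound <= 100.0)
    frame.to_csv(path, index=False)
    if png_path is not None:
        _render_chart(frame, bounds, data, Path(png_path))


def _render_chart(frame: pd.DataFrame, bounds: dict, data: ObservationSet,
                  png_path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(frame["index"], frame["value"], "o-", color="black", label="data")
    styles = {"xmr_min": "C0", "xmr_max": "C1", "inner_fence": "C2",
              "outer_fence": "C3", "three_sigma": "C4"}
    percent_scale = "%" in (data.unit_label or "")
    for prefix, color in styles.items():
        for side in ("lower", "upper"):
            bound = bounds[f"{prefix}_{side}"]
            if percent_scale and not 0.0 <= bound <= 100.0:
                continue  # limits off the percentage scale are not plotted
            ax.axhline(bound, color=color, linestyle="--", linewidth=0.9,
                       label=prefix if side == "lower" else None)
    ax.set_xlabel("index")
    ax.set_ylabel(data.unit_label or "value")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
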