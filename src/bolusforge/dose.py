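"""PTV dose metrics, plan-difference percentages and column summaries.

Dose comparisons between bolus variants use the signed percentage::

    dD = (Dr - Dm) / Dr * 100 %

with ``Dr`` a PTV dose metric under the reference-bolus plan and ``Dm`` the
same metric under the fabricated-bolus plan (negative when the fabricated
plan delivers more dose).

Per-metric columns across a patient cohort are summarised with a
Shapiro-Wilk normality gate: normal columns as mean +/- sample SD,
non-normal ones as median with quartiles.  Quartiles use the rank position
``(n + 1) p`` with linear interpolation, the convention under which, for
n = 11, Q1 and Q3 are exactly the 3rd and 9th order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import VoxelGrid

__all__ = [
    "DoseGrid",
    "PTVDoseMetrics",
    "DoseComparison",
    "ColumnSummary",
    "ptv_dose_metrics",
    "delta_d",
    "compare_plans",
    "summarize_column",
    "round_report",
]


def round_report(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of clinical report tables."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class DoseGrid:
    """A dose raster (Gy) with a companion PTV occupancy mask on one lattice."""

    dose: VoxelGrid
    ptv_mask: np.ndarray  # boolean, same dims as dose.values

    def __post_init__(self) -> None:
        self.ptv_mask = np.asarray(self.ptv_mask, dtype=bool)
        if self.ptv_mask.shape != self.dose.values.shape:
            raise ValueError("PTV mask must share the dose lattice")
        if np.any(self.dose.values < 0):
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class PTVDoseMetrics:
    """Five-point PTV dose summary in Gy.

    ``d_near_min``/``d_near_max`` are the robust DVH extremes D98%/D2%: the
    dose exceeded by 98% (respectively 2%) of the PTV volume, evaluated as
    the 2nd/98th dose-volume percentile with linear interpolation.
    """

    d_min: float
    d_near_min: float  # D98%
    d_mean: float
    d_near_max: float  # D2%
    d_max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "min": self.d_min,
            "near_min": self.d_near_min,
            "mean": self.d_mean,
            "near_max": self.d_near_max,
            "max": self.d_max,
        }


@dataclass(frozen=True)
class DoseComparison:
    """One metric under reference (Dr) and fabricated (Dm) plans, in Gy."""

    dr: float
    dm: float
    delta_d: float  # percent

    def __post_init__(self) -> None:
        expected = (self.dr - self.dm) / self.dr * 100.0
        if abs(self.delta_d - expected) > 1e-9 * max(abs(expected), 1.0):
            raise ValueError("delta_d inconsistent with Dr, Dm")


def ptv_dose_metrics(d: DoseGrid) -> PTVDoseMetrics:
    """Min, D98%, mean, D2% and max dose over the PTV mask."""
    vals = d.dose.values[d.ptv_mask]
    if vals.size == 0:
        raise ValueError("PTV mask selects no voxels")
    vals = np.asarray(vals, dtype=float)
    return PTVDoseMetrics(
        d_min=float(vals.min()),
        d_near_min=float(np.quantile(vals, 0.02)),
        d_mean=float(vals.mean()),
        d_near_max=float(np.quantile(vals, 0.98)),
        d_max=float(vals.max()),
    )


def delta_d(dr: float, dm: float) -> float:
    """Signed percent difference of a dose metric between two plans."""
    if dr <= 0:
        raise ValueError("reference dose must be positive")
    return (dr - dm) / dr * 100.0


def compare_plans(
    ref: DoseGrid | PTVDoseMetrics, test: DoseGrid | PTVDoseMetrics
) -> dict[str, DoseComparison]:
    """Per-metric dose comparison between a reference and a fabricated plan."""
    mr = ref if isinstance(ref, PTVDoseMetrics) else ptv_dose_metrics(ref)
    mt = test if isinstance(test, PTVDoseMetrics) else ptv_dose_metrics(test)
    out = {}
    for key, dr in mr.as_dict().items():
        dm = mt.as_dict()[key]
        out[key] = DoseComparison(dr=dr, dm=dm, delta_d=delta_d(dr, dm))
    return out


@dataclass(frozen=True)
class ColumnSummary:
    """Normality-gated summary of one cohort column.

    All four statistics are always populated; ``mode`` records which pair
    the normality gate (or an explicit override) selected for reporting.
    """

    n: int
    shapiro_p: float  # nan when normality is undefined (constant column)
    is_normal: bool | None
    mean: float
    sd: float  # sample SD (n - 1)
    median: float
    q1: float
    q3: float
    mode: str  # "mean_sd" | "median_quartiles"


def _rank_quantile(sorted_vals: np.ndarray, p: float) -> float:
    """Quantile at rank position (n + 1) p with linear interpolation."""
    n = len(sorted_vals)
    pos = (n + 1) * p
    pos = min(max(pos, 1.0), float(n))
    lo = int(math.floor(pos))
    frac = pos - lo
    if lo >= n:
        return float(sorted_vals[-1])
    return float(sorted_vals[lo - 1] + frac * (sorted_vals[lo] - sorted_vals[lo - 1]))


def summarize_column(
    values, alpha: float = 0.05, mode: str = "auto"
) -> ColumnSummary:
    """Summarise a column of per-patient percentages (or any scalar column).

    ``mode="auto"`` runs the Shapiro-Wilk test at ``alpha`` and reports
    mean +/- SD when p > alpha, else median with (n + 1) p quartiles.
    Explicit ``mean_sd`` / ``median_quartiles`` overrides exist because a
    published cohort's recorded normality outcomes are facts, not something
    to re-adjudicate.  A constant column has undefined normality and falls
    back to mean with SD 0.
    """
    vals = np.asarray(list(values), dtype=float)
    n = len(vals)
    if mode not in ("auto", "mean_sd", "median_quartiles"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto" and n < 3:
        raise ValueError("auto mode needs at least 3 values for the normality test")
    if n == 0:
        raise ValueError("empty column")
    s = np.sort(vals)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    median = _rank_quantile(s, 0.5)
    q1 = _rank_quantile(s, 0.25)
    q3 = _rank_quantile(s, 0.75)
    shapiro_p = float("nan")
    is_normal: bool | None = None
    if np.ptp(vals) == 0.0:
        chosen = "mean_sd" if mode == "auto" else mode
        return ColumnSummary(n, shapiro_p, None, mean, 0.0, median, q1, q3, chosen)
    if mode == "auto" or n >= 3:
        try:
            shapiro_p = float(stats.shapiro(vals).pvalue)
            is_normal = shapiro_p > alpha
        except ValueError:  # pragma: no cover - tiny n with override mode
            pass
    if mode == "auto":
        chosen = "mean_sd" if is_normal else "median_quartiles"
    else:
        chosen = mode
    return ColumnSummary(n, shapiro_p, is_normal, mean, sd, median, q1, q3, chosen)
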