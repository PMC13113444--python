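"""Gait-cycle resampling and waveform agreement statistics.

Estimated and reference force profiles are compared on a common 0-100 %
gait-cycle grid.  Pearson correlation quantifies linear agreement for
non-pathological gait; Spearman (rank) correlation is preferred for stroke
gait, where extreme-value deviations break linearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CYCLE_GRID_POINTS

__all__ = [
    "ComparisonReport",
    "resample_to_cycle",
    "pearson_r",
    "spearman_rho",
    "classify_strength",
    "compare_waveforms",
    "DEFAULT_STRENGTH_CUTS",
]

#: |r| at or above the second cut is "strong", at or above the first
#: "moderate", otherwise "weak".  Values exactly at a cut take the higher band.
DEFAULT_STRENGTH_CUTS = (0.5, 0.8)

CYCLE_GRID = np.linspace(0.0, 100.0, CYCLE_GRID_POINTS)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-muscle agreement between an estimated and a reference waveform."""

    muscle: str
    coefficient: float
    method: str
    condition: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise ValueError(f"correlation coefficient out of [-1, 1]: {self.coefficient}")


def resample_to_cycle(times, values, events) -> np.ndarray:
    """Resample a time series onto the 101-point gait-cycle grid.

    ``events`` are successive foot-strike times of one foot; each pair of
    consecutive events bounds one cycle, which is linearly interpolated onto
    the 0-100 % grid.  Multiple cycles are averaged pointwise.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    events = np.sort(np.asarray(events, dtype=float))
    if events.size < 2:
        raise ValueError("at least two foot-strike events are required")
    dt = np.median(np.diff(times)) if times.size > 1 else 0.0
    if events[0] < times[0] - dt or events[-1] > times[-1] + dt:
        raise ValueError("events fall outside the sampled time range")
    cycles = []
    for start, stop in zip(events[:-1], events[1:]):
        grid_t = start + (CYCLE_GRID / 100.0) * (stop - start)
        cycles.append(np.interp(grid_t, times, values))
    return np.mean(cycles, axis=0)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("at least 3 samples are required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation is undefined for a constant series")
    return a, b


def pearson_r(a, b) -> float:
    """Product-moment correlation between two equal-length waveforms."""
    a, b = _check_pair(a, b)
    return float(stats.pearsonr(a, b).statistic)


def spearman_rho(a, b) -> float:
    """Rank correlation (Pearson on average ranks) between two waveforms."""
    a, b = _check_pair(a, b)
    return float(stats.spearmanr(a, b).statistic)


def classify_strength(coefficient: float, cuts: tuple[float, float] = DEFAULT_STRENGTH_CUTS) -> str:
    """Map |r| to a qualitative band: weak / moderate / strong."""
    if not -1.0 - 1e-12 <= coefficient <= 1.0 + 1e-12:
        raise ValueError(f"coefficient must lie in [-1, 1], got {coefficient}")
    lo, hi = cuts
    mag = abs(coefficient)
    if mag >= hi:
        return "strong"
    if mag >= lo:
        return "moderate"
    return "weak"


def compare_waveforms(
    estimated: pd.DataFrame,
    reference: pd.DataFrame,
    method: str = "pearson",
    condition: str = "",
) -> list[ComparisonReport]:
    """Correlate estimated vs reference waveforms muscle by muscle.

    Both frames are wide-format: a ``cycle_pct`` column plus one column per
    muscle.  Only muscles present in both frames are compared.
    """
    corr = {"pearson": pearson_r, "spearman": spearman_rho}.get(method)
    if corr is None:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    shared = [c for c in estimated.columns if c != "cycle_pct" and c in reference.columns]
    if not shared:
        raise ValueError("no shared muscle columns between the two tables")
    reports = []
    for muscle in shared:
        r = corr(estimated[muscle].to_numpy(), reference[muscle].to_numpy())
        reports.append(
            ComparisonReport(
                muscle=muscle,
                coefficient=r,
                method=method,
                condition=condition,
                band=classify_strength(r),
            )
        )
    return reports
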