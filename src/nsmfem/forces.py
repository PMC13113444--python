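"""Normalized active/passive muscle force and cycle-offset compensation.

The force-length model is a simplified Hill-type relation driven only by
the normalized fiber length L/L0 and the architecture index Ia; muscle
activation is deliberately absent (the model targets slow gait, where a
kinematics-only estimate tracks reference forces well).

Active force peaks at 1 when L = L0 and decays on either side; passive
force grows exponentially with stretch and only becomes prominent beyond
the optimal length.  Because active force is generated while the muscle
shortens, its peak lags the muscle-length peak by a roughly constant
fraction of the gait cycle; that lag (the "cycle offset") is compensated by
circularly shifting the active waveform.  A packaged table supplies the
observed per-muscle offsets for five walking conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import CYCLE_GRID_POINTS, MUSCLE_NAMES

__all__ = [
    "ForceProfile",
    "CycleOffsetTable",
    "CONDITIONS",
    "active_force",
    "passive_force",
    "apply_cycle_offset",
    "estimate_cycle_offset",
    "normalize_profile",
    "mean_cycle_offset",
    "load_cycle_offsets",
]

#: Walking conditions of the packaged cycle-offset table.  ESND = elderly
#: subjects, no lower-limb disease; ESP = elderly stroke patients.
CONDITIONS = ("ESP_free", "ESND_R_fast", "ESND_free", "ESND_slow", "ESND_X_slow")

#: Map from a trial's speed label to the matching non-pathological condition.
SPEED_LABEL_TO_CONDITION = {
    "X-slow": "ESND_X_slow",
    "slow": "ESND_slow",
    "free": "ESND_free",
    "R-fast": "ESND_R_fast",
}

_GRID = np.linspace(0.0, 100.0, CYCLE_GRID_POINTS)


@dataclass
class ForceProfile:
    """Normalized force waveforms for one muscle on the 0-100 % cycle grid."""

    muscle: str
    active: np.ndarray
    passive: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: _GRID.copy())
    applied_offset_pct: float = 0.0

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=float)
        self.passive = np.asarray(self.passive, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if not (len(self.active) == len(self.passive) == len(self.grid)):
            raise ValueError("active, passive and grid series must have equal length")
        if np.any(self.passive < 0):
            raise ValueError("passive force must be non-negative")


def _validate_lengths(L, L0) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("fiber length L must be positive")
    if not np.isscalar(L0) and np.asarray(L0).ndim:
        raise ValueError("L0 must be a scalar")
    if L0 <= 0:
        raise ValueError("optimal fiber length L0 must be positive")
    return L / L0


def active_force(L, L0: float, Ia: float):
    """Normalized active force f_l(L/L0, Ia) in (0, 1], maximal at L = L0.

    For a parallel muscle (Ia = 1)::

        f_l = exp(-2.727 * ln(L/L0)^2)

    For pennate muscles (Ia < 1) the bell narrows with increasing Ia::

        f_l = exp(-(((L/L0)**0.9631 - 1) / (0.3531 * (1 - Ia)))**2)

    Both branches equal 1 exactly at L = L0 and fall monotonically away
    from it.  ``L`` may be a scalar or an array; ``L0`` and ``Ia`` are
    scalars.
    """
    ratio = _validate_lengths(L, L0)
    if not 0.0 < Ia <= 1.0:
        raise ValueError(f"architecture index must lie in (0, 1], got {Ia}")
    if Ia == 1.0:
        out = np.exp(-2.727 * np.log(ratio) ** 2)
    else:
        out = np.exp(-(((ratio**0.9631) - 1.0) / (0.3531 * (1.0 - Ia))) ** 2)
    return float(out) if np.isscalar(L) else out


def passive_force(L, L0: float, Ia: float):
    """Normalized passive force f_p = 0.0195 * exp((2.933 + 4.911*Ia) * (L/L0 - 1)).

    Strictly increasing in L; equals 0.0195 at the optimal length and only
    becomes prominent for L > L0.  Larger architecture indices stiffen the
    exponential rise.
    """
    ratio = _validate_lengths(L, L0)
    if not 0.0 < Ia <= 1.0:
        raise ValueError(f"architecture index must lie in (0, 1], got {Ia}")
    out = 0.0195 * np.exp((2.933 + 4.911 * Ia) * (ratio - 1.0))
    return float(out) if np.isscalar(L) else out


def _roll_cycle(series: np.ndarray, steps: int) -> np.ndarray:
    """Circularly shift a 101-point cycle series forward by whole grid steps.

    The grid duplicates the cycle endpoint (0 % == 100 %), so the shift
    operates on the first 100 samples and the duplicate is rebuilt.
    """
    core = np.roll(series[:-1], steps)
    return np.concatenate([core, core[:1]])


def apply_cycle_offset(profile: ForceProfile, offset_pct: float) -> ForceProfile:
    """Compensate the active waveform by a forward circular shift.

    Only the active series is shifted: passive force depends on the
    instantaneous fiber length alone, so it carries no electromechanical
    lag.  The offset is quantized to the nearest 1 % grid step.
    """
    if not 0.0 <= offset_pct < 100.0:
        raise ValueError(f"offset must lie in [0, 100), got {offset_pct}")
    steps = int(round(offset_pct)) % 100
    return replace(
        profile,
        active=_roll_cycle(profile.active, steps),
        passive=profile.passive.copy(),
        applied_offset_pct=profile.applied_offset_pct + offset_pct,
    )


def estimate_cycle_offset(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Circular lag (in % cycle) that best aligns candidate onto reference.

    Maximizes the circular cross-correlation of the mean-centered series
    over all whole-grid lags; ties break toward the smallest lag.  Applying
    the returned offset to the candidate aligns the waveform peaks to
    within one grid step.
    """
    a = np.asarray(candidate, dtype=float)[: CYCLE_GRID_POINTS - 1]
    b = np.asarray(reference, dtype=float)[: CYCLE_GRID_POINTS - 1]
    if a.shape != b.shape:
        raise ValueError("candidate and reference must share the cycle grid")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cycle offset is undefined for a constant series")
    a = a - a.mean()
    b = b - b.mean()
    # c[k] = sum_i a[i - k] * b[i], circular: correlation after shifting a by k.
    corr = np.array([np.dot(np.roll(a, k), b) for k in range(len(a))])
    return float(np.argmax(corr))


def normalize_profile(series: np.ndarray) -> np.ndarray:
    """Divide a waveform by its maximum so the output peaks at exactly 1."""
    s = np.asarray(series, dtype=float)
    peak = s.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("series must have a positive finite maximum")
    return s / peak


@dataclass
class CycleOffsetTable:
    """Per-muscle, per-condition active-force cycle offsets (% of cycle)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "muscle" in self.table.columns:
            self.table = self.table.set_index("muscle")
        bad = [c for c in self.table.columns if c not in CONDITIONS]
        if bad:
            raise ValueError(f"unknown conditions in offset table: {bad}")
        values = self.table.to_numpy(dtype=float)
        if np.any((values < 0) | (values >= 100)):
            raise ValueError("cycle offsets must lie in [0, 100)")

    def offset(self, muscle: str, condition: str) -> float:
        if condition not in self.table.columns:
            raise KeyError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        if muscle not in self.table.index:
            raise KeyError(f"unknown muscle {muscle!r}")
        return float(self.table.loc[muscle, condition])


def load_cycle_offsets() -> CycleOffsetTable:
    """Load the packaged cycle-offset table for the five walking conditions."""
    with resources.files("nsmfem.data").joinpath("cycle_offsets.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    return CycleOffsetTable(table)


def mean_cycle_offset(table: CycleOffsetTable, condition: str) -> float:
    """Arithmetic mean of the nine per-muscle offsets for one condition."""
    if condition not in table.table.columns:
        raise KeyError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    missing = [m for m in MUSCLE_NAMES if m not in table.table.index]
    if missing:
        raise KeyError(f"offset table is missing muscles: {missing}")
    return float(np.mean([table.offset(m, condition) for m in MUSCLE_NAMES]))
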