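"""Subject anthropometry: trunk regression, scale factors and segment masses.

A personalized digital-twin skeleton is obtained from a generic model by
geometric linear scaling: each segment's scale factor is the ratio of the
subject's segment length to the generic model's.  The trunk (sternum-head
distance) is rarely measured directly, so it is regressed from height,
weight or sitting height; the height branch has by far the best fit
(r² = 0.97) and is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AnthropometricProfile",
    "RegressionFit",
    "ScaleSet",
    "STERNUM_HEAD_REGRESSIONS",
    "estimate_sternum_head",
    "compute_scale_factors",
    "scale_optimal_fiber_length",
    "segment_mass",
    "load_mass_fractions",
    "load_subject_profile",
]


@dataclass(frozen=True)
class RegressionFit:
    """A fitted univariate linear regression y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


#: Sternum-head distance (mm) regressed on a single anthropometric predictor.
#: Inputs: height in mm, body mass in kg, sitting height in mm.
STERNUM_HEAD_REGRESSIONS: dict[str, RegressionFit] = {
    "height": RegressionFit(slope=0.3674, intercept=-297.0699, r_squared=0.97),
    "weight": RegressionFit(slope=2.1135, intercept=-188.2610, r_squared=0.52),
    "sitting": RegressionFit(slope=0.7111, intercept=-310.3478, r_squared=0.94),
}


@dataclass
class AnthropometricProfile:
    """A subject's body dimensions used to scale the generic skeleton.

    ``sternum_head_mm`` may be measured directly; when left unset it is
    derived from height via the regression's height branch.
    """

    height_mm: float
    mass_kg: float
    sitting_height_mm: float | None = None
    sternum_head_mm: float | None = None
    segment_lengths_mm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height_mm <= 0:
            raise ValueError(f"height_mm must be positive, got {self.height_mm}")
        if self.mass_kg <= 0:
            raise ValueError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.sitting_height_mm is not None and self.sitting_height_mm <= 0:
            raise ValueError("sitting_height_mm must be positive when given")
        for name, length in self.segment_lengths_mm.items():
            if length <= 0:
                raise ValueError(f"segment {name!r} has non-positive length {length}")
        if self.sternum_head_mm is None:
            self.sternum_head_mm = estimate_sternum_head(self, branch="height")


@dataclass(frozen=True)
class ScaleSet:
    """Per-segment dimensionless scale factors plus segment mass fractions."""

    factors: dict[str, float]
    mass_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"scale factor for {name!r} must be positive, got {f}")
        for name, c in self.mass_coefficients.items():
            if not 0.0 <= c < 1.0:
                raise ValueError(f"mass fraction for {name!r} must lie in [0, 1), got {c}")

    def factor(self, segment: str) -> float:
        """Scale factor for a segment; ``femur_r`` falls back to ``femur``."""
        if segment in self.factors:
            return self.factors[segment]
        base = segment.rsplit("_", 1)[0]
        if base in self.factors:
            return self.factors[base]
        raise KeyError(f"no scale factor for segment {segment!r}")


def estimate_sternum_head(profile: AnthropometricProfile, branch: str = "height") -> float:
    """Estimate the sternum-head distance (mm) from one body dimension.

    Parameters
    ----------
    profile
        Subject anthropometry.  The selected branch's field must be set.
    branch
        ``"height"`` (default, best fit), ``"weight"`` or ``"sitting"``.
    """
    if branch not in STERNUM_HEAD_REGRESSIONS:
        raise ValueError(
            f"unknown branch {branch!r}; expected one of {sorted(STERNUM_HEAD_REGRESSIONS)}"
        )
    value = {
        "height": profile.height_mm,
        "weight": profile.mass_kg,
        "sitting": profile.sitting_height_mm,
    }[branch]
    if value is None:
        raise ValueError(f"branch {branch!r} requires a value but none was provided")
    if value <= 0:
        raise ValueError(f"branch {branch!r} input must be positive, got {value}")
    return STERNUM_HEAD_REGRESSIONS[branch].predict(value)


def compute_scale_factors(
    subject_segments: dict[str, float],
    generic_segments: dict[str, float],
    mass_coefficients: dict[str, float] | None = None,
) -> ScaleSet:
    """Per-segment scale factors = subject length / generic length.

    Both maps must share their segment keys; every length must be positive.
    Factors are applied isotropically to the segment's attachment
    coordinates and optimal fiber lengths.
    """
    missing = set(subject_segments) ^ set(generic_segments)
    if missing:
        raise KeyError(f"segment keys differ between subject and generic model: {sorted(missing)}")
    factors: dict[str, float] = {}
    for name in subject_segments:
        subj, gen = subject_segments[name], generic_segments[name]
        if subj <= 0:
            raise ValueError(f"subject segment {name!r} has non-positive length {subj}")
        if gen <= 0:
            raise ValueError(f"generic segment {name!r} has non-positive length {gen}")
        factors[name] = subj / gen
    if mass_coefficients is None:
        mass_coefficients = load_mass_fractions()
    return ScaleSet(factors=factors, mass_coefficients=mass_coefficients)


def scale_optimal_fiber_length(l0_generic: float, segment_factor: float) -> float:
    """Subject optimal fiber length = generic value x the segment's scale factor."""
    if l0_generic <= 0:
        raise ValueError(f"generic optimal fiber length must be positive, got {l0_generic}")
    if segment_factor <= 0:
        raise ValueError(f"segment scale factor must be positive, got {segment_factor}")
    return l0_generic * segment_factor


def load_mass_fractions() -> dict[str, float]:
    """Packaged table of segment mass fractions of total body mass."""
    with resources.files("nsmfem.data").joinpath("segment_mass_fractions.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    fractions = dict(zip(table["segment"], table["fraction"].astype(float)))
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("packaged mass fractions sum to more than 1")
    return fractions


def segment_mass(
    total_mass_kg: float,
    segment: str,
    coefficients: dict[str, float] | None = None,
) -> float:
    """Segment mass = total body mass x the segment's proportional coefficient."""
    if total_mass_kg <= 0:
        raise ValueError(f"total mass must be positive, got {total_mass_kg}")
    if coefficients is None:
        coefficients = load_mass_fractions()
    base = segment.rsplit("_", 1)[0]
    key = segment if segment in coefficients else base
    if key not in coefficients:
        raise KeyError(f"no mass coefficient for segment {segment!r}")
    return total_mass_kg * coefficients[key]


def load_subject_profile(path: str | Path) -> AnthropometricProfile:
    """Read a subject config (YAML or JSON) into an :class:`AnthropometricProfile`.

    Expected keys: ``height_mm``, ``mass_kg``, optional ``sitting_height_mm``,
    ``sternum_head_mm`` and ``segment_lengths_mm``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    return AnthropometricProfile(
        height_mm=float(raw["height_mm"]),
        mass_kg=float(raw["mass_kg"]),
        sitting_height_mm=(
            float(raw["sitting_height_mm"]) if raw.get("sitting_height_mm") is not None else None
        ),
        sternum_head_mm=(
            float(raw["sternum_head_mm"]) if raw.get("sternum_head_mm") is not None else None
        ),
        segment_lengths_mm={k: float(v) for k, v in raw.get("segment_lengths_mm", {}).items()},
    )
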