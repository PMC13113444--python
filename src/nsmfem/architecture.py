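"""Muscle architecture index from pennation angle and optimal fiber length.

The architecture index Ia is a dimensionless summary of a muscle's fiber
arrangement: 1 for a parallel-fibered muscle, decreasing as pennation
concentrates fibers.  It is obtained from a quadratic regression on
published cadaveric architecture data; muscles with pennation below 5
degrees are treated as parallel (Ia = 1) because the regression's source
data only covers 5-25 degrees.

Units: the regression was fit with optimal fiber lengths tabulated in
centimetres; callers holding millimetre model units must convert (the
pipeline does this internally, see ``OPTIMAL_LENGTH_UNIT_CM``).
"""

from __future__ import annotations

import math
import warnings

__all__ = [
    "architecture_index",
    "PARALLEL_PENNATION_DEG",
    "PENNATION_RANGE_DEG",
    "ARCHITECTURE_COEFFS",
]

#: Below this pennation angle (degrees) a muscle counts as parallel, Ia = 1.
PARALLEL_PENNATION_DEG = 5.0

#: Pennation range (degrees) covered by the regression's source data.
PENNATION_RANGE_DEG = (5.0, 25.0)

#: Regression coefficients for Ia(x, y): constant, x, x*y, x^2, y, y^2,
#: with x = pennation angle in degrees and y = optimal fiber length in cm.
ARCHITECTURE_COEFFS = {
    "const": 0.1546,
    "x": -5.7662e-5,
    "xy": 6.6753e-4,
    "x2": -2.0563e-4,
    "y": -1.3233e-3,
    "y2": 7.6327e-4,
}

#: Expected unit of ``optimal_length`` (centimetres); a millimetre value
#: passed by mistake inflates the y^2 term a hundredfold.
OPTIMAL_LENGTH_UNIT_CM = True

_CLAMP_FLOOR = 1e-6  # Ia must stay positive for the force model's (0, 1] domain


def architecture_index(pennation_deg: float, optimal_length: float) -> float:
    """Architecture index Ia in (0, 1] for one muscle.

    Parameters
    ----------
    pennation_deg
        Pennation angle in degrees.  Below 5 degrees the muscle is treated
        as parallel and Ia is exactly 1; above 25 degrees the regression is
        evaluated outside its calibration range and a warning is issued.
    optimal_length
        Optimal fiber length in centimetres.

    The raw polynomial can leave (0, 1] for long-fibered inputs; the result
    is then clamped with a warning rather than silently propagated, because
    the force-length model requires Ia in (0, 1].
    """
    if not (math.isfinite(pennation_deg) and math.isfinite(optimal_length)):
        raise ValueError("pennation angle and optimal length must be finite")
    if pennation_deg < 0:
        raise ValueError(f"pennation angle must be non-negative, got {pennation_deg}")
    if optimal_length <= 0:
        raise ValueError(f"optimal length must be positive, got {optimal_length}")

    if pennation_deg < PARALLEL_PENNATION_DEG:
        return 1.0
    if pennation_deg > PENNATION_RANGE_DEG[1]:
        warnings.warn(
            f"pennation {pennation_deg:.1f} deg is outside the regression's "
            f"{PENNATION_RANGE_DEG[0]:.0f}-{PENNATION_RANGE_DEG[1]:.0f} deg calibration range",
            stacklevel=2,
        )

    c = ARCHITECTURE_COEFFS
    x, y = pennation_deg, optimal_length
    raw = (
        c["const"]
        + c["x"] * x
        + c["xy"] * x * y
        + c["x2"] * x * x
        + c["y"] * y
        + c["y2"] * y * y
    )
    if raw > 1.0 or raw <= 0.0:
        warnings.warn(
            f"architecture index {raw:.4f} outside (0, 1] for pennation "
            f"{x:.1f} deg, L0 {y:.2f} cm; clamping",
            stacklevel=2,
        )
        return min(max(raw, _CLAMP_FLOOR), 1.0)
    return raw
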