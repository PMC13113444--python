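"""End-to-end force estimation: body model + gait trial -> force profiles.

For each muscle: map attachments through the segment poses, take the
straight-line muscle-tendon length sample by sample, resample to the
0-100 % gait cycle, normalize by the (optionally subject-scaled) optimal
length, evaluate the active and passive force-length relations, compensate
the active waveform by the condition's cycle offset, and normalize the
active curve to its peak.
"""

from __future__ import annotations

import numpy as np

from . import forces as f
from .anthropometry import ScaleSet, scale_optimal_fiber_length
from .geometry import MusclePath, length_timeseries
from .synthetic import BodyModel, GaitTrial, mirror_muscle

__all__ = ["estimate_muscle_forces", "scaled_muscle"]


def scaled_muscle(path: MusclePath, scale_set: ScaleSet | None) -> MusclePath:
    """Apply per-segment isotropic scale factors to a muscle path.

    Attachment coordinates are scaled by their owning segment's factor and
    the optimal length by the insertion segment's factor (the segment that
    dominates the path's excursion).
    """
    if scale_set is None:
        return path
    from dataclasses import replace

    fo = scale_set.factor(path.origin_segment)
    fi = scale_set.factor(path.insertion_segment)
    return replace(
        path,
        origin=path.origin * fo,
        insertion=path.insertion * fi,
        optimal_fiber_length=scale_optimal_fiber_length(path.optimal_fiber_length, fi),
    )


def estimate_muscle_forces(
    model: BodyModel,
    trial: GaitTrial,
    side: str = "right",
    scale_set: ScaleSet | None = None,
    condition: str | None = None,
    offsets: f.CycleOffsetTable | None = None,
    normalize: bool = True,
) -> dict[str, f.ForceProfile]:
    """Estimate normalized force profiles for the nine muscles of one leg.

    Parameters
    ----------
    model
        Generic body model (fixture) whose muscles are defined on the right
        leg; ``side="left"`` mirrors them.
    trial
        A gait trial carrying segment poses and foot-strike events.
    scale_set
        Optional subject scale factors for a personalized estimate.
    condition
        Cycle-offset condition (e.g. ``"ESND_X_slow"``); when None it is
        derived from the trial's speed label.  The packaged offset table is
        used unless ``offsets`` overrides it.
    normalize
        Divide each active waveform by its peak (the standard presentation);
        disable to compare raw peak heights across legs.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if condition is None:
        condition = f.SPEED_LABEL_TO_CONDITION.get(trial.speed_label)
    if offsets is None:
        offsets = f.load_cycle_offsets()

    profiles: dict[str, f.ForceProfile] = {}
    for path in model.muscles:
        muscle = scaled_muscle(path, scale_set)
        if side == "left":
            muscle = mirror_muscle(muscle)
        ratio = length_timeseries(muscle, trial)  # L/L0 on the 101-point grid
        active = f.active_force(ratio * muscle.optimal_fiber_length,
                                muscle.optimal_fiber_length,
                                muscle.architecture_index)
        passive = f.passive_force(ratio * muscle.optimal_fiber_length,
                                  muscle.optimal_fiber_length,
                                  muscle.architecture_index)
        profile = f.ForceProfile(muscle=path.name, active=np.asarray(active),
                                 passive=np.asarray(passive))
        if condition is not None:
            profile = f.apply_cycle_offset(profile, offsets.offset(path.name, condition))
        if normalize:
            profile.active = f.normalize_profile(profile.active)
        profiles[path.name] = profile
    return profiles
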