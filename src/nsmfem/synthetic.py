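"""Deterministic synthetic slow-gait trials and the packaged body model.

Real validation of the force estimator used marker-based motion capture of
elderly subjects; none of that data is redistributable.  This module stands
in for it: a versioned generic body model (pelvis, femora, tibiae, feet,
nine muscle paths) and a seeded kinematic gait simulator producing landmark
trajectories, segment poses and foot-strike events at the four studied
walking speeds.

The simulator is kinematic only: sagittal joint angles follow low-order
(3-harmonic) Fourier series, segment poses follow by forward kinematics
over the fixture skeleton, and the pelvis translates at the condition's
walking speed.  Ground contact, ground-reaction forces and axial rotations
are not modeled, so foot-ground consistency is approximate; that is
sufficient for exercising muscle-length and force computations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .architecture import architecture_index
from .geometry import MUSCLE_NAMES, MusclePath, SegmentPose

__all__ = [
    "BodyModel",
    "GaitModelParams",
    "GaitTrial",
    "SPEED_CONDITIONS",
    "DEFAULT_SEED",
    "generate_gait_trial",
    "generate_hemiplegic_trial",
    "generic_body_fixture",
    "mirror_muscle",
]

#: Walking-speed conditions: label -> (mean speed m/s, spread m/s).
SPEED_CONDITIONS = {
    "X-slow": (0.61, 0.09),
    "slow": (0.80, 0.12),
    "free": (1.17, 0.14),
    "R-fast": (1.64, 0.18),
}

#: Default stride length per condition (m); cycle duration = stride / speed.
DEFAULT_STRIDE_M = {"X-slow": 0.85, "slow": 1.00, "free": 1.22, "R-fast": 1.48}

DEFAULT_SEED = 20260326


class FixtureChecksumError(RuntimeError):
    """The packaged body-model file does not match its recorded checksum."""


@dataclass
class BodyModel:
    """The generic digital-twin geometry: segments, landmarks and muscles."""

    version: str
    segments: dict[str, dict]
    landmarks: dict[str, tuple[str, np.ndarray]]  # marker -> (segment, local pos)
    muscles: list[MusclePath]
    stretch_prone: tuple[str, ...]
    gait_fourier: dict[str, dict]

    def muscle(self, name: str) -> MusclePath:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"unknown muscle {name!r}")

    def segment_lengths(self) -> dict[str, float]:
        return {name: float(seg["length_mm"]) for name, seg in self.segments.items()}

    @property
    def marker_defs(self) -> dict[str, tuple[str, np.ndarray]]:
        return self.landmarks


@dataclass
class GaitModelParams:
    """Tunable parameters of the synthetic gait generator.

    ``asymmetry_factor`` scales the left side's joint-angle excursions
    (1 = symmetric); ``noise_mm`` adds white Gaussian noise to the landmark
    trajectories only (poses stay exact), mimicking marker jitter.
    """

    stride_m: float | None = None
    cycle_s: float | None = None
    amplitude_scale: float | None = None
    asymmetry_factor: float = 1.0
    seed: int = DEFAULT_SEED
    noise_mm: float = 0.0
    sample_rate_hz: float = 100.0
    n_cycles: int = 2

    def __post_init__(self) -> None:
        if self.cycle_s is not None and self.cycle_s <= 0:
            raise ValueError("cycle duration must be positive")
        if self.asymmetry_factor <= 0:
            raise ValueError("asymmetry factor must be positive")
        if self.noise_mm < 0:
            raise ValueError("noise amplitude must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("at least one gait cycle is required")


@dataclass
class GaitTrial:
    """A synthetic motion trial: trajectories, poses and gait events."""

    sample_rate: float
    times: np.ndarray
    landmarks: dict[str, np.ndarray]
    pose_rotations: dict[str, np.ndarray]
    pose_translations: dict[str, np.ndarray]
    joint_angles: dict[str, np.ndarray]
    foot_strikes: dict[str, np.ndarray]
    speed_label: str
    speed_mps: float
    params: GaitModelParams = field(default_factory=GaitModelParams)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        for side, ev in self.foot_strikes.items():
            if len(ev) < 2:
                raise ValueError(f"{side} side needs at least two foot-strike events")

    @property
    def events(self) -> np.ndarray:
        """Right-side foot-strike times (the default cycle reference)."""
        return self.foot_strikes["right"]

    def pose_at(self, index: int) -> dict[str, SegmentPose]:
        return {
            seg: SegmentPose(self.pose_rotations[seg][index], self.pose_translations[seg][index])
            for seg in self.pose_rotations
        }

    @property
    def mean_forward_speed_mps(self) -> float:
        disp = self.pose_translations["pelvis"][-1, 0] - self.pose_translations["pelvis"][0, 0]
        return float(disp / 1000.0 / (self.times[-1] - self.times[0]))


def _fixture_text() -> str:
    return resources.files("nsmfem.data").joinpath("body_model.json").read_text()


def generic_body_fixture() -> BodyModel:
    """Load and integrity-check the packaged generic body model.

    The model contains pelvis/femur/tibia/foot segments for both sides, the
    marker set used by the simulator, and the nine muscle paths with
    pennation angles straddling the 5-degree parallel-muscle rule.  Each
    muscle's architecture index is computed at load time from its pennation
    angle and anatomical fiber length (cm).
    """
    text = _fixture_text()
    recorded = (
        resources.files("nsmfem.data").joinpath("body_model.sha256").read_text().split()[0]
    )
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != recorded:
        raise FixtureChecksumError(
            f"body model checksum mismatch: {digest} != recorded {recorded}"
        )
    raw = json.loads(text)

    muscles = []
    for m in raw["muscles"]:
        for key in ("origin_segment", "insertion_segment"):
            if m[key] not in raw["segments"]:
                raise ValueError(f"muscle {m['name']} references unknown segment {m[key]!r}")
        muscles.append(
            MusclePath(
                name=m["name"],
                origin=np.asarray(m["origin"], dtype=float),
                origin_segment=m["origin_segment"],
                insertion=np.asarray(m["insertion"], dtype=float),
                insertion_segment=m["insertion_segment"],
                pennation_deg=float(m["pennation_deg"]),
                optimal_fiber_length=float(m["L0_generic_mm"]),
                architecture_index=architecture_index(
                    float(m["pennation_deg"]), float(m["fiber_length_cm"])
                ),
            )
        )
    names = {m.name for m in muscles}
    if names != set(MUSCLE_NAMES):
        raise ValueError(f"fixture must define exactly the nine muscles, got {sorted(names)}")

    landmarks = {
        name: (spec["segment"], np.asarray(spec["position"], dtype=float))
        for name, spec in raw["landmarks"].items()
    }
    for name, (seg, _) in landmarks.items():
        if seg not in raw["segments"]:
            raise ValueError(f"landmark {name} references unknown segment {seg!r}")

    return BodyModel(
        version=raw["version"],
        segments=raw["segments"],
        landmarks=landmarks,
        muscles=muscles,
        stretch_prone=tuple(raw["stretch_prone"]),
        gait_fourier=raw["gait_fourier"],
    )


def mirror_muscle(path: MusclePath) -> MusclePath:
    """The left-side counterpart of a right-side muscle (z negated)."""

    def flip_seg(seg: str) -> str:
        if seg.endswith("_r"):
            return seg[:-2] + "_l"
        if seg.endswith("_l"):
            return seg[:-2] + "_r"
        return seg

    flip = np.array([1.0, 1.0, -1.0])
    return replace(
        path,
        origin=path.origin * flip,
        insertion=path.insertion * flip,
        origin_segment=flip_seg(path.origin_segment),
        insertion_segment=flip_seg(path.insertion_segment),
    )


def _fourier_deg(coeffs: dict, phase: np.ndarray, amp: float) -> np.ndarray:
    """Evaluate a truncated Fourier series (degrees) at cycle phase in [0, 1)."""
    out = np.full_like(phase, float(coeffs["mean"]))
    for k, (c, s) in enumerate(zip(coeffs["cos"], coeffs["sin"]), start=1):
        out = out + amp * (
            c * np.cos(2 * np.pi * k * phase) + s * np.sin(2 * np.pi * k * phase)
        )
    return out


def _rz_row(theta_rad: np.ndarray) -> np.ndarray:
    """Stacked sagittal rotations about z in the row-vector convention."""
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    n = len(theta_rad)
    R = np.zeros((n, 3, 3))
    R[:, 0, 0] = c
    R[:, 0, 1] = s
    R[:, 1, 0] = -s
    R[:, 1, 1] = c
    R[:, 2, 2] = 1.0
    return R


def _resolve_speed(speed_label: str, params: GaitModelParams) -> tuple[float, float, float]:
    if speed_label not in SPEED_CONDITIONS:
        raise ValueError(
            f"unknown speed label {speed_label!r}; expected one of {sorted(SPEED_CONDITIONS)}"
        )
    speed = SPEED_CONDITIONS[speed_label][0]
    stride = params.stride_m if params.stride_m is not None else DEFAULT_STRIDE_M[speed_label]
    cycle = params.cycle_s if params.cycle_s is not None else stride / speed
    if params.cycle_s is not None or params.stride_m is not None:
        speed = stride / cycle
    return speed, stride, cycle


def generate_gait_trial(
    speed_label: str,
    params: GaitModelParams | None = None,
    model: BodyModel | None = None,
    phase_shift: dict[str, float] | None = None,
    side_amplitude: dict[str, float] | None = None,
) -> GaitTrial:
    """Generate one deterministic synthetic walking trial.

    Joint angles follow the fixture's 3-harmonic Fourier patterns, scaled
    slightly with walking speed; the left leg runs half a cycle out of
    phase.  Foot strikes of each side sit at that side's cycle boundaries.
    The generator is a pure function of its arguments: identical inputs
    yield bitwise-identical trials.

    ``phase_shift`` and ``side_amplitude`` are per-side overrides used by
    the hemiplegic generator; leave them unset for normal gait.
    """
    params = params or GaitModelParams()
    model = model or generic_body_fixture()
    speed, stride, cycle = _resolve_speed(speed_label, params)

    if params.amplitude_scale is not None:
        amp = params.amplitude_scale
    else:
        # Mild amplitude growth with speed across the studied band.
        amp = 0.85 + 0.25 * (speed - 0.61) / (1.64 - 0.61)

    duration = params.n_cycles * cycle
    n = int(round(duration * params.sample_rate_hz)) + 1
    times = np.linspace(0.0, duration, n)
    phase = times / cycle

    shifts = {"right": 0.0, "left": 0.5}
    if phase_shift:
        shifts.update(phase_shift)
    amps = {"right": amp, "left": amp * params.asymmetry_factor}
    if side_amplitude:
        amps = {side: amps[side] * side_amplitude.get(side, 1.0) for side in amps}

    seg = model.segments
    l_femur = seg["femur_r"]["length_mm"]
    l_tibia = seg["tibia_r"]["length_mm"]
    hip_offset = np.asarray(seg["femur_r"]["offset_in_parent"], dtype=float)
    pelvis_h = seg["pelvis"]["origin_height_mm"]

    # Pelvis: forward translation at the walking speed plus vertical bob at
    # twice the stride frequency; no pelvic rotation.
    pelvis_t = np.zeros((n, 3))
    pelvis_t[:, 0] = speed * 1000.0 * times
    pelvis_t[:, 1] = pelvis_h + 12.0 * np.sin(4 * np.pi * phase)
    pelvis_R = np.tile(np.eye(3), (n, 1, 1))

    rotations: dict[str, np.ndarray] = {"pelvis": pelvis_R}
    translations: dict[str, np.ndarray] = {"pelvis": pelvis_t}
    joint_angles: dict[str, np.ndarray] = {}
    foot_strikes: dict[str, np.ndarray] = {}

    for side, suffix, z_sign in (("right", "_r", 1.0), ("left", "_l", -1.0)):
        ph = phase + shifts[side]
        hip_deg = _fourier_deg(model.gait_fourier["hip_deg"], ph, amps[side])
        knee_deg = _fourier_deg(model.gait_fourier["knee_deg"], ph, amps[side])
        ankle_deg = _fourier_deg(model.gait_fourier["ankle_deg"], ph, amps[side])
        joint_angles[f"hip{suffix}"] = hip_deg
        joint_angles[f"knee{suffix}"] = knee_deg
        joint_angles[f"ankle{suffix}"] = ankle_deg

        th_hip = np.deg2rad(hip_deg)
        th_shank = th_hip - np.deg2rad(knee_deg)
        th_foot = th_shank + np.deg2rad(ankle_deg)

        offset = hip_offset * np.array([1.0, 1.0, z_sign])
        hip_pos = pelvis_t + offset  # pelvis rotation is identity
        R_femur = _rz_row(th_hip)
        knee_pos = hip_pos + np.einsum("j,njk->nk", np.array([0.0, -l_femur, 0.0]), R_femur)
        R_tibia = _rz_row(th_shank)
        ankle_pos = knee_pos + np.einsum("j,njk->nk", np.array([0.0, -l_tibia, 0.0]), R_tibia)
        R_foot = _rz_row(th_foot)

        rotations[f"femur{suffix}"] = R_femur
        translations[f"femur{suffix}"] = hip_pos
        rotations[f"tibia{suffix}"] = R_tibia
        translations[f"tibia{suffix}"] = knee_pos
        rotations[f"foot{suffix}"] = R_foot
        translations[f"foot{suffix}"] = ankle_pos

        # Strikes where this side's phase crosses whole cycles inside the trial.
        k0 = np.ceil(shifts[side] - 1e-9)
        strikes = (np.arange(k0, shifts[side] + params.n_cycles + 1e-9) - shifts[side]) * cycle
        foot_strikes[side] = strikes[(strikes >= -1e-9) & (strikes <= duration + 1e-9)]

    landmark_traj: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(params.seed)
    for marker, (segment, local) in model.landmarks.items():
        traj = (
            np.einsum("j,njk->nk", local, rotations[segment]) + translations[segment]
        )
        if params.noise_mm > 0:
            traj = traj + rng.normal(0.0, params.noise_mm, traj.shape)
        landmark_traj[marker] = traj

    return GaitTrial(
        sample_rate=params.sample_rate_hz,
        times=times,
        landmarks=landmark_traj,
        pose_rotations=rotations,
        pose_translations=translations,
        joint_angles=joint_angles,
        foot_strikes=foot_strikes,
        speed_label=speed_label,
        speed_mps=speed,
        params=params,
    )


def generate_hemiplegic_trial(
    params: GaitModelParams | None = None,
    affected_side: str = "right",
    weakness_factor: float = 1.0,
    speed_label: str = "free",
    model: BodyModel | None = None,
) -> GaitTrial:
    """Generate a hemiplegic-gait trial with one-sided weakness.

    The affected side's joint-angle excursions are scaled by
    ``weakness_factor`` (1 = healthy, no-op), and its foot strike is
    delayed by a small phase lag proportional to the weakness, lengthening
    the unaffected side's stance — the compensatory asymmetry typical of
    post-stroke gait.  ``weakness_factor = 1`` reproduces the symmetric
    trial exactly.
    """
    if affected_side not in ("left", "right"):
        raise ValueError(f"affected side must be 'left' or 'right', got {affected_side!r}")
    if not 0.0 < weakness_factor <= 1.0:
        raise ValueError(f"weakness factor must lie in (0, 1], got {weakness_factor}")
    params = params or GaitModelParams()
    delay = 0.06 * (1.0 - weakness_factor)
    base_shift = {"right": 0.0, "left": 0.5}
    base_shift[affected_side] -= delay
    return generate_gait_trial(
        speed_label,
        params=params,
        model=model,
        phase_shift=base_shift,
        side_amplitude={affected_side: weakness_factor},
    )
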