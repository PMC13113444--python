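"""Segment frames, homogeneous transforms and muscle-tendon geometry.

All transforms use the row-vector homogeneous convention: a point is a 1x4
row ``[x y z 1]`` multiplied by the 4x4 matrix on the right, so the rotation
occupies the upper-left 3x3 block and the translation sits in the last row.
Converters to the more common column convention are provided at the
boundary (:meth:`FrameTransform.to_column_convention`).

Muscle paths are straight lines from origin to insertion; no wrapping
surfaces or via points are modeled.  The normalized fiber length consumed by
the force model is the muscle-tendon distance divided by the optimal fiber
length (no tendon-slack or pennation projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "FrameTransform",
    "LandmarkSet",
    "MusclePath",
    "SegmentPose",
    "MUSCLE_NAMES",
    "CADAVER_PELVIC_TRANSITION",
    "build_pelvic_frames",
    "estimate_transition_matrix",
    "transform_point",
    "muscle_tendon_length",
    "length_timeseries",
    "poses_from_landmarks",
]

#: The nine representative lower-limb muscles covered by the model.
MUSCLE_NAMES = (
    "Glut_Max1",
    "TFL",
    "Iliacus",
    "Pectineus",
    "Vas_Int",
    "Med_Gas",
    "Tib_Ant",
    "Tib_Post",
    "Soleus",
)

#: Number of samples on the 0-100 % gait-cycle grid (both endpoints included).
CYCLE_GRID_POINTS = 101


class DegenerateGeometryError(ValueError):
    """Raised when landmarks are collinear/coincident and no frame exists."""


@dataclass
class FrameTransform:
    """A rigid 4x4 homogeneous transform in the row-vector convention.

    ``apply(p)`` computes ``[p 1] @ matrix`` and returns the Cartesian part.
    """

    matrix: np.ndarray
    source: str = "anatomical"
    target: str = "kinematic"
    rotation_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {self.matrix.shape}")
        if not np.allclose(self.matrix[:, 3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last column must be (0, 0, 0, 1) in the row-vector convention")
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=self.rotation_tol * 10):
            raise ValueError("rotation block is not orthonormal within tolerance")
        if abs(np.linalg.det(R) - 1.0) > self.rotation_tol * 10:
            raise ValueError("rotation block must have determinant +1")

    @classmethod
    def identity(cls, source: str = "a", target: str = "b") -> "FrameTransform":
        return cls(np.eye(4), source=source, target=target)

    @classmethod
    def from_rotation_translation(
        cls,
        rotation_rows: np.ndarray,
        translation: np.ndarray,
        source: str = "a",
        target: str = "b",
        rotation_tol: float = 1e-6,
    ) -> "FrameTransform":
        """Assemble from a row-convention 3x3 rotation and a translation."""
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation_rows, dtype=float)
        m[3, :3] = np.asarray(translation, dtype=float)
        return cls(m, source=source, target=target, rotation_tol=rotation_tol)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[3, :3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack (n, 3) through the transform."""
        pts = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation + self.translation
        return out[0] if single else out

    def inverse(self) -> "FrameTransform":
        R_inv = self.rotation.T
        t_inv = -self.translation @ R_inv
        return FrameTransform.from_rotation_translation(
            R_inv, t_inv, source=self.target, target=self.source,
            rotation_tol=self.rotation_tol,
        )

    def compose(self, other: "FrameTransform") -> "FrameTransform":
        """The transform 'self then other' (row convention: p @ A @ B)."""
        return FrameTransform(
            self.matrix @ other.matrix,
            source=self.source,
            target=other.target,
            rotation_tol=max(self.rotation_tol, other.rotation_tol),
        )

    def to_column_convention(self) -> np.ndarray:
        """The equivalent column-convention matrix (point as column on the right)."""
        return self.matrix.T


#: Pelvic anatomical-to-kinematic transition matrix reported from cadaveric
#: calibration data (row-vector convention; translation in meters in the
#: source).  The rotation block is orthonormal only to transcription
#: precision (~1e-3), hence the relaxed tolerance.
CADAVER_PELVIC_TRANSITION = FrameTransform(
    np.array(
        [
            [0.9133, -0.4072, 0.0, 0.0],
            [0.4072, 0.9133, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-0.0646, -0.0526, 0.0, 1.0],
        ]
    ),
    source="pelvis_anatomical",
    target="pelvis_kinematic",
    rotation_tol=1e-3,
)


@dataclass
class LandmarkSet:
    """Named 3-D points in a common frame (units follow the body model, mm)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for name, p in self.points.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(f"missing landmarks: {missing}")


@dataclass
class MusclePath:
    """A muscle's straight-line path plus its architecture parameters.

    Attachment coordinates live in the owning segment's kinematic frame.
    ``architecture_index`` (Ia) is 1 for parallel-fibered muscles and drops
    towards ~0.2 for strongly pennate ones.
    """

    name: str
    origin: np.ndarray
    origin_segment: str
    insertion: np.ndarray
    insertion_segment: str
    pennation_deg: float
    optimal_fiber_length: float
    architecture_index: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        if self.pennation_deg < 0:
            raise ValueError("pennation angle must be non-negative")
        if self.optimal_fiber_length <= 0:
            raise ValueError("optimal fiber length must be positive")
        if not 0.0 < self.architecture_index <= 1.0:
            raise ValueError("architecture index must lie in (0, 1]")


@dataclass
class SegmentPose:
    """Rigid pose of a segment's kinematic frame in the lab frame."""

    rotation: np.ndarray  # 3x3, row convention (local row-vector @ rotation)
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("pose rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("pose rotation must have determinant +1")

    def to_lab(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError(f"degenerate geometry while building {context}")
    return v / norm


def build_pelvic_frames(landmarks: LandmarkSet) -> tuple[FrameTransform, FrameTransform]:
    """Build the pelvic anatomical and kinematic frames from bony landmarks.

    Landmarks (lab frame): ``P1a`` right anterior superior iliac spine (ASIS),
    ``P2a`` midpoint of the superior margin of the pubic symphysis, ``P4a``
    left ASIS; ``P3a`` (mid-ASIS point) is derived as the P1a-P4a midpoint
    when absent.

    Anatomical frame: origin P2a, y up along P2a->P3a, x anterior
    (perpendicular to the frontal plane), z to the right completing the
    right-handed triad.  Kinematic frame: origin P3a, z along P4a->P1a,
    x anterior, y superior.  Both are returned as local->lab transforms.
    """
    landmarks.require("P1a", "P2a", "P4a")
    p1, p2, p4 = landmarks["P1a"], landmarks["P2a"], landmarks["P4a"]
    p3 = landmarks.points.get("P3a", 0.5 * (p1 + p4))
    if "P3a" in landmarks.points and not np.allclose(p3, 0.5 * (p1 + p4), atol=1e-3 * max(1.0, np.linalg.norm(p1 - p4))):
        raise ValueError("P3a must be the midpoint of the ASIS line P1a-P4a")

    # Anatomical frame at the pubic symphysis.
    y_a = _unit(p3 - p2, "pelvic anatomical y axis")
    z_hint = p1 - p4  # right-pointing ASIS line
    x_a = _unit(np.cross(y_a, z_hint), "pelvic anatomical x axis")
    z_a = np.cross(x_a, y_a)
    anatomical = FrameTransform.from_rotation_translation(
        np.vstack([x_a, y_a, z_a]), p2, source="pelvis_anatomical", target="lab"
    )

    # Kinematic frame at the mid-ASIS point.
    z_k = _unit(p1 - p4, "pelvic kinematic z axis")
    x_k = _unit(np.cross(p3 - p2, z_k), "pelvic kinematic x axis")
    y_k = np.cross(z_k, x_k)
    kinematic = FrameTransform.from_rotation_translation(
        np.vstack([x_k, y_k, z_k]), p3, source="pelvis_kinematic", target="lab"
    )
    return anatomical, kinematic


def estimate_transition_matrix(
    points_source: np.ndarray,
    points_target: np.ndarray,
    source: str = "anatomical",
    target: str = "kinematic",
) -> FrameTransform:
    """Least-squares rigid transform mapping paired points source -> target.

    Closed-form orthogonal Procrustes fit (rotation + translation, no
    scaling) minimizing the summed squared residuals under the row-vector
    convention.  The RMS residual is stored on the returned transform as
    ``residual_rms``.
    """
    a = np.asarray(points_source, dtype=float)
    b = np.asarray(points_target, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("at least 3 paired points are required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # Collinearity check: the two smallest singular values vanish together.
    if np.linalg.matrix_rank(a0, tol=1e-8 * max(1.0, np.abs(a0).max())) < 2:
        raise DegenerateGeometryError("point set is collinear; rotation is not identifiable")
    rot, _ = Rotation.align_vectors(b0, a0)  # column convention: b ~ R @ a
    R_row = rot.as_matrix().T
    t = cb - ca @ R_row
    fit = FrameTransform.from_rotation_translation(R_row, t, source=source, target=target)
    residuals = a @ R_row + t - b
    fit.residual_rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return fit


def transform_point(point: np.ndarray, transform: FrameTransform) -> np.ndarray:
    """Map a 3-D point through a homogeneous transform (row-vector product)."""
    return transform.apply(point)


def muscle_tendon_length(path: MusclePath, pose_by_segment: dict[str, SegmentPose]) -> float:
    """Straight-line origin-to-insertion distance in the lab frame."""
    for seg in (path.origin_segment, path.insertion_segment):
        if seg not in pose_by_segment:
            raise KeyError(f"no pose for segment {seg!r} required by muscle {path.name}")
    o = pose_by_segment[path.origin_segment].to_lab(path.origin)
    i = pose_by_segment[path.insertion_segment].to_lab(path.insertion)
    return float(np.linalg.norm(i - o))


def muscle_length_series(
    path: MusclePath,
    rotations: dict[str, np.ndarray],
    translations: dict[str, np.ndarray],
) -> np.ndarray:
    """Vectorized muscle-tendon length over stacked poses (n, 3, 3)/(n, 3)."""
    for seg in (path.origin_segment, path.insertion_segment):
        if seg not in rotations or seg not in translations:
            raise KeyError(f"no pose series for segment {seg!r} required by muscle {path.name}")
    o = np.einsum(
        "j,njk->nk", path.origin, rotations[path.origin_segment]
    ) + translations[path.origin_segment]
    i = np.einsum(
        "j,njk->nk", path.insertion, rotations[path.insertion_segment]
    ) + translations[path.insertion_segment]
    return np.linalg.norm(i - o, axis=1)


def length_timeseries(path: MusclePath, trial, l0: float | None = None) -> np.ndarray:
    """Normalized fiber length L/L0 on the 101-point gait-cycle grid.

    The muscle-tendon length is evaluated at every trial sample, resampled
    to the 0-100 % cycle grid between the foot strikes of the side the
    muscle attaches to, and divided by the optimal fiber length.
    """
    from .validation import resample_to_cycle

    if l0 is None:
        l0 = path.optimal_fiber_length
    if l0 <= 0:
        raise ValueError("optimal fiber length must be positive")
    lengths = muscle_length_series(path, trial.pose_rotations, trial.pose_translations)
    side = "left" if path.insertion_segment.endswith("_l") else "right"
    events = trial.foot_strikes[side]
    series = resample_to_cycle(trial.times, lengths, events)
    return series / l0


def poses_from_landmarks(
    landmark_traj: dict[str, np.ndarray],
    marker_defs: dict[str, tuple[str, np.ndarray]],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Recover per-segment pose series from landmark trajectories.

    ``marker_defs`` maps marker name -> (segment, local position).  Each
    segment needs at least two markers; segments with exactly two are
    augmented with an out-of-sagittal-plane virtual pair, which assumes the
    motion has no axial rotation (adequate for the sagittal-dominant gait
    this package emulates and generates).

    Returns stacked row-convention rotations (n, 3, 3) and translations
    (n, 3) per segment.
    """
    by_segment: dict[str, list[tuple[str, np.ndarray]]] = {}
    for marker, (segment, local) in marker_defs.items():
        if marker in landmark_traj:
            by_segment.setdefault(segment, []).append((marker, np.asarray(local, dtype=float)))

    n = next(iter(landmark_traj.values())).shape[0]
    rotations: dict[str, np.ndarray] = {}
    translations: dict[str, np.ndarray] = {}
    z_off = np.array([0.0, 0.0, 50.0])
    for segment, markers in by_segment.items():
        if len(markers) < 2:
            raise ValueError(f"segment {segment!r} needs at least two markers for pose recovery")
        local = np.array([loc for _, loc in markers])
        R_seg = np.empty((n, 3, 3))
        t_seg = np.empty((n, 3))
        for k in range(n):
            lab = np.array([landmark_traj[name][k] for name, _ in markers])
            loc, labp = local, lab
            if len(markers) == 2 or np.linalg.matrix_rank(local - local.mean(axis=0), tol=1e-6) < 2:
                loc = np.vstack([local, local + z_off])
                labp = np.vstack([lab, lab + z_off])
            fit = estimate_transition_matrix(loc, labp, source=segment, target="lab")
            R_seg[k] = fit.rotation
            t_seg[k] = fit.translation
        rotations[segment] = R_seg
        translations[segment] = t_seg
    return rotations, translations
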