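"""Frames, homogeneous transforms, rigid fitting and muscle-tendon lengths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsmfem.geometry import (
    CADAVER_PELVIC_TRANSITION,
    DegenerateGeometryError,
    FrameTransform,
    LandmarkSet,
    MusclePath,
    SegmentPose,
    build_pelvic_frames,
    estimate_transition_matrix,
    muscle_tendon_length,
    length_timeseries,
    poses_from_landmarks,
    transform_point,
)


def random_rigid(rng) -> FrameTransform:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix().T
    t = rng.normal(scale=100.0, size=3)
    return FrameTransform.from_rotation_translation(R, t)


def make_path(**kw):
    defaults = dict(
        name="TFL",
        origin=[0.0, 0.0, 0.0],
        origin_segment="A",
        insertion=[3.0, 4.0, 0.0],
        insertion_segment="B",
        pennation_deg=3.0,
        optimal_fiber_length=100.0,
    )
    defaults.update(kw)
    return MusclePath(**defaults)


class TestFrameTransform:
    def test_identity_maps_points_to_themselves(self):
        p = np.array([1.0, -2.0, 3.0])
        assert np.allclose(transform_point(p, FrameTransform.identity()), p)

    def test_round_trip_through_inverse(self):
        rng = np.random.default_rng(7)
        T = random_rigid(rng)
        p = rng.normal(size=3)
        assert np.allclose(T.inverse().apply(T.apply(p)), p, atol=1e-9)

    def test_composition_equals_sequential_application(self):
        rng = np.random.default_rng(8)
        A, B = random_rigid(rng), random_rigid(rng)
        p = rng.normal(size=3)
        assert np.allclose(
            A.compose(B).apply(p), B.apply(A.apply(p)), atol=1e-12 * 1e3
        )

    def test_column_convention_converter(self):
        rng = np.random.default_rng(9)
        T = random_rigid(rng)
        p = rng.normal(size=3)
        col = T.to_column_convention() @ np.append(p, 1.0)
        assert np.allclose(col[:3], T.apply(p))

    def test_bad_last_column_rejected(self):
        m = np.eye(4)
        m[0, 3] = 0.5
        with pytest.raises(ValueError, match="last column"):
            FrameTransform(m)

    def test_reflection_rejected(self):
        m = np.diag([1.0, 1.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="determinant"):
            FrameTransform(m)


class TestPelvicFrames:
    def test_lab_aligned_landmarks_give_identity_frames(self):
        landmarks = LandmarkSet(
            {
                "P1a": [0.0, 0.0, 120.0],
                "P4a": [0.0, 0.0, -120.0],
                "P2a": [0.0, -80.0, 0.0],
            }
        )
        anatomical, kinematic = build_pelvic_frames(landmarks)
        assert np.allclose(anatomical.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(kinematic.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(anatomical.translation, [0.0, -80.0, 0.0])
        assert np.allclose(kinematic.translation, [0.0, 0.0, 0.0])

    def test_axes_match_explicit_cross_products(self):
        p1 = np.array([10.0, 5.0, 118.0])
        p4 = np.array([-12.0, 2.0, -122.0])
        p2 = np.array([25.0, -80.0, 3.0])
        anatomical, kinematic = build_pelvic_frames(
            LandmarkSet({"P1a": p1, "P4a": p4, "P2a": p2})
        )
        p3 = 0.5 * (p1 + p4)
        y = (p3 - p2) / np.linalg.norm(p3 - p2)
        x = np.cross(y, p1 - p4)
        x /= np.linalg.norm(x)
        z = np.cross(x, y)
        assert np.allclose(anatomical.rotation, np.vstack([x, y, z]), atol=1e-12)
        zk = (p1 - p4) / np.linalg.norm(p1 - p4)
        assert np.allclose(kinematic.rotation[2], zk, atol=1e-12)

    def test_rotation_blocks_are_orthonormal(self):
        rng = np.random.default_rng(11)
        pts = {"P1a": rng.normal(size=3) + [0, 0, 120],
               "P4a": rng.normal(size=3) - [0, 0, 120],
               "P2a": rng.normal(size=3) - [0, 80, 0]}
        for frame in build_pelvic_frames(LandmarkSet(pts)):
            R = frame.rotation
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_landmarks_raise_degenerate_error(self):
        with pytest.raises(DegenerateGeometryError):
            build_pelvic_frames(
                LandmarkSet(
                    {"P1a": [1.0, 0, 0], "P4a": [-1.0, 0, 0], "P2a": [0.0, 0, 0]}
                )
            )

    def test_misplaced_midpoint_rejected(self):
        with pytest.raises(ValueError, match="midpoint"):
            build_pelvic_frames(
                LandmarkSet(
                    {
                        "P1a": [0.0, 0.0, 120.0],
                        "P4a": [0.0, 0.0, -120.0],
                        "P3a": [50.0, 0.0, 0.0],
                        "P2a": [0.0, -80.0, 0.0],
                    }
                )
            )


class TestTransitionMatrix:
    def test_identical_point_sets_give_identity(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [0, 100.0, 0], [0, 0, 100.0]])
        fit = estimate_transition_matrix(pts, pts)
        assert np.allclose(fit.matrix, np.eye(4), atol=1e-12)
        assert fit.residual_rms < 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=3, max_value=12))
    def test_recovers_planted_rigid_transform(self, seed, n_points):
        rng = np.random.default_rng(seed)
        T = random_rigid(rng)
        src = rng.normal(scale=100.0, size=(n_points, 3))
        fit = estimate_transition_matrix(src, T.apply(src))
        assert np.abs(fit.matrix - T.matrix).max() < 1e-9
        assert fit.residual_rms < 1e-9

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            estimate_transition_matrix(src, src)

    def test_too_few_points_rejected(self):
        src = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError, match="3"):
            estimate_transition_matrix(src, src)


class TestPrintedPelvicMatrix:
    def test_rotation_block_normalized_to_transcription_precision(self):
        assert 0.9133**2 + 0.4072**2 == pytest.approx(1.0, abs=1e-3)
        R = CADAVER_PELVIC_TRANSITION.rotation
        assert np.linalg.det(R) == pytest.approx(1.0, abs=2e-3)

    def test_origin_maps_to_printed_translation(self):
        mapped = transform_point(np.zeros(3), CADAVER_PELVIC_TRANSITION)
        assert np.allclose(mapped, [-0.0646, -0.0526, 0.0], atol=1e-12)


class TestMuscleTendonLength:
    def test_three_four_five(self):
        poses = {"A": SegmentPose(np.eye(3), np.zeros(3)),
                 "B": SegmentPose(np.eye(3), np.zeros(3))}
        assert muscle_tendon_length(make_path(), poses) == pytest.approx(5.0)

    def test_homogeneity_under_uniform_scaling(self):
        rng = np.random.default_rng(3)
        t_a, t_b = rng.normal(size=3), rng.normal(size=3)
        s = 2.5
        path = make_path(origin=rng.normal(size=3), insertion=rng.normal(size=3))
        base = muscle_tendon_length(
            path, {"A": SegmentPose(np.eye(3), t_a), "B": SegmentPose(np.eye(3), t_b)}
        )
        from dataclasses import replace

        scaled_path = replace(path, origin=s * path.origin, insertion=s * path.insertion)
        scaled = muscle_tendon_length(
            scaled_path,
            {"A": SegmentPose(np.eye(3), s * t_a), "B": SegmentPose(np.eye(3), s * t_b)},
        )
        assert scaled == pytest.approx(s * base, rel=1e-12)

    def test_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(4)
        T = random_rigid(rng)
        path = make_path(origin=rng.normal(size=3), insertion=rng.normal(size=3))
        pose_a = SegmentPose(np.eye(3), rng.normal(size=3))
        pose_b = SegmentPose(np.eye(3), rng.normal(size=3))
        moved = {
            name: SegmentPose(pose.rotation @ T.rotation, pose.translation @ T.rotation + T.translation)
            for name, pose in {"A": pose_a, "B": pose_b}.items()
        }
        assert muscle_tendon_length(path, moved) == pytest.approx(
            muscle_tendon_length(path, {"A": pose_a, "B": pose_b}), rel=1e-12
        )

    def test_missing_pose_errors(self):
        with pytest.raises(KeyError, match="B"):
            muscle_tendon_length(make_path(), {"A": SegmentPose(np.eye(3), np.zeros(3))})


class TestLengthTimeseries:
    def test_grid_has_101_samples(self, body_model, xslow_trial):
        series = length_timeseries(body_model.muscle("Soleus"), xslow_trial)
        assert series.shape == (101,)
        assert np.all(series > 0)

    def test_stretch_prone_muscles_exceed_optimum(self, body_model, xslow_trial):
        over = [
            length_timeseries(body_model.muscle(name), xslow_trial).max() > 1.0
            for name in body_model.stretch_prone
        ]
        assert any(over)

    def test_static_trial_gives_constant_series(self, body_model, xslow_trial):
        from dataclasses import replace

        frozen_R = {s: np.repeat(R[:1], len(xslow_trial.times), axis=0)
                    for s, R in xslow_trial.pose_rotations.items()}
        frozen_t = {s: np.repeat(t[:1], len(xslow_trial.times), axis=0)
                    for s, t in xslow_trial.pose_translations.items()}
        static = replace(xslow_trial, pose_rotations=frozen_R, pose_translations=frozen_t)
        series = length_timeseries(body_model.muscle("Iliacus"), static)
        assert np.ptp(series) < 1e-12

    def test_nonpositive_l0_errors(self, body_model, xslow_trial):
        with pytest.raises(ValueError, match="positive"):
            length_timeseries(body_model.muscle("Soleus"), xslow_trial, l0=0.0)


class TestPoseRecovery:
    def test_recovers_simulated_poses_from_landmarks(self, body_model, xslow_trial):
        rotations, translations = poses_from_landmarks(
            xslow_trial.landmarks, body_model.marker_defs
        )
        for seg in rotations:
            assert np.allclose(rotations[seg], xslow_trial.pose_rotations[seg], atol=1e-6)
            assert np.allclose(
                translations[seg], xslow_trial.pose_translations[seg], atol=1e-6
            )
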