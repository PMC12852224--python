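"""The intervertebral joint: construction, splits, forward/inverse
kinematics, single-axis motions and the pose-shift case metrics."""

import numpy as np
import pytest

from fsukin.geometry import (
    AntipodalRotationError,
    RigidTransform,
    euler_zyx_rotation,
    geodesic_distance,
)
from fsukin.joint import (
    FsuReference,
    JointCoordinates,
    ParentMode,
    apply_single_axis_motion,
    build_joint,
    case_vertebra_shift,
    extract_coordinates,
    forward_pose,
    joint_transform,
    shift_reference,
)
from fsukin.synthetic import FsuGeneratorParams, ShiftSpec, apply_synthetic_shift, generate_fsu



def max_abs_diff(a: RigidTransform, b: RigidTransform) -> float:
    return float(np.abs(a.as_matrix() - b.as_matrix()).max())


class TestBuildJoint:
    def test_single_parent_copies_caudal_axes(self, skewed_fsu):
        jd = build_joint(skewed_fsu.reference, ParentMode("single"))
        np.testing.assert_array_equal(
            jd.frame_A.orientation, skewed_fsu.reference.caudal.orientation
        )
        np.testing.assert_array_equal(jd.split_A_V1.rotation, np.eye(3))

    def test_double_parent_halves_the_relative_rotation(self):
        fsu = generate_fsu(FsuGeneratorParams(cranial_skew_deg=(40.0, 0.0, 0.0)))
        jd = build_joint(fsu.reference, ParentMode("double"))
        r_v1_a = fsu.reference.caudal.orientation.T @ jd.frame_A.orientation
        np.testing.assert_allclose(r_v1_a, euler_zyx_rotation(20.0, 0, 0), atol=1e-9)
        # the halved offset squared reproduces the full relative rotation
        rel = fsu.reference.caudal.orientation.T @ fsu.reference.cranial.orientation
        np.testing.assert_allclose(r_v1_a @ r_v1_a, rel, atol=1e-9)

    def test_double_parent_identity_reference_coincides_with_single(self, symmetric_fsu):
        js = build_joint(symmetric_fsu.reference, ParentMode("single"))
        jdbl = build_joint(symmetric_fsu.reference, ParentMode("double"))
        assert max_abs_diff(js.split_A_V1, jdbl.split_A_V1) < 1e-12
        assert max_abs_diff(js.split_V2_A, jdbl.split_V2_A) < 1e-12

    def test_double_parent_ratio_zero_reproduces_single(self, skewed_fsu):
        js = build_joint(skewed_fsu.reference, ParentMode("single"))
        j0 = build_joint(skewed_fsu.reference, ParentMode("double", ratio=0.0))
        assert max_abs_diff(js.split_A_V1, j0.split_A_V1) < 1e-12

    @pytest.mark.parametrize("mode", ["single", "double"])
    def test_split_consistency(self, shifted_fsu, mode):
        fsu, relative_io, _ = shifted_fsu
        for ref in (fsu.reference, shift_reference(fsu.reference, relative_io)):
            jd = build_joint(ref, ParentMode(mode))
            assert max_abs_diff(jd.reference_pose, ref.relative) < 1e-9

    def test_origin_between_bounding_endplates(self, skewed_fsu):
        ref = skewed_fsu.reference
        jd = build_joint(ref, ParentMode("single"))
        expected = 0.5 * (ref.caudal_landmarks.p1 + ref.cranial_landmarks.p2)
        np.testing.assert_allclose(jd.frame_A.origin, expected, atol=1e-12)
        outer = build_joint(ref, ParentMode("single"), origin_convention="outer")
        expected_outer = 0.5 * (ref.caudal_landmarks.p2 + ref.cranial_landmarks.p1)
        np.testing.assert_allclose(outer.frame_A.origin, expected_outer, atol=1e-12)

    def test_double_parent_half_turn_reference_raises(self, symmetric_fsu):
        ref = symmetric_fsu.reference
        flip = RigidTransform(
            euler_zyx_rotation(0.0, 0.0, 180.0), np.zeros(3)
        )
        pivot = ref.cranial.origin
        world = RigidTransform(flip.rotation, pivot - flip.rotation @ pivot)
        cranial_lm = ref.cranial_landmarks.transformed(world)
        flipped = FsuReference.from_landmarks(ref.caudal_landmarks, cranial_lm)
        with pytest.raises(AntipodalRotationError):
            build_joint(flipped, ParentMode("double"))


class TestJointTransform:
    def test_zero_coordinates_give_identity(self):
        t = joint_transform(JointCoordinates())
        np.testing.assert_array_equal(t.rotation, np.eye(3))
        np.testing.assert_array_equal(t.translation, np.zeros(3))

    def test_pure_translation(self):
        t = joint_transform(JointCoordinates(x=1, y=2, z=3))
        np.testing.assert_array_equal(t.translation, [1, 2, 3])
        np.testing.assert_array_equal(t.rotation, np.eye(3))

    def test_rotation_block_follows_euler_zyx(self):
        t = joint_transform(JointCoordinates(alpha=90, gamma=90))
        np.testing.assert_allclose(
            t.rotation, [[0, 0, 1], [1, 0, 0], [0, 1, 0]], atol=1e-12
        )
        np.testing.assert_array_equal(t.translation, np.zeros(3))


class TestForwardInverse:
    @pytest.mark.parametrize("mode", ["single", "double"])
    def test_zero_theta_reproduces_reference(self, skewed_fsu, mode):
        jd = build_joint(skewed_fsu.reference, ParentMode(mode))
        assert max_abs_diff(forward_pose(jd, JointCoordinates()), jd.reference_pose) < 1e-12

    def test_round_trip_random_coordinates(self, skewed_fsu, rng):
        for mode in ("single", "double"):
            jd = build_joint(skewed_fsu.reference, ParentMode(mode))
            for _ in range(200):
                theta = JointCoordinates(
                    *rng.uniform(-3.0, 3.0, size=3), *rng.uniform(-20.0, 20.0, size=3)
                )
                recovered = extract_coordinates(jd, forward_pose(jd, theta))
                np.testing.assert_allclose(
                    recovered.as_array(), theta.as_array(), atol=1e-9
                )
                assert not recovered.gimbal_degenerate

    def test_reference_pose_extracts_to_zero(self, skewed_fsu):
        jd = build_joint(skewed_fsu.reference, ParentMode("single"))
        theta = extract_coordinates(jd, skewed_fsu.reference.relative)
        np.testing.assert_allclose(theta.as_array(), 0.0, atol=1e-9)

    def test_io_pose_under_po_joint_reproduces_relative_rotation_change(self, shifted_fsu):
        fsu, relative_io, truth = shifted_fsu
        jd = build_joint(fsu.reference, ParentMode("single"))
        theta = extract_coordinates(jd, relative_io)
        assert np.abs(theta.as_array()).max() > 0.1
        inner = joint_transform(theta)
        assert geodesic_distance(
            inner.rotation @ np.eye(3), np.eye(3)
        ) == pytest.approx(truth.rotation_deg, abs=1e-9)

    def test_gimbal_pose_is_flagged_and_still_consistent(self, skewed_fsu):
        jd = build_joint(skewed_fsu.reference, ParentMode("single"))
        target = forward_pose(jd, JointCoordinates(alpha=30.0, beta=90.0, gamma=10.0))
        recovered = extract_coordinates(jd, target)
        assert recovered.gimbal_degenerate
        assert recovered.gamma == 0.0
        assert max_abs_diff(forward_pose(jd, recovered), target) < 1e-9


class TestSingleAxisMotion:
    def test_zero_magnitude_is_identity(self, shifted_fsu):
        fsu, relative_io, _ = shifted_fsu
        jd = build_joint(fsu.reference, ParentMode("single"))
        for convention in ("increment", "parameter"):
            out = apply_single_axis_motion(jd, relative_io, "x", 0.0, convention=convention)
            assert max_abs_diff(out, relative_io) < 1e-9

    def test_unknown_axis_rejected(self, skewed_fsu):
        jd = build_joint(skewed_fsu.reference, ParentMode("single"))
        with pytest.raises(ValueError, match="unknown joint axis"):
            apply_single_axis_motion(jd, jd.reference_pose, "pitch", 1.0)

    @pytest.mark.parametrize("convention", ["increment", "parameter"])
    @pytest.mark.parametrize("axis, magnitude", [("y", 2.0), ("beta", 12.0)])
    def test_reduces_to_forward_pose_at_reference_equilibrium(
        self, skewed_fsu, convention, axis, magnitude
    ):
        jd = build_joint(skewed_fsu.reference, ParentMode("single"))
        out = apply_single_axis_motion(
            jd, jd.reference_pose, axis, magnitude, convention=convention
        )
        expected = forward_pose(jd, JointCoordinates().incremented(axis, magnitude))
        assert max_abs_diff(out, expected) < 1e-9

    def test_translation_moves_along_joint_axis(self, skewed_fsu):
        # brute-force oracle: +2 mm along y must displace the cranial vertebra
        # by 2 mm along the joint frame's cephalad axis, with V1 fixed
        ref = skewed_fsu.reference
        jd = build_joint(ref, ParentMode("single"))
        out = apply_single_axis_motion(jd, jd.reference_pose, "y", 2.0)
        t1 = ref.caudal.as_transform()
        before = (t1 @ jd.reference_pose.inverse()).translation
        after = (t1 @ out.inverse()).translation
        np.testing.assert_allclose(after - before, 2.0 * jd.frame_A.e_y, atol=1e-9)

    def test_single_parent_translations_identical_po_vs_io(self, shifted_fsu):
        fsu, relative_io, _ = shifted_fsu
        io_ref = shift_reference(fsu.reference, relative_io)
        jp = build_joint(fsu.reference, ParentMode("single"))
        ji = build_joint(io_ref, ParentMode("single"))
        for axis in ("x", "y", "z"):
            for mag in (-3.0, -1.0, 2.0):
                a = apply_single_axis_motion(jp, relative_io, axis, mag)
                b = apply_single_axis_motion(ji, relative_io, axis, mag)
                assert max_abs_diff(a, b) == 0.0

    def test_single_parent_bendings_lever_arm_law(self, shifted_fsu):
        # closed form: pure rotations by the same angle about parallel axes
        # through offset origins differ by a translation 2 sin(delta/2) d_perp
        fsu, relative_io, _ = shifted_fsu
        io_ref = shift_reference(fsu.reference, relative_io)
        jp = build_joint(fsu.reference, ParentMode("single"))
        ji = build_joint(io_ref, ParentMode("single"))
        t1_inv = fsu.reference.caudal.as_transform().inverse()
        d = t1_inv.apply(ji.frame_A.origin) - t1_inv.apply(jp.frame_A.origin)
        for axis, unit in (("alpha", [1, 0, 0]), ("beta", [0, 1, 0]), ("gamma", [0, 0, 1])):
            for delta in (-15.0, 5.0, 10.0):
                a = apply_single_axis_motion(jp, relative_io, axis, delta)
                b = apply_single_axis_motion(ji, relative_io, axis, delta)
                assert geodesic_distance(a.rotation, b.rotation) < 1e-6
                unit = np.asarray(unit, dtype=float)
                d_perp = d - (d @ unit) * unit
                expected = 2.0 * np.sin(np.radians(abs(delta) / 2.0)) * np.linalg.norm(d_perp)
                measured = np.linalg.norm(a.inverse().translation - b.inverse().translation)
                assert measured == pytest.approx(expected, abs=1e-9)


class TestCaseVertebraShift:
    def test_reference_pose_gives_zero(self, skewed_fsu):
        d = case_vertebra_shift(skewed_fsu.reference, skewed_fsu.reference.relative)
        assert d.delta_r_mm == pytest.approx(0.0, abs=1e-12)
        assert d.delta_R_deg == pytest.approx(0.0, abs=1e-6)

    def test_pure_translation_shift(self, symmetric_fsu):
        ref = symmetric_fsu.reference
        shifted = RigidTransform(
            ref.relative.rotation, ref.relative.translation + np.array([3.0, 0.0, 0.0])
        )
        d = case_vertebra_shift(ref, shifted)
        assert d.delta_r_mm == pytest.approx(3.0, abs=1e-12)
        assert d.delta_R_deg == pytest.approx(0.0, abs=1e-9)

    def test_generator_ground_truth_recovery(self, skewed_fsu):
        relative_io, truth = apply_synthetic_shift(
            skewed_fsu.reference, ShiftSpec(translation_mm=3.0, rotation_deg=15.0, seed=4)
        )
        d = case_vertebra_shift(skewed_fsu.reference, relative_io)
        assert d.delta_r_mm == pytest.approx(3.0, abs=1e-9)
        assert d.delta_R_deg == pytest.approx(15.0, abs=1e-9)


class TestShiftReference:
    def test_caudal_side_untouched_and_relative_realised(self, shifted_fsu):
        fsu, relative_io, _ = shifted_fsu
        io_ref = shift_reference(fsu.reference, relative_io)
        assert io_ref.ref_tag == "IO"
        np.testing.assert_array_equal(io_ref.caudal.origin, fsu.reference.caudal.origin)
        assert max_abs_diff(io_ref.relative, relative_io) < 1e-9

    def test_single_parent_joints_share_axis_directions(self, shifted_fsu):
        fsu, relative_io, _ = shifted_fsu
        io_ref = shift_reference(fsu.reference, relative_io)
        jp = build_joint(fsu.reference, ParentMode("single"))
        ji = build_joint(io_ref, ParentMode("single"))
        np.testing.assert_array_equal(jp.frame_A.orientation, ji.frame_A.orientation)
        assert np.linalg.norm(jp.frame_A.origin - ji.frame_A.origin) > 0.5
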