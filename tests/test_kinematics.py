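"""Quaternion/Euler joint-angle derivation and convention corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mocapcompare as mc
from mocapcompare import kinematics as kin
from mocapcompare.errors import (
    ConfigurationError,
    ConventionError,
    EmptySeriesError,
    InvalidOrientationError,
    StreamMismatchError,
)

from conftest import constant_series, random_unit_quats

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


class TestRelativeOrientation:
    def test_self_relative_is_identity(self, rng):
        q = random_unit_quats(rng, 10)
        rel = kin.relative_orientation(q, q)
        assert kin.quat_allclose(rel, np.tile(IDENTITY, (10, 1)), atol=1e-12)

    def test_identity_parent_returns_child(self, rng):
        q = random_unit_quats(rng, 5)
        rel = kin.relative_orientation(np.tile(IDENTITY, (5, 1)), q)
        assert kin.quat_allclose(rel, q, atol=1e-12)

    def test_round_trip_random_pairs(self, rng):
        """compose(parent, rel) must reproduce the child, up to sign."""
        qp = random_unit_quats(rng, 1000)
        qc = random_unit_quats(rng, 1000)
        rel = kin.relative_orientation(qp, qc)
        recomposed = kin.from_rotation(kin.as_rotation(qp) * kin.as_rotation(rel))
        assert kin.quat_allclose(recomposed, qc, atol=1e-9)

    def test_non_unit_input_rejected(self):
        with pytest.raises(InvalidOrientationError):
            kin.relative_orientation([2.0, 0, 0, 0], IDENTITY)


class TestEulerDecomposition:
    @pytest.mark.parametrize("order", kin.EULER_ORDERS)
    def test_identity_gives_zero_angles(self, order):
        angles, flag = kin.decompose_euler(IDENTITY, order)
        np.testing.assert_allclose(angles, 0.0, atol=1e-12)
        assert not flag

    @pytest.mark.parametrize("order", kin.EULER_ORDERS)
    def test_pure_first_axis_rotation(self, order):
        q = kin.compose_euler([30.0, 0.0, 0.0], order)
        angles, _ = kin.decompose_euler(q, order)
        np.testing.assert_allclose(angles, [30.0, 0.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("order", kin.EULER_ORDERS)
    def test_round_trip_random(self, rng, order):
        q = random_unit_quats(rng, 1000)
        angles, _ = kin.decompose_euler(q, order)
        assert np.all(np.abs(angles[:, 1]) <= 90.0 + 1e-9)
        assert kin.quat_allclose(kin.compose_euler(angles, order), q, atol=1e-8)

    def test_sign_invariance(self, rng):
        q = random_unit_quats(rng, 200)
        a1, _ = kin.decompose_euler(q, "YXZ")
        a2, _ = kin.decompose_euler(-q, "YXZ")
        np.testing.assert_allclose(a1, a2, atol=1e-10)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(-1.0, 1.0, allow_nan=False).filter(lambda x: abs(x) > 1e-3),
            min_size=4, max_size=4,
        ),
        st.sampled_from(kin.EULER_ORDERS),
    )
    def test_round_trip_property(self, components, order):
        """Any rotation survives decompose-then-recompose, up to quaternion sign."""
        q = np.asarray(components) / np.linalg.norm(components)
        angles, _ = kin.decompose_euler(q, order)
        assert kin.quat_allclose(kin.compose_euler(angles, order), q, atol=1e-8)

    def test_gimbal_flag_near_singularity(self):
        q = kin.compose_euler([10.0, 89.5, 5.0], "YXZ")
        _, flag = kin.decompose_euler(q, "YXZ", gimbal_tol_deg=2.0)
        assert flag
        q = kin.compose_euler([10.0, 45.0, 5.0], "YXZ")
        _, flag = kin.decompose_euler(q, "YXZ", gimbal_tol_deg=2.0)
        assert not flag


class TestAlignment:
    def _stream(self, quats):
        return kin.OrientationStream(sensor_id="upper_arm", rate=100.0, quats=quats)

    def test_identity_placement_is_noop(self, rng):
        q = random_unit_quats(rng, 50)
        placement = kin.SensorPlacement("upper_arm", "upper_arm")  # si = +y
        out = kin.align_sensor_to_segment(self._stream(q), placement)
        assert kin.quat_allclose(out.quats, q, atol=1e-12)

    def test_rotated_si_axis_matches_direct_composition(self, rng):
        # si axis along sensor +x: a fixed non-trivial triad rotation
        placement = kin.SensorPlacement("upper_arm", "upper_arm", si_axis=(1, 0, 0))
        q = random_unit_quats(rng, 50)
        out = kin.align_sensor_to_segment(self._stream(q), placement)
        expected = kin.as_rotation(q) * placement.rotation()
        assert kin.quat_allclose(out.quats, kin.from_rotation(expected), atol=1e-12)

    def test_triad_is_right_handed_orthonormal(self):
        for axis in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.3, -0.8, 0.52)]:
            m = kin.SensorPlacement("head", "head", si_axis=axis).rotation().as_matrix()
            np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(m) == pytest.approx(1.0)

    def test_degenerate_si_axis_rejected(self):
        placement = kin.SensorPlacement("head", "head", si_axis=(0, 1e-12, 0))
        with pytest.raises(ConfigurationError):
            placement.rotation()

    def test_mismatched_sensor_id_rejected(self, rng):
        placement = kin.SensorPlacement("head", "head")
        with pytest.raises(ConfigurationError):
            kin.align_sensor_to_segment(self._stream(random_unit_quats(rng, 3)), placement)


class TestDeriveJointAngles:
    def _ramp_streams(self, jd, ramp_deg, n=100):
        parent = kin.OrientationStream(
            sensor_id=jd.parent_sensor, rate=100.0, quats=np.tile([1.0, 0, 0, 0], (n, 1))
        )
        angles = np.zeros((n, 3))
        angles[:, 0] = np.linspace(0.0, ramp_deg, n)
        child = kin.OrientationStream(
            sensor_id=jd.child_sensor, rate=100.0,
            quats=kin.compose_euler(angles, jd.euler_order),
        )
        return parent, child

    def test_constant_identical_streams_give_zero(self, joints):
        jd = joints["elbow"]
        n = 20
        s = kin.OrientationStream("upper_arm", 100.0, np.tile([1.0, 0, 0, 0], (n, 1)))
        s2 = kin.OrientationStream("forearm", 100.0, np.tile([1.0, 0, 0, 0], (n, 1)))
        out = kin.derive_joint_angles(s, s2, jd, reference_initial=(0, 0, 0))
        for series in out:
            np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_first_axis_ramp_with_initialization(self, joints):
        """A 0->40 deg ramp about the first Euler axis, initialized at 5 deg."""
        jd = joints["elbow"]
        parent, child = self._ramp_streams(jd, 40.0)
        out = kin.derive_joint_angles(parent, child, jd, reference_initial=(5.0, 0, 0))
        np.testing.assert_allclose(out[0].values, np.linspace(5.0, 45.0, 100), atol=1e-6)
        np.testing.assert_allclose(out[1].values, 0.0, atol=1e-6)
        np.testing.assert_allclose(out[2].values, 0.0, atol=1e-6)

    def test_sign_flip_inverts_ramp(self, joints):
        from dataclasses import replace

        jd = replace(joints["elbow"], sign_flips=(-1, 1, 1))
        parent, child = self._ramp_streams(jd, 40.0)
        out = kin.derive_joint_angles(parent, child, jd, reference_initial=(5.0, 0, 0))
        np.testing.assert_allclose(out[0].values, np.linspace(5.0, -35.0, 100), atol=1e-6)

    def test_negated_quaternions_give_same_angles(self, joints, rng):
        jd = joints["elbow"]
        parent, child = self._ramp_streams(jd, 40.0)
        out1 = kin.derive_joint_angles(parent, child, jd, (0, 0, 0))
        child_neg = kin.OrientationStream(jd.child_sensor, 100.0, -child.quats)
        out2 = kin.derive_joint_angles(parent, child_neg, jd, (0, 0, 0))
        for s1, s2 in zip(out1, out2):
            np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)

    def test_unwrap_across_180(self, joints):
        """A ramp crossing 180 deg must not fold back."""
        jd = joints["elbow"]
        parent, child = self._ramp_streams(jd, 200.0, n=400)
        out = kin.derive_joint_angles(parent, child, jd, reference_initial=(0, 0, 0))
        np.testing.assert_allclose(out[0].values, np.linspace(0, 200.0, 400), atol=1e-6)

    def test_stream_mismatch_rejected(self, joints):
        jd = joints["elbow"]
        parent, child = self._ramp_streams(jd, 40.0)
        short = kin.OrientationStream(jd.child_sensor, 100.0, child.quats[:-5])
        with pytest.raises(StreamMismatchError):
            kin.derive_joint_angles(parent, short, jd, (0, 0, 0))
        slow = kin.OrientationStream(jd.child_sensor, 50.0, child.quats)
        with pytest.raises(StreamMismatchError):
            kin.derive_joint_angles(parent, slow, jd, (0, 0, 0))


class TestCorrections:
    def test_flag_gimbal_within_limits_unchanged(self):
        s = constant_series(20.0, n=100)
        out = kin.flag_gimbal_anomalies(s, (-90, 90))
        assert out.quality_mask.all() and not out.excluded

    def test_flag_gimbal_all_out_of_range_excluded(self):
        s = constant_series(100.0, n=50)
        out = kin.flag_gimbal_anomalies(s, (-90, 90))
        assert not out.quality_mask.any() and out.excluded
        np.testing.assert_array_equal(out.values, s.values)  # values untouched

    def test_flag_gimbal_partial_below_threshold_retained(self):
        v = np.zeros(100)
        v[[10, 40, 70]] = 200.0
        s = constant_series(0.0, n=100).with_values(v)
        out = kin.flag_gimbal_anomalies(s, (-90, 90), exclusion_threshold=0.05)
        assert out.quality_mask.sum() == 97 and not out.excluded

    def test_rezero_shift_and_identity(self):
        s = constant_series(0.0, n=10).with_values(np.arange(10.0) + 12.0)
        out = kin.rezero(s, 0.0)
        assert out.values[0] == pytest.approx(0.0)
        np.testing.assert_allclose(out.values, np.arange(10.0))
        same = kin.rezero(s, s.values[0])
        np.testing.assert_allclose(same.values, s.values)

    def test_rezero_preserves_range_of_motion(self, rng):
        v = rng.normal(0, 20, 300)
        s = constant_series(0.0, n=300).with_values(v)
        out = kin.rezero(s, -33.3)
        assert mc.range_of_motion(out) == pytest.approx(mc.range_of_motion(s))

    def test_rezero_all_invalid_raises(self):
        s = constant_series(1.0, n=5)
        s.quality_mask[:] = False
        with pytest.raises(EmptySeriesError):
            kin.rezero(s, 0.0)

    def test_elbow_offset_arithmetic_and_inverse(self):
        s = constant_series(90.0, n=5, joint="elbow", system="markerless")
        out = kin.apply_elbow_offset(s, 15.0)
        np.testing.assert_allclose(out.values, 105.0)
        np.testing.assert_allclose(
            kin.apply_elbow_offset(out, -15.0).values, s.values, atol=1e-12
        )
        unchanged = kin.apply_elbow_offset(s, 0.0)
        np.testing.assert_allclose(unchanged.values, s.values)

    def test_elbow_offset_misuse_rejected(self):
        with pytest.raises(ConventionError):
            kin.apply_elbow_offset(constant_series(0, joint="shoulder", system="markerless"))
        with pytest.raises(ConventionError):
            kin.apply_elbow_offset(constant_series(0, joint="elbow", system="imu"))
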