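"""Sensor-to-segment alignment algebra, repetition segmentation, ROM."""

import numpy as np
import pytest

from margkin import align
from margkin.quatcore import (
    canonicalize,
    conjugate,
    hamilton,
    identity_quat,
    normalize,
    quat_angle,
    quat_from_axis_angle,
    quat_to_euler,
)


def _rand_quats(n, seed):
    rng = np.random.default_rng(seed)
    return normalize(rng.normal(size=(n, 4)))


class TestInitialFrames:
    def test_level_foot_gives_identity(self):
        q = align.derive_initial_frames(identity_quat())
        np.testing.assert_allclose(q, identity_quat(), atol=1e-12)

    def test_pitched_foot_keeps_heading(self):
        # Foot pitched 20° nose-up after a 30° yaw: the segment frame must
        # recover exactly the yaw, with zero roll/pitch.
        yaw = quat_from_axis_angle([0, 0, 1], np.deg2rad(30.0))
        pitch = quat_from_axis_angle([0, 1, 0], np.deg2rad(-20.0))
        q_foot = hamilton(yaw, pitch)
        q_seg = align.derive_initial_frames(q_foot)
        np.testing.assert_allclose(canonicalize(q_seg), canonicalize(yaw), atol=1e-9)

    def test_yawed_foot_yaws_all_frames(self):
        q_foot = quat_from_axis_angle([0, 0, 1], np.deg2rad(37.0))
        q_seg = align.derive_initial_frames(q_foot)
        ang = quat_to_euler(q_seg, "ZYX")
        np.testing.assert_allclose(ang, [37.0, 0.0, 0.0], atol=1e-9)

    def test_vertical_foot_axis_rejected(self):
        q_foot = quat_from_axis_angle([0, 1, 0], np.deg2rad(88.0))  # x-axis near vertical
        with pytest.raises(ValueError, match="degenerate"):
            align.derive_initial_frames(q_foot)


class TestAlignmentAlgebra:
    def test_identical_frames_give_identity_transform(self):
        q = _rand_quats(1, 0)[0]
        qt = align.alignment_transform(q, q)
        np.testing.assert_allclose(qt, identity_quat(), atol=1e-12)

    def test_sensor_rotated_about_segment_z(self):
        q_seg = identity_quat()
        q_sensor = quat_from_axis_angle([0, 0, 1], np.pi / 2)
        qt = align.alignment_transform(q_seg, q_sensor)
        np.testing.assert_allclose(qt, canonicalize(q_sensor), atol=1e-12)

    def test_transform_recovers_initial_segment_orientation(self):
        # Applying the per-sample formula at the calibration instant must
        # reproduce the assumed initial segment orientation, for any pair.
        q_seg0 = _rand_quats(1000, 1)
        q_sen0 = _rand_quats(1000, 2)
        qt = align.alignment_transform(q_seg0, q_sen0)
        back = align.segment_orientation(q_sen0, qt)
        err = quat_angle(hamilton(conjugate(q_seg0), back))
        assert err.max() < 1e-12

    def test_identity_transform_passthrough(self):
        q = _rand_quats(5, 3)
        out = align.segment_orientation(q, identity_quat())
        np.testing.assert_allclose(canonicalize(out), canonicalize(q), atol=1e-12)

    def test_rigid_corotation(self):
        # If sensor and segment rotate together by r, the aligned segment
        # orientation is r composed with the initial segment orientation.
        q_seg0 = _rand_quats(1, 4)[0]
        q_sen0 = _rand_quats(1, 5)[0]
        r = _rand_quats(1, 6)[0]
        qt = align.alignment_transform(q_seg0, q_sen0)
        out = align.segment_orientation(hamilton(r, q_sen0), qt)
        expected = hamilton(r, q_seg0)
        assert quat_angle(hamilton(conjugate(expected), out)) < 1e-12


class TestJointAngle:
    def test_identical_orientations_zero_flexion(self):
        q = _rand_quats(1, 7)[0]
        qj = align.joint_angle(q, q)
        np.testing.assert_allclose(canonicalize(qj), identity_quat(), atol=1e-12)
        assert align.flexion_trace(qj) == pytest.approx(0.0, abs=1e-9)

    def test_pure_sagittal_flexion(self):
        q_prox = _rand_quats(1, 8)[0]
        q_dist = hamilton(q_prox, quat_from_axis_angle([0, 1, 0], np.deg2rad(90.0)))
        qj = align.joint_angle(q_prox, q_dist)
        assert align.flexion_trace(qj) == pytest.approx(90.0, abs=1e-9)

    def test_swap_antisymmetry(self):
        q_prox = _rand_quats(1, 9)[0]
        q_dist = hamilton(q_prox, quat_from_axis_angle([0, 1, 0], np.deg2rad(35.0)))
        fwd = align.joint_angle(q_prox, q_dist)
        rev = align.joint_angle(q_dist, q_prox)
        np.testing.assert_allclose(canonicalize(rev), canonicalize(conjugate(fwd)), atol=1e-12)
        assert align.flexion_trace(rev) == pytest.approx(-align.flexion_trace(fwd))

    def test_full_range_flexion_not_clipped(self):
        # Sagittal-first decomposition must survive >90° (squat-scale) angles.
        q_prox = identity_quat()
        q_dist = quat_from_axis_angle([0, 1, 0], np.deg2rad(121.2))
        assert align.flexion_trace(align.joint_angle(q_prox, q_dist)) == pytest.approx(121.2, abs=1e-9)


class TestRepetitionSegmentation:
    @staticmethod
    def _series(flex, fs=100.0):
        t = np.arange(len(flex)) / fs
        return align.JointAngleSeries("hip", t, np.tile(identity_quat(), (len(flex), 1)), np.asarray(flex))

    def test_five_cycle_trace_gives_five_windows(self):
        t = np.arange(0, 12.5, 0.01)
        flex = 90 * np.clip(np.sin(2 * np.pi * t / 2.5 - np.pi / 2) * 0.5 + 0.5, 0, None)
        series = self._series(flex)
        wins = align.segment_repetitions(series)
        assert len(wins) == 5
        for w in wins:
            assert w.start < w.peak < w.end

    def test_constant_trace_empty(self):
        wins = align.segment_repetitions(self._series(np.full(500, 10.0)))
        assert wins == []

    def test_single_half_cycle(self):
        t = np.arange(0, 2.0, 0.01)
        flex = 60 * np.sin(np.pi * t / 2.0)
        wins = align.segment_repetitions(self._series(flex))
        assert len(wins) == 1

    def test_windows_ordered_non_overlapping(self):
        t = np.arange(0, 10.0, 0.01)
        flex = 50 * (0.5 - 0.5 * np.cos(2 * np.pi * t / 2.0))
        wins = align.segment_repetitions(self._series(flex))
        for a, b in zip(wins[:-1], wins[1:]):
            assert a.end <= b.start


class TestRom:
    @staticmethod
    def _series(flex, fs=100.0):
        t = np.arange(len(flex)) / fs
        return align.JointAngleSeries("knee", t, np.tile(identity_quat(), (len(flex), 1)), np.asarray(flex))

    def test_sinusoid_rom_is_twice_amplitude(self):
        t = np.arange(0, 6.0, 0.001)
        A = 40.0
        series = self._series(A * np.sin(2 * np.pi * t / 2.0), fs=1000.0)
        wins = align.segment_repetitions(series, min_rom=20, min_separation=1.0)
        rom = align.compute_rom(series, wins)
        np.testing.assert_allclose(rom.rom_deg, 2 * A, atol=0.01)

    def test_squat_scale_recovery(self, squat_noise_free):
        # Noise-free squat at the reference hip excursion: ROM within 1°.
        series = squat_noise_free["angles"]["hip"]
        wins = align.segment_repetitions(series)
        rom = align.compute_rom(series, wins)
        assert len(wins) == 5
        np.testing.assert_allclose(rom.rom_deg, 96.8, atol=1.0)

    def test_identical_windows_zero_sd(self):
        t = np.arange(0, 5.0, 0.01)
        series = self._series(30 * (0.5 - 0.5 * np.cos(2 * np.pi * t / 2.5)))
        wins = align.segment_repetitions(series)
        rom = align.compute_rom(series, wins)
        assert rom.sd == pytest.approx(0.0, abs=0.05)

    def test_out_of_bounds_window_rejected(self):
        series = self._series(np.zeros(100))
        with pytest.raises(ValueError, match="bounds"):
            align.compute_rom(series, [align.RepetitionWindow(0, 50, 150)])

    def test_rom_invariant_to_global_heading_rotation(self, squat_noise_free, rng):
        # A fixed rotation of the global frame about the vertical must not
        # change any joint ROM (the anatomical frames are gravity-anchored,
        # so only heading rotations leave the calibration assumptions valid).
        oris = squat_noise_free["orientations"]
        r = quat_from_axis_angle([0, 0, 1], float(rng.uniform(-np.pi, np.pi)))
        rotated = {
            seg: align.OrientationSeries if False else type(s)(
                time=s.time, quat=hamilton(np.tile(r, (s.quat.shape[0], 1)), s.quat), valid=s.valid, segment=s.segment
            )
            for seg, s in oris.items()
        }
        base_angles = squat_noise_free["angles"]
        rot_angles = align.compute_joint_angles(rotated, align.build_assignment(rotated, 0))
        for joint in align.JOINTS:
            w0 = align.segment_repetitions(base_angles[joint])
            w1 = align.segment_repetitions(rot_angles[joint])
            if not w0:
                continue
            r0 = align.compute_rom(base_angles[joint], w0)
            r1 = align.compute_rom(rot_angles[joint], w1)
            np.testing.assert_allclose(r1.rom_deg, r0.rom_deg, atol=1e-6)


class TestMisalignmentCompounding:
    def test_bias_grows_with_injected_calibration_error(self, squat_noise_free):
        # Deliberately corrupting the assumed initial foot frame by delta
        # degrees produces joint-angle bias that grows with delta.
        oris = squat_noise_free["orientations"]
        truth = squat_noise_free["truth"]

        def max_bias(delta_deg):
            assignment = align.build_assignment(oris, 0)
            err_q = quat_from_axis_angle([1, 0, 0], np.deg2rad(delta_deg))
            for seg in align.SEGMENTS:
                corrupted = hamilton(err_q, assignment.seg_initial[seg])
                assignment.transform[seg] = align.alignment_transform(
                    corrupted if seg in ("thigh", "foot") else assignment.seg_initial[seg],
                    assignment.sensor_initial[seg],
                )
            angles = align.compute_joint_angles(oris, assignment)
            return max(
                np.abs(angles[j].flexion_deg - truth.joint_flexion_deg[j]).max() for j in align.JOINTS
            )

        b0, b1, b2 = max_bias(0.0), max_bias(4.0), max_bias(8.0)
        assert b0 < b1 <= b2


class TestCalibrationIndex:
    def test_initial_transient_skipped(self):
        fs = 1125.0
        n = int(2 * fs)
        gyro = np.zeros((n, 3))
        gyro[:200, 0] = 2.0  # start-of-recording transient
        idx = align.find_calibration_index(gyro, fs)
        assert idx >= 200

    def test_no_static_window_rejected(self):
        gyro = np.full((1000, 3), 1.0)
        with pytest.raises(ValueError, match="quasi-static"):
            align.find_calibration_index(gyro, 1125.0)
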