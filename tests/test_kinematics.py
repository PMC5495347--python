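"""Calibration, frame construction and joint-angle decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from armkin.kinematics import (
    CHANNELS,
    DEFAULT_CONVENTIONS,
    DegenerateFrameError,
    calibrate_landmarks,
    compose_rotation,
    compute_joint_angles,
    compute_segment_frames,
    decompose_rotation,
)
from armkin.markers import (
    DEFAULT_MARKER_SET,
    MarkerSetDefinition,
    MarkerTrajectorySet,
    MarkerValidationError,
)
from armkin.simulate import (
    SimulationConfig,
    _recording_channels,
    forward_kinematics,
    markers_from_poses,
    simulate_child_trial,
    BodyModel,
)
from tests.conftest import NOISY_CONFIG, NULL_CONFIG


def _angles_vs_truth(trial, model, truth, task, curvature, lowpass):
    angles = compute_joint_angles(
        compute_segment_frames(trial, model, lowpass_hz=lowpass)
    )
    q, _ = _recording_channels(task, NULL_CONFIG, truth.offsets, truth.slopes,
                               truth.duration_factor, curvature)
    return angles, q


class TestDecomposeRotation:
    @pytest.mark.parametrize("seq", ["ZXY", "YXZ", "YXY"])
    def test_identity_gives_zero(self, seq):
        ang, gimbal = decompose_rotation(np.eye(3), seq)
        assert np.allclose(ang, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seq", ["ZXY", "YXZ", "YXY"])
    def test_pure_first_axis_rotation(self, seq):
        R = compose_rotation([30.0, 0.0, 0.0], seq)
        ang, _ = decompose_rotation(R, seq)
        # proper sequences are degenerate at zero middle angle: the twist
        # collapses onto the first angle either way
        assert ang[0] == pytest.approx(30.0, abs=1e-9)
        assert abs(ang[1]) < 1e-9

    @pytest.mark.parametrize("seq", ["ZXY", "YXZ", "YXY"])
    def test_round_trip_1000_random_rotations(self, seq, rng):
        # gimbal-excluded triplets: Tait-Bryan middle away from +/-90,
        # proper middle away from 0/180
        n = 1000
        first = rng.uniform(-170, 170, n)
        third = rng.uniform(-170, 170, n)
        if seq in ("ZXY", "YXZ"):
            mid = rng.uniform(-80, 80, n)
        else:
            mid = rng.uniform(10, 170, n)
        trip = np.column_stack([first, mid, third])
        R = compose_rotation(trip, seq)
        back, gimbal = decompose_rotation(R, seq)
        assert not gimbal.any()
        assert np.max(np.abs(back - trip)) < 1e-9

    def test_gimbal_flagged_with_third_angle_zeroed(self):
        R = compose_rotation([25.0, 90.0, 40.0], "ZXY")
        ang, gimbal = decompose_rotation(R, "ZXY")
        assert gimbal
        assert ang[2] == pytest.approx(0.0, abs=1e-9)
        # the full twist lands on the first angle
        assert ang[0] == pytest.approx(65.0, abs=1e-6)

    def test_nan_input_propagates(self):
        ang, gimbal = decompose_rotation(np.full((3, 3), np.nan), "ZXY")
        assert np.isnan(ang).all() and not gimbal


class TestCalibration:
    def test_noiseless_residual_at_numerical_precision(self, null_model):
        assert null_model.residual < 1e-9

    def test_one_millimeter_noise_residual_under_3mm(self, noisy_model):
        assert noisy_model.residual < 3e-3

    def test_missing_landmark_named(self, null_child):
        static, _, _ = null_child
        idx = static.index_of("EL")
        pos = static.positions.copy()
        pos[:, idx, :] = np.nan
        broken = MarkerTrajectorySet(labels=static.labels, positions=pos,
                                     rate=static.rate, trial_kind="static")
        with pytest.raises(MarkerValidationError, match="EL"):
            calibrate_landmarks(broken, DEFAULT_MARKER_SET)

    def test_collinear_cluster_is_degenerate(self, null_child):
        static, _, _ = null_child
        pos = static.positions.copy()
        # collapse the hand cluster onto a line
        for i, lbl in enumerate(("HAN1", "HAN2", "HAN3")):
            j = static.index_of(lbl)
            pos[:, j, :] = pos[:, static.index_of("HAN1"), :] + i * np.array(
                [0.01, 0.0, 0.0]
            )
        broken = MarkerTrajectorySet(labels=static.labels, positions=pos,
                                     rate=static.rate, trial_kind="static")
        with pytest.raises(DegenerateFrameError):
            calibrate_landmarks(broken, DEFAULT_MARKER_SET)


class TestSegmentFrames:
    def test_orthonormal_throughout(self, null_child, null_model):
        _, recs, _ = null_child
        frames = compute_segment_frames(recs["HTH"][0], null_model,
                                        lowpass_hz=None)
        for seg, R in frames.rotations.items():
            ok = frames.valid[seg]
            RtR = np.einsum("fji,fjk->fik", R[ok], R[ok])
            assert np.max(np.abs(RtR - np.eye(3))) < 1e-8
            assert np.allclose(np.linalg.det(R[ok]), 1.0, atol=1e-8)

    def test_rigid_translation_leaves_orientations_unchanged(
        self, null_child, null_model
    ):
        _, recs, _ = null_child
        trial = recs["HTH"][0]
        shifted = MarkerTrajectorySet(
            labels=trial.labels,
            positions=trial.positions + np.array([0.3, -0.1, 0.8]),
            rate=trial.rate,
        )
        f0 = compute_segment_frames(trial, null_model, lowpass_hz=None)
        f1 = compute_segment_frames(shifted, null_model, lowpass_hz=None)
        for seg in f0.rotations:
            assert np.nanmax(np.abs(f0.rotations[seg] - f1.rotations[seg])) < 1e-9

    def test_global_rotation_equivariance(self, null_child, null_model):
        _, recs, _ = null_child
        trial = recs["HTH"][0]
        Q = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        rotated = MarkerTrajectorySet(
            labels=trial.labels,
            positions=trial.positions @ Q.T,
            rate=trial.rate,
        )
        f0 = compute_segment_frames(trial, null_model, lowpass_hz=None)
        f1 = compute_segment_frames(rotated, null_model, lowpass_hz=None)
        for seg in f0.rotations:
            expected = np.einsum("ij,fjk->fik", Q, f0.rotations[seg])
            assert np.nanmax(np.abs(f1.rotations[seg] - expected)) < 1e-9

    def test_angles_invariant_to_lab_rigid_motion(self, null_child, null_model):
        # all 13 channels are translation-invariant; the 10 inter-segment
        # channels are also invariant to a global rotation (trunk channels
        # are lab-referenced by convention and rotate with the lab)
        _, recs, _ = null_child
        trial = recs["RGV"][0]
        Q = Rotation.from_euler("zyx", [20, 45, -30], degrees=True).as_matrix()
        moved = MarkerTrajectorySet(
            labels=trial.labels,
            positions=trial.positions @ Q.T + np.array([1.0, 0.2, -0.5]),
            rate=trial.rate,
        )
        a0 = compute_joint_angles(
            compute_segment_frames(trial, null_model, lowpass_hz=None))
        a1 = compute_joint_angles(
            compute_segment_frames(moved, null_model, lowpass_hz=None))
        inter = [i for i, ch in enumerate(a0.channels)
                 if not ch.startswith("trunk")]
        assert np.nanmax(np.abs(a0.values[:, inter] - a1.values[:, inter])) < 1e-8

    def test_fully_occluded_segment_frame_flagged_invalid(
        self, null_child, null_model
    ):
        _, recs, _ = null_child
        trial = recs["HTH"][0]
        pos = trial.positions.copy()
        for lbl in ("HAN1", "HAN2", "HAN3"):
            pos[100:120, trial.index_of(lbl), :] = np.nan
        occluded = MarkerTrajectorySet(labels=trial.labels, positions=pos,
                                       rate=trial.rate)
        frames = compute_segment_frames(occluded, null_model, lowpass_hz=None)
        assert not frames.valid["hand"][100:120].any()
        angles = compute_joint_angles(frames)
        assert np.isnan(angles.channel("wrist_flex_ext")[100:120]).all()


class TestJointAngles:
    def test_scripted_channels_recovered_exactly_noiseless(self, null_child,
                                                           null_model):
        _, recs, truth = null_child
        for task in ("HTH", "HTM", "RGV"):
            angles, q = _angles_vs_truth(recs[task][0], null_model, truth,
                                         task, 0.0, None)
            for ch in CHANNELS:
                assert np.nanmax(np.abs(angles.channel(ch) - q[ch])) < 1e-6

    def test_recovery_within_half_degree_at_1mm_noise(self, noisy_child,
                                                      noisy_model):
        _, recs, truth = noisy_child
        for task in ("HTH", "RGV"):
            angles, q = _angles_vs_truth(recs[task][0], noisy_model, truth,
                                         task, 0.0, 6.0)
            for ch in CHANNELS:
                err = angles.channel(ch) - q[ch]
                rmse = np.sqrt(np.nanmean(err**2))
                assert rmse < 0.5, f"{task}/{ch}: rmse {rmse:.3f} deg"

    def test_isolated_elbow_ramp_moves_only_the_elbow(self):
        # scripted 0 -> 60 degree elbow flexion on an otherwise frozen chain
        body = BodyModel.default()
        F = 200
        q = {ch: np.zeros(F) for ch in CHANNELS}
        base = 20.0
        q["elbow_flex_ext"] = base + np.linspace(0.0, 60.0, F)
        q["shoulder_elev"] = np.full(F, -40.0)  # keep clear of gimbal
        R, o = forward_kinematics(q, body)
        labels, pos = markers_from_poses(R, o, body)
        trial = MarkerTrajectorySet(labels=labels, positions=pos, rate=100.0)
        static, _, _ = simulate_child_trial("I", NULL_CONFIG, seed=2)
        model = calibrate_landmarks(static, DEFAULT_MARKER_SET)
        angles = compute_joint_angles(
            compute_segment_frames(trial, model, lowpass_hz=None))
        got = angles.channel("elbow_flex_ext")
        assert np.nanmax(np.abs(got - q["elbow_flex_ext"])) < 1e-6
        for ch in ("trunk_flex_ext", "trunk_lat_bend", "trunk_rot"):
            assert np.nanmax(np.abs(angles.channel(ch))) < 0.1

    def test_left_side_mirroring_matches_right(self, null_child):
        _, recs_r, _ = null_child
        ms_left = MarkerSetDefinition(side="left")
        static_l, recs_l, _ = simulate_child_trial(
            "I", NULL_CONFIG, seed=2, markerset=ms_left)
        static_r, _, _ = null_child
        model_r = calibrate_landmarks(static_r, DEFAULT_MARKER_SET)
        model_l = calibrate_landmarks(static_l, ms_left)
        a_r = compute_joint_angles(
            compute_segment_frames(recs_r["HTM"][0], model_r, lowpass_hz=None))
        a_l = compute_joint_angles(
            compute_segment_frames(recs_l["HTM"][0], model_l, lowpass_hz=None))
        assert np.nanmax(np.abs(a_r.values - a_l.values)) < 1e-9

    def test_thirteen_channels_and_conventions_consistent(self):
        assert len(CHANNELS) == 13
        mapped = [ch for conv in DEFAULT_CONVENTIONS
                  for ch in conv.channels if ch is not None]
        assert sorted(mapped) == sorted(CHANNELS)
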