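import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitlift._errors import DataError, DegenerateError, NoCycleError
from gaitlift.cli import AnalyzeConfig, analyze_pose
from gaitlift.containers import Pose3DSeries
from gaitlift.gait_geometry import (ANGLE_NAMES, compute_angle_curves,
                                    detect_heel_strikes, human_frame,
                                    knee_angle, plane_angles, resample_cycle,
                                    segment_vectors)


class TestHumanFrame:
    def test_advancing_origin_axes(self):
        F = 5
        PR = np.tile([1.0, 0.0, 0.0], (F, 1))
        PL = np.tile([-1.0, 0.0, 0.0], (F, 1))
        PR[:, 1] = PL[:, 1] = np.arange(F)  # origin advances along +Y
        frame = human_frame(PR, PL)
        assert np.allclose(frame.xh, [1, 0, 0], atol=1e-12)
        assert np.allclose(frame.yh, [0, 0, 1], atol=1e-12)
        assert np.allclose(frame.zh, [0, -1, 0], atol=1e-12)

    def test_orthonormal_right_handed(self, rng):
        PR = rng.normal(size=(20, 3)).cumsum(axis=0) + [50, 0, 0]
        PL = PR + rng.normal(size=(20, 3)) * 0.1 + [-100, 0, 0]
        frame = human_frame(PR, PL)
        for a, b in [(frame.xh, frame.yh), (frame.xh, frame.zh),
                     (frame.yh, frame.zh)]:
            assert np.abs(np.sum(a * b, axis=1)).max() < 1e-9
        for a in (frame.xh, frame.yh, frame.zh):
            assert np.abs(np.linalg.norm(a, axis=1) - 1).max() < 1e-9
        cross = np.cross(frame.xh, frame.yh)
        assert np.allclose(cross, frame.zh, atol=1e-9)

    def test_first_frame_copies_second(self):
        PR = np.array([[1.0, 0, 0], [1, 1, 0], [1, 2, 0]])
        PL = PR - [2, 0, 0]
        frame = human_frame(PR, PL)
        assert np.array_equal(frame.v2[0], frame.v2[1])

    def test_stationary_origin_degenerate(self):
        PR = np.tile([1.0, 0, 0], (4, 1))
        PL = np.tile([-1.0, 0, 0], (4, 1))
        with pytest.raises(DegenerateError):
            human_frame(PR, PL)

    def test_coincident_hips_degenerate(self):
        P = np.arange(12, dtype=float).reshape(4, 3)
        with pytest.raises(DegenerateError):
            human_frame(P, P)


class TestKneeAngle:
    @pytest.mark.parametrize("T,S,expected", [
        ([0, 0, 1], [0, 0, 1], 0.0),
        ([0, 0, 1], [0, 1, 0], np.pi / 2),
        ([0, 0, 1], [0, 1, 1], np.pi / 4),
    ])
    def test_reference_angles(self, T, S, expected):
        assert knee_angle(T, S) == pytest.approx(expected, abs=1e-12)

    def test_zero_segment_rejected(self):
        with pytest.raises(DegenerateError):
            knee_angle([0, 0, 0], [0, 0, 1])


class TestPlaneAngles:
    def _frame(self, F=3):
        PR = np.tile([1.0, 0, 0], (F, 1))
        PL = np.tile([-1.0, 0, 0], (F, 1))
        PR[:, 1] = PL[:, 1] = np.arange(F)
        return human_frame(PR, PL)

    def test_aligned_segment_angle_zero(self):
        frame = self._frame()
        from gaitlift.gait_geometry import SegmentVectors
        U = np.tile([1.0, 0, 0], (3, 1))      # along xh
        T = np.tile([0.0, 0, 1], (3, 1))
        S = np.tile([0.0, 1, 0], (3, 1))
        angles = plane_angles(SegmentVectors(U=U, T=T, S=S), frame)
        assert np.allclose(angles["RUX"], 0.0, atol=1e-12)

    def test_orthogonal_segment_angle_right(self):
        frame = self._frame()
        from gaitlift.gait_geometry import SegmentVectors
        T = np.tile([0.0, 1, 1], (3, 1))      # in the yh-zh plane
        segs = SegmentVectors(U=T.copy(), T=T, S=T.copy())
        assert np.allclose(plane_angles(segs, frame)["RTX"], np.pi / 2,
                           atol=1e-12)

    def test_all_angles_in_range(self, sim_bundle):
        curves = _marker_curves(sim_bundle)
        for name in ANGLE_NAMES:
            series = curves.angles[name]
            assert np.all(series >= 0) and np.all(series <= np.pi)


def _marker_curves(bundle):
    pose = bundle.pose3d
    frame = human_frame(pose.joint("right_hip"), pose.joint("left_hip"))
    return compute_angle_curves(pose, frame)


class TestRigidInvariance:
    def test_angles_invariant_to_rigid_motion_and_scale(self, sim_bundle):
        pose = sim_bundle.pose3d
        base = _marker_curves(sim_bundle)
        R = Rotation.from_euler("xyz", [21.0, -35.0, 64.0],
                                degrees=True).as_matrix()
        moved = Pose3DSeries(
            fps=pose.fps,
            coords=2.5 * pose.coords @ R.T + np.array([100.0, -50.0, 30.0]))
        transformed = _marker_curves(
            type(sim_bundle)(config=sim_bundle.config, pose3d=moved,
                             markers=sim_bundle.markers,
                             keypoints=sim_bundle.keypoints,
                             analytic_knee_angle=sim_bundle.analytic_knee_angle,
                             analytic_strike_times=sim_bundle.analytic_strike_times,
                             analytic_strike_frames=sim_bundle.analytic_strike_frames))
        for name in ANGLE_NAMES:
            assert np.allclose(base.angles[name], transformed.angles[name],
                               atol=1e-9), name

    def test_rts_matches_analytic_curve(self, sim_bundle):
        segs = segment_vectors(sim_bundle.pose3d)
        rts = knee_angle(segs.T, segs.S)
        assert np.abs(rts - sim_bundle.analytic_knee_angle).max() < 1e-6


class TestHeelStrikes:
    def test_sinusoid_strikes_spaced_by_period(self):
        P = 80
        t = np.arange(3 * P)
        x = np.sin(2 * np.pi * t / P)
        index = detect_heel_strikes(x, fps=60.0)
        assert np.array_equal(index.strikes, [P // 4, P // 4 + P,
                                              P // 4 + 2 * P])
        assert np.all(np.diff(index.strikes) == P)

    def test_constant_series_no_cycle(self):
        with pytest.raises(NoCycleError):
            detect_heel_strikes(np.ones(200), fps=60.0)

    def test_small_noise_keeps_strike_count(self):
        P = 80
        t = np.arange(3 * P)
        clean = np.sin(2 * np.pi * t / P)
        noisy = clean + np.random.default_rng(42).normal(0, 0.01, len(t))
        a = detect_heel_strikes(clean, fps=60.0)
        b = detect_heel_strikes(noisy, fps=60.0)
        assert len(a.strikes) == len(b.strikes)

    def test_detected_within_2_frames_of_analytic(self, sim_bundle):
        res = analyze_pose(sim_bundle.pose3d, AnalyzeConfig())
        detected = res.cycle_index.strikes
        dev = np.abs(detected[:, None]
                     - sim_bundle.analytic_strike_frames[None, :]).min(axis=1)
        assert dev.max() <= 2


class TestResampleCycle:
    def test_constant_series(self):
        out = resample_cycle(np.full(100, 3.3), (10, 60), 50)
        assert np.allclose(out, 3.3)

    def test_linear_ramp_gives_arithmetic_progression(self):
        series = np.arange(100, dtype=float)
        out = resample_cycle(series, (20, 70), 25)
        assert np.allclose(np.diff(out), 2.0)
        assert out[0] == 20.0

    def test_sinusoid_matches_analytic_phases(self):
        P = 120
        t = np.arange(4 * P)
        series = np.sin(2 * np.pi * t / P)
        K = 50
        out = resample_cycle(series, (P, 2 * P), K)
        phases = P + P * np.arange(K) / K
        analytic = np.sin(2 * np.pi * phases / P)
        assert np.abs(out - analytic).max() < 1e-3

    def test_bad_cycle_rejected(self):
        with pytest.raises(DataError):
            resample_cycle(np.arange(10.0), (5, 5), 10)
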