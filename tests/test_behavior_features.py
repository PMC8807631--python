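"""Egocentric speeds, social distances, events, head direction, features."""

import numpy as np
import pytest

from socialtrack3d.behavior_features import (FeatureMatrix, SocialEvent,
                                             build_feature_matrix,
                                             detect_social_events,
                                             egocentric_speeds,
                                             head_direction_partner,
                                             social_distances)
from socialtrack3d.body_model import BodyConstants, build_skeletons_batch
from socialtrack3d.scene_synthesis import (KP_CODE, PointCloudFrame,
                                           SceneConfig, ear_landmarks,
                                           sample_pose_sequence)
from socialtrack3d.tracker import RawTrack
from socialtrack3d.trajectory_smoothing import KalmanConfig, rebuild_skeletons

BC = BodyConstants()


def _track_from_params(p0, p1):
    """Ground-truth SmoothedTrack without tracking (smoothing a clean track)."""
    raw = RawTrack(np.asarray(p0, dtype=float), np.asarray(p1, dtype=float),
                   np.zeros(len(p0)))
    return rebuild_skeletons(raw, KalmanConfig.for_synthetic_tracker())


def _static_params(T, x0=(-0.12, 0, 0.02), x1=(0.12, 0, 0.02), gamma1=np.pi):
    p0 = np.zeros((T, 9))
    p0[:, :3] = x0
    p0[:, 7] = 0.5
    p1 = np.zeros((T, 8))
    p1[:, :3] = x1
    p1[:, 4] = gamma1
    p1[:, 7] = 0.5
    return p0, p1


class TestEgocentricSpeeds:
    def test_stationary_pose_has_zero_speed(self):
        track = _track_from_params(*_static_params(60))
        v = egocentric_speeds(track, 0)
        assert np.allclose(v, 0, atol=1e-9)

    def test_pure_forward_translation(self):
        p0, p1 = _static_params(120)
        p0[:, 0] = -0.2 + 0.1 * np.arange(120) / 60.0  # +x at 0.1 m/s, heading +x
        track = _track_from_params(p0, p1)
        v = egocentric_speeds(track, 0)
        sl = slice(30, 90)
        assert np.allclose(v[sl, 0], 0.1, atol=1e-3)
        assert np.allclose(v[sl, 1:], 0, atol=1e-3)

    def test_matches_rotated_frame_finite_difference_oracle(self):
        T = 180
        p0, p1 = _static_params(T, x1=(0.3, 0.3, 0.02))
        t = np.arange(T) / 60.0
        # Circular translation with heading following the motion.
        R_c, om = 0.08, 1.2
        p0[:, 0] = R_c * np.cos(om * t) - 0.15
        p0[:, 1] = R_c * np.sin(om * t)
        p0[:, 4] = om * t + np.pi / 2
        track = _track_from_params(p0, p1)
        v = egocentric_speeds(track, 0)
        c_hip = track.landmarks0["c_hip"]
        axis = track.hip_axis(0)
        v_ref = np.gradient(c_hip, 1 / 60.0, axis=0)
        fwd = axis.copy()
        fwd[:, 2] = 0
        fwd /= np.linalg.norm(fwd, axis=1, keepdims=True)
        left = np.stack([-fwd[:, 1], fwd[:, 0], np.zeros(T)], 1)
        sl = slice(20, T - 20)
        assert np.allclose(v[sl, 0], np.sum(v_ref * fwd, 1)[sl], atol=1e-9)
        assert np.allclose(v[sl, 1], np.sum(v_ref * left, 1)[sl], atol=1e-9)
        # Tangential speed magnitude ~ omega * R on the smoothed trajectory.
        speed = np.linalg.norm(v_ref[:, :2], axis=1)
        assert np.allclose(np.hypot(v[sl, 0], v[sl, 1]), speed[sl], atol=1e-6)


class TestSocialDistances:
    def test_identical_tips_give_zero(self):
        p0, p1 = _static_params(10, x0=(0, 0, 0.02), x1=(0, 0, 0.02), gamma1=0)
        track = _track_from_params(p0, p1)
        d = social_distances(track)
        assert np.allclose(d[:, 0], 0, atol=1e-9)

    def test_hand_placed_separation(self):
        # Two mice facing each other, tips 7 cm apart.
        reach0 = np.linalg.norm(
            build_skeletons_batch(_static_params(1)[0][:1], BC, True)["c_tip"][0]
            - [-0.12, 0, 0.02])
        gap = 0.07
        x = reach0 + gap / 2
        p0, p1 = _static_params(10, x0=(-x, 0, 0.02), x1=(x, 0, 0.02))
        track = _track_from_params(p0, p1)
        assert np.allclose(social_distances(track)[:, 0], gap, atol=1e-6)

    def test_equals_per_frame_loop(self):
        cfg = SceneConfig(n_frames=40, seed=3)
        seq = sample_pose_sequence(cfg)
        track = _track_from_params(seq.params_implanted, seq.params_partner)
        d = social_distances(track)
        for t in range(0, 40, 7):
            tip0 = track.landmarks0["c_tip"][t]
            tip1 = track.landmarks1["c_tip"][t]
            tail0 = track.landmarks0["c_tail"][t]
            tail1 = track.landmarks1["c_tail"][t]
            assert d[t, 0] == pytest.approx(np.linalg.norm(tip0 - tip1))
            assert d[t, 1] == pytest.approx(np.linalg.norm(tip0 - tail1))
            assert d[t, 2] == pytest.approx(np.linalg.norm(tip1 - tail0))


class TestEventDetection:
    def test_scripted_episode_detected(self):
        cfg = SceneConfig(n_frames=600, seed=2)
        seq = sample_pose_sequence(cfg)
        track = _track_from_params(seq.params_implanted, seq.params_partner)
        events = detect_social_events(social_distances(track))
        for episode in seq.episodes:
            matching = [e for e in events if e.kind == episode["kind"]]
            assert len(matching) == 1
            ev = matching[0]
            assert abs(ev.start - episode["start"]) <= 30
            assert abs(ev.end - episode["end"]) <= 30

    def test_brief_crossing_removed_by_opening(self):
        d = np.full((100, 3), 0.2)
        d[50:52, 0] = 0.01  # 2-frame nose-nose crossing
        assert detect_social_events(d) == []

    def test_gap_merged_by_closing(self):
        d = np.full((200, 3), 0.2)
        d[50:70, 0] = 0.01
        d[90:110, 0] = 0.01  # 20-frame gap between two nose-nose episodes
        events = detect_social_events(d)
        nn = [e for e in events if e.kind == "nose_nose"]
        assert len(nn) == 1
        assert nn[0].start <= 50 + 3 and nn[0].end >= 110 - 3

    def test_idempotent_and_noise_invariant(self, rng):
        d = np.full((300, 3), 0.2)
        d[100:160, 1] = 0.012  # nose0 -> tail1 contact
        base = detect_social_events(d)
        noisy = d + rng.uniform(-0.003, 0.003, d.shape)
        assert detect_social_events(d) == base
        events = detect_social_events(noisy)
        assert [(e.kind, e.start, e.end) for e in events] == \
            [(e.kind, e.start, e.end) for e in base]

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            SocialEvent("nose_nose", 10, 10)
        with pytest.raises(ValueError):
            SocialEvent("bogus", 0, 5)


class TestHeadDirection:
    def _frames_with_ears(self, track, roll=0.0, drop_frame=None):
        """Synthesize ear key-points for body 1, optionally rolled about the
        nose axis."""
        T = len(track)
        frames = []
        lm = track.landmarks1
        axis = track.head_axis(1)
        bc = BC
        for t in range(T):
            sk = {"c_nose": lm["c_nose"][t:t + 1],
                  "R_hip": np.eye(3)[None], "R_head": np.eye(3)[None]}
            # Build ears in a frame aligned with the head axis.
            from socialtrack3d.body_model import rotation_aligning
            R = rotation_aligning(np.array([1.0, 0, 0]), axis[t])
            if roll:
                from scipy.spatial.transform import Rotation
                R = R @ Rotation.from_rotvec([roll, 0, 0]).as_matrix()
            sk = {"c_nose": lm["c_nose"][t:t + 1], "R_hip": R[None],
                  "R_head": np.eye(3)[None]}
            ears = ear_landmarks(sk, bc, np.deg2rad(60), np.deg2rad(30))[0]
            if drop_frame is not None and t == drop_frame:
                kp = np.zeros((0, 3))
                types = np.zeros(0, dtype=int)
            else:
                kp = ears
                types = np.full(2, KP_CODE["ear"])
            frames.append(PointCloudFrame(np.zeros((0, 3)), np.zeros(0), kp,
                                          np.ones(len(kp)), types))
        return frames

    def test_symmetric_level_ears_point_up(self):
        p0, p1 = _static_params(80, gamma1=0.4)
        track = _track_from_params(p0, p1)
        frames = self._frames_with_ears(track)
        hd = head_direction_partner(track, frames)
        assert np.allclose(np.linalg.norm(hd, axis=1), 1, atol=1e-9)
        v_nose = track.head_axis(1)
        assert np.max(np.abs(np.sum(hd * v_nose, axis=1))) < 1e-6
        assert np.all(hd[:, 2] > 0.99)

    def test_head_roll_recovered(self):
        p0, p1 = _static_params(120, gamma1=0.4)
        track = _track_from_params(p0, p1)
        roll = np.deg2rad(30)
        frames = self._frames_with_ears(track, roll=roll)
        hd = head_direction_partner(track, frames)
        up = np.array([0.0, 0.0, 1.0])
        tilt = np.arccos(np.clip(hd[20:-20] @ up, -1, 1))
        assert np.all(np.abs(tilt - roll) < np.deg2rad(5))

    def test_missing_ear_frame_interpolated(self):
        p0, p1 = _static_params(60)
        track = _track_from_params(p0, p1)
        frames = self._frames_with_ears(track, drop_frame=30)
        hd = head_direction_partner(track, frames)
        assert np.all(np.isfinite(hd))

    def test_no_ears_at_all_is_an_error(self):
        p0, p1 = _static_params(20)
        track = _track_from_params(p0, p1)
        empty = PointCloudFrame(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 3)),
                                np.zeros(0), np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            head_direction_partner(track, [empty] * 20)


class TestFeatureMatrix:
    def test_exactly_45_named_columns(self):
        p0, p1 = _static_params(60)
        fm = build_feature_matrix(_track_from_params(p0, p1))
        assert len(fm.names) == 45
        assert len(set(fm.names)) == 45

    def test_stationary_scene_has_zero_derivatives(self):
        p0, p1 = _static_params(80)
        fm = build_feature_matrix(_track_from_params(p0, p1))
        for name in fm.names:
            if name.startswith("d_") or "speed" in name or "range_rate" in name:
                assert np.allclose(fm.data[name], 0, atol=1e-6), name

    def test_angular_columns_wrapped(self):
        cfg = SceneConfig(n_frames=100, seed=6)
        seq = sample_pose_sequence(cfg)
        fm = build_feature_matrix(
            _track_from_params(seq.params_implanted, seq.params_partner))
        for name in fm.circular:
            col = fm.data[name].to_numpy()
            assert np.all(col > -np.pi - 1e-12) and np.all(col <= np.pi + 1e-12)

    def test_range_rate_negative_during_scripted_approach(self):
        cfg = SceneConfig(n_frames=600, seed=2)
        seq = sample_pose_sequence(cfg)
        fm = build_feature_matrix(
            _track_from_params(seq.params_implanted, seq.params_partner))
        ep = seq.episodes[0]
        pre = slice(max(ep["start"] - 40, 0), ep["start"])
        assert fm.data["hip_range_rate"].to_numpy()[pre].mean() < 0

    def test_duplicate_names_rejected(self):
        import pandas as pd
        df = pd.DataFrame(np.zeros((5, 2)), columns=["a", "a"])
        with pytest.raises(ValueError):
            FeatureMatrix(df)

    def test_csv_export(self, tmp_path):
        p0, p1 = _static_params(10)
        fm = build_feature_matrix(_track_from_params(p0, p1))
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        assert path.read_text().splitlines()[0].startswith("frame,")
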