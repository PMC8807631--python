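"""Tracking objective: clipped distance terms, barriers, batch correctness."""

import warnings

import numpy as np
import pytest

from socialtrack3d.body_model import BodyConstants, approx_surface_distance
from socialtrack3d.fit_loss import (CandidateSet, LossConfig, flip_barrier,
                                    keypoint_loss, overlap_barrier,
                                    pointcloud_loss, total_loss)
from socialtrack3d.scene_synthesis import (KP_CODE, PointCloudFrame,
                                           SceneConfig, render_frame,
                                           sample_pose_sequence)

BC = BodyConstants()
LC = LossConfig()


def _random_candidates(rng, n, implanted, center=(0, 0, 0.02)):
    dim = 9 if implanted else 8
    p = np.zeros((n, dim))
    p[:, :3] = np.asarray(center) + rng.normal(0, 0.03, (n, 3))
    p[:, 3:5] = rng.uniform(-0.5, 0.5, (n, 2))
    p[:, 5] = rng.uniform(-1.0, 1.0, n)
    p[:, 6] = rng.uniform(-0.8, 0.8, n)
    p[:, 7] = rng.uniform(0, 1, n)
    if implanted:
        p[:, 8] = rng.uniform(-np.pi, np.pi, n)
    return p


def _random_frame(rng, n_points=40, n_kp=6):
    return PointCloudFrame(
        rng.normal(0, 0.05, (n_points, 3)) + [0, 0, 0.02],
        rng.uniform(0.1, 0.5, n_points),
        rng.normal(0, 0.05, (n_kp, 3)) + [0, 0, 0.02],
        rng.uniform(0.5, 1.0, n_kp),
        rng.integers(0, 4, n_kp))


def _loop_loss_oracle(frame, set0, set1, config):
    """Naive per-pair re-implementation of the clipped min-distance losses."""
    m, n = len(set0), len(set1)
    pc = np.zeros((m, n))
    kp = np.zeros((m, n))
    d0 = set0.surface_distances(frame.points)
    d1 = set1.surface_distances(frame.points)
    k0 = set0.keypoint_distances(frame)
    k1 = set1.keypoint_distances(frame)
    w_kp = frame.kp_posterior if config.use_posterior_weights \
        else np.ones(frame.kp_count)
    for i in range(m):
        for j in range(n):
            for p in range(frame.n_points):
                pc[i, j] += frame.weights[p] * min(d0[i, p], d1[j, p],
                                                   config.clip_dist)
            for q in range(frame.kp_count):
                kp[i, j] += w_kp[q] * min(k0[i, q], k1[j, q], config.clip_dist)
    return pc, kp


class TestPointcloudLoss:
    def test_surface_cloud_has_zero_loss(self):
        cfg = SceneConfig(n_frames=2, pc_noise_sd=0, kp_noise_sd=0,
                          kp_dropout_prob=0, seed=1)
        seq = sample_pose_sequence(cfg)
        frame = render_frame(seq[0], cfg)
        s0 = CandidateSet(seq.params_implanted[:1], BC, True)
        s1 = CandidateSet(seq.params_partner[:1], BC, False)
        assert pointcloud_loss(frame, s0, s1, LC)[0, 0] < 1e-12

    def test_distant_point_contributes_clipped_weighted_value(self):
        frame = PointCloudFrame(np.array([[1.0, 1.0, 1.0]]), np.array([0.7]),
                                np.zeros((0, 3)), np.zeros(0),
                                np.zeros(0, dtype=int))
        s0 = CandidateSet(np.array([[0, 0, 0.02, 0, 0, 0, 0, 0.5, 0]]), BC, True)
        s1 = CandidateSet(np.array([[0.1, 0, 0.02, 0, 0, 0, 0, 0.5]]), BC, False)
        loss = pointcloud_loss(frame, s0, s1, LC)
        assert loss[0, 0] == pytest.approx(0.7 * LC.clip_dist)

    def test_empty_cloud_is_zero_with_warning(self):
        frame = PointCloudFrame(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 3)),
                                np.zeros(0), np.zeros(0, dtype=int))
        s0 = CandidateSet(np.array([[0, 0, 0.02, 0, 0, 0, 0, 0.5, 0]]), BC, True)
        s1 = CandidateSet(np.array([[0.1, 0, 0.02, 0, 0, 0, 0, 0.5]]), BC, False)
        with pytest.warns(UserWarning):
            assert np.all(pointcloud_loss(frame, s0, s1, LC) == 0)

    def test_invariant_to_point_relabeling(self, rng):
        frame = _random_frame(rng)
        perm = rng.permutation(frame.n_points)
        shuffled = PointCloudFrame(frame.points[perm], frame.weights[perm],
                                   frame.keypoints, frame.kp_posterior,
                                   frame.kp_type)
        s0 = CandidateSet(_random_candidates(rng, 3, True), BC, True)
        s1 = CandidateSet(_random_candidates(rng, 4, False), BC, False)
        assert np.allclose(pointcloud_loss(frame, s0, s1, LC),
                           pointcloud_loss(shuffled, s0, s1, LC))


class TestKeypointLoss:
    def test_keypoints_at_landmarks_give_zero(self):
        cfg = SceneConfig(n_frames=2, pc_noise_sd=0, kp_noise_sd=0,
                          kp_dropout_prob=0, seed=1)
        seq = sample_pose_sequence(cfg)
        frame = render_frame(seq[0], cfg)
        s0 = CandidateSet(seq.params_implanted[:1], BC, True)
        s1 = CandidateSet(seq.params_partner[:1], BC, False)
        assert keypoint_loss(frame, s0, s1, LC)[0, 0] < 1e-12

    def test_equidistant_keypoint_tie_is_loss_neutral(self):
        # A nose key-point exactly between two mirrored bodies: the loss is
        # the same whichever body it is assigned to.
        p0 = np.array([[-0.1, 0, 0.02, 0, 0, 0, 0, 0.5, 0]])
        p1 = np.array([[0.1, 0, 0.02, 0, np.pi, 0, 0, 0.5]])
        s0 = CandidateSet(p0, BC, True)
        s1 = CandidateSet(p1, BC, False)
        kp = np.array([[0.0, 0.0, 0.02]])
        frame = PointCloudFrame(np.zeros((0, 3)), np.zeros(0), kp,
                                np.ones(1), np.array([KP_CODE["nose"]]))
        d0 = s0.keypoint_distances(frame)[0, 0]
        d1 = s1.keypoint_distances(frame)[0, 0]
        assert d0 == pytest.approx(d1)
        loss = keypoint_loss(frame, s0, s1, LC)
        assert loss[0, 0] == pytest.approx(min(d0, LC.clip_dist))

    def test_unknown_keypoint_type_rejected(self, rng):
        frame = PointCloudFrame(np.zeros((0, 3)), np.zeros(0),
                                np.zeros((1, 3)), np.ones(1), np.array([7]))
        s0 = CandidateSet(_random_candidates(rng, 1, True), BC, True)
        s1 = CandidateSet(_random_candidates(rng, 1, False), BC, False)
        with pytest.raises(ValueError):
            keypoint_loss(frame, s0, s1, LC)


class TestBatchEqualsLoop:
    def test_batched_losses_match_naive_loop_oracle(self, rng):
        frame = _random_frame(rng)
        s0 = CandidateSet(_random_candidates(rng, 5, True), BC, True)
        s1 = CandidateSet(_random_candidates(rng, 7, False), BC, False)
        pc_ref, kp_ref = _loop_loss_oracle(frame, s0, s1, LC)
        assert np.allclose(pointcloud_loss(frame, s0, s1, LC), pc_ref,
                           atol=1e-10)
        assert np.allclose(keypoint_loss(frame, s0, s1, LC), kp_ref, atol=1e-10)

    def test_chunked_evaluation_matches_unchunked(self, rng):
        frame = _random_frame(rng, n_points=100)
        s0 = CandidateSet(_random_candidates(rng, 4, True), BC, True)
        s1 = CandidateSet(_random_candidates(rng, 4, False), BC, False)
        small = LossConfig(point_chunk=7)
        assert np.allclose(pointcloud_loss(frame, s0, s1, LC),
                           pointcloud_loss(frame, s0, s1, small), atol=1e-12)


class TestBarriers:
    def test_distant_bodies_unpenalized(self):
        s0 = CandidateSet(np.array([[-0.5, 0, 0.02, 0, 0, 0, 0, 0.5, 0]]), BC, True)
        s1 = CandidateSet(np.array([[0.5, 0, 0.02, 0, 0, 0, 0, 0.5]]), BC, False)
        assert overlap_barrier(s0, s1, LC)[0, 0] == 0

    def test_identical_poses_fully_penalized(self):
        p = np.array([[0, 0, 0.02, 0, 0, 0, 0, 0.5]])
        s0 = CandidateSet(np.hstack([p, [[0.1]]]), BC, True)
        s1 = CandidateSet(p, BC, False)
        assert overlap_barrier(s0, s1, LC)[0, 0] == LC.barrier_penalty

    def test_boundary_is_strict(self):
        # Hip centers exactly at 0.8 * (b0 + b1): no penalty; just inside: penalty.
        s_val = 0.5
        b_hip = BC.b_hip_min + (BC.b_hip_max - BC.b_hip_min) * (1 - s_val)
        # Keep heads pointing away so only the hip-hip pair is near the limit.
        lim = 0.8 * (b_hip + b_hip)
        p0 = np.array([[0, 0, 0.02, 0, np.pi, 0, 0, s_val, 0.0]])
        p1 = np.array([[lim, 0, 0.02, 0, 0.0, 0, 0, s_val]])
        s0 = CandidateSet(p0, BC, True)
        s1 = CandidateSet(p1, BC, False)
        assert overlap_barrier(s0, s1, LC)[0, 0] == 0
        p1_in = p1.copy()
        p1_in[0, 0] = lim - 1e-6
        assert overlap_barrier(s0, CandidateSet(p1_in, BC, False),
                               LC)[0, 0] == LC.barrier_penalty

    def test_flip_barrier_against_previous_frame(self):
        prev0 = CandidateSet(np.array([[-0.1, 0, 0.02, 0, 0, 0, 0, 0.5, 0]]),
                             BC, True)
        prev1 = CandidateSet(np.array([[0.1, 0, 0.02, 0, np.pi, 0, 0, 0.5]]),
                             BC, False)
        # Candidate for body 0 sitting on the previous position of body 1.
        swapped0 = CandidateSet(np.array([[0.1, 0, 0.02, 0, np.pi, 0, 0, 0.5, 0]]),
                                BC, True)
        ok1 = CandidateSet(np.array([[0.3, 0, 0.02, 0, 0, 0, 0, 0.5]]), BC, False)
        pen = flip_barrier(swapped0, ok1, (prev0, prev1), LC)
        assert pen[0, 0] == LC.barrier_penalty
        stay0 = CandidateSet(np.array([[-0.1, 0, 0.02, 0, 0, 0, 0, 0.5, 0]]),
                             BC, True)
        assert flip_barrier(stay0, ok1, (prev0, prev1), LC)[0, 0] == 0
        assert flip_barrier(stay0, ok1, None, LC)[0, 0] == 0


class TestTotalLoss:
    def test_ground_truth_attains_matrix_minimum(self, rng):
        cfg = SceneConfig(n_frames=2, pc_noise_sd=0, kp_noise_sd=0,
                          kp_dropout_prob=0, seed=4)
        seq = sample_pose_sequence(cfg)
        frame = render_frame(seq[0], cfg)
        truth0, truth1 = seq.params_implanted[0], seq.params_partner[0]
        c0 = np.vstack([truth0, _random_candidates(rng, 6, True, truth0[:3])])
        c1 = np.vstack([truth1, _random_candidates(rng, 6, False, truth1[:3])])
        loss = total_loss(frame, CandidateSet(c0, BC, True),
                          CandidateSet(c1, BC, False), None, LC)
        assert np.unravel_index(np.argmin(loss), loss.shape) == (0, 0)

    def test_zero_weights_give_zero_matrix(self, rng):
        frame = _random_frame(rng)
        cfg = LossConfig(w_pointcloud=0.0, w_keypoint=0.0)
        s0 = CandidateSet(_random_candidates(rng, 3, True, (-0.2, 0, 0.02)),
                          BC, True)
        s1 = CandidateSet(_random_candidates(rng, 3, False, (0.2, 0, 0.02)),
                          BC, False)
        loss = total_loss(frame, s0, s1, None, cfg)
        assert loss.shape == (3, 3)
        # Barriers may still fire; mask them out by construction (bodies far).
        assert np.all(loss[loss < cfg.barrier_penalty] == 0)

    def test_single_candidates_give_1x1_matrix(self, rng):
        frame = _random_frame(rng)
        s0 = CandidateSet(_random_candidates(rng, 1, True, (-0.2, 0, 0.02)),
                          BC, True)
        s1 = CandidateSet(_random_candidates(rng, 1, False, (0.2, 0, 0.02)),
                          BC, False)
        loss = total_loss(frame, s0, s1, None, LC)
        assert loss.shape == (1, 1)
        pc = pointcloud_loss(frame, s0, s1, LC)[0, 0]
        kp = keypoint_loss(frame, s0, s1, LC)[0, 0]
        w_kp = frame.n_points / frame.kp_count
        assert loss[0, 0] == pytest.approx(pc + w_kp * kp)
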