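"""Per-frame tracking objective.

Four contributions, evaluated for batches of candidate poses of the two
bodies and broadcast over all m x n joint pairings:

* point-cloud term: camera-weighted, clipped approximate distance from every
  cloud point to the nearest body surface of the candidate pair;
* key-point term: clipped distance from each detected key-point to its mapped
  landmark on whichever body is closer;
* overlap barrier: large penalty when any cross-body pair of barrier spheres
  (spheres centered on the ellipsoids with radius equal to the minor axis)
  comes closer than ``overlap_factor`` times the sum of the two radii;
* flip barrier: the same condition between each body now and the OTHER body
  in the previous frame, which pins the two identities over time.

Distances are clipped at ``clip_dist`` so distant imaging outliers contribute
a bounded amount instead of skewing the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .body_model import BodyConstants, build_skeletons_batch
from .scene_synthesis import KP_CODE, PointCloudFrame

__all__ = ["LossConfig", "CandidateSet", "pointcloud_loss", "keypoint_loss",
           "overlap_barrier", "flip_barrier", "total_loss"]


@dataclass
class LossConfig:
    clip_dist: float = 0.03          # m
    w_pointcloud: float = 1.0
    w_keypoint: float | None = None  # None -> N/M per frame
    barrier_penalty: float = 1.0e6
    overlap_factor: float = 0.8
    use_posterior_weights: bool = True
    point_chunk: int = 256           # memory cap for the m x n x P broadcast
    constants: BodyConstants = field(default_factory=BodyConstants)

    def __post_init__(self) -> None:
        if self.clip_dist <= 0:
            raise ValueError("clip_dist must be > 0")
        if not (0 < self.overlap_factor <= 1):
            raise ValueError("overlap_factor must lie in (0, 1]")


class CandidateSet:
    """A batch of K candidate poses of one body, with derived geometry."""

    def __init__(self, params: np.ndarray, constants: BodyConstants,
                 implanted: bool):
        self.params = np.atleast_2d(np.asarray(params, dtype=float))
        self.implanted = implanted
        self.constants = constants.scaled()
        self.skel = build_skeletons_batch(self.params, constants, implanted)

    def __len__(self) -> int:
        return self.params.shape[0]

    def surface_distances(self, points: np.ndarray) -> np.ndarray:
        """(K, N) distance from each point to the nearest body surface."""
        K, N = len(self), points.shape[0]
        if N == 0:
            return np.zeros((K, 0))
        d = np.full((K, N), np.inf)
        for center, Q in ((self.skel["c_hip"], self.skel["Q_hip"]),
                          (self.skel["c_nose"], self.skel["Q_nose"])):
            p = points[None, :, :] - center[:, None, :]
            qn2 = np.einsum("kni,kij,knj->kn", p, Q, p)
            r = np.linalg.norm(p, axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                di = np.abs(1.0 - 1.0 / np.sqrt(qn2)) * r
            di = np.where(qn2 <= 0, 0.0, di)
            np.minimum(d, di, out=d)
        if self.implanted:
            p = points[None, :, :] - self.skel["c_impl"][:, None, :]
            di = np.abs(np.linalg.norm(p, axis=2) - self.constants.r_impl)
            np.minimum(d, di, out=d)
        return d

    def keypoint_distances(self, frame: PointCloudFrame) -> np.ndarray:
        """(K, M) distance from each key-point to its mapped landmark.

        nose -> c_tip, tail -> c_tail, implant -> c_impl (infinite for an
        unimplanted body), ear -> head-ellipsoid surface.
        """
        K, M = len(self), frame.kp_count
        d = np.full((K, M), np.inf)
        kp = frame.keypoints
        known = set(KP_CODE.values())
        for code in np.unique(frame.kp_type):
            if int(code) not in known:
                raise ValueError(f"unknown key-point type code {code}")
        for code, landmark in ((KP_CODE["nose"], "c_tip"),
                               (KP_CODE["tail"], "c_tail")):
            sel = frame.kp_type == code
            if np.any(sel):
                diff = kp[None, sel, :] - self.skel[landmark][:, None, :]
                d[:, sel] = np.linalg.norm(diff, axis=2)
        sel = frame.kp_type == KP_CODE["implant"]
        if np.any(sel) and self.implanted:
            diff = kp[None, sel, :] - self.skel["c_impl"][:, None, :]
            d[:, sel] = np.linalg.norm(diff, axis=2)
        sel = frame.kp_type == KP_CODE["ear"]
        if np.any(sel):
            p = kp[None, sel, :] - self.skel["c_nose"][:, None, :]
            qn2 = np.einsum("kni,kij,knj->kn", p, self.skel["Q_nose"], p)
            r = np.linalg.norm(p, axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                d[:, sel] = np.abs(1.0 - 1.0 / np.sqrt(qn2)) * r
        return d

    def barrier_spheres(self) -> tuple[np.ndarray, np.ndarray]:
        """(K, S, 3) centers and (K, S) radii of the barrier spheres."""
        centers = [self.skel["c_hip"], self.skel["c_nose"]]
        radii = [self.skel["b_hip"],
                 np.full(len(self), self.constants.b_nose)]
        if self.implanted:
            centers.append(self.skel["c_impl"])
            radii.append(np.full(len(self), self.constants.r_impl))
        return np.stack(centers, 1), np.stack(radii, 1)


def _min_combine(a: np.ndarray, b: np.ndarray, w: np.ndarray,
                 chunk: int) -> np.ndarray:
    """sum_p w_p * min(a[i, p], b[j, p]) over all (i, j), chunked over p."""
    m, n = a.shape[0], b.shape[0]
    out = np.zeros((m, n))
    for lo in range(0, a.shape[1], chunk):
        hi = lo + chunk
        out += np.einsum("ijp,p->ij",
                         np.minimum(a[:, None, lo:hi], b[None, :, lo:hi]),
                         w[lo:hi])
    return out


def pointcloud_loss(frame: PointCloudFrame, set0: CandidateSet,
                    set1: CandidateSet, config: LossConfig) -> np.ndarray:
    """(m, n) weighted clipped point-cloud loss over all candidate pairings."""
    if frame.n_points == 0:
        warnings.warn("empty point cloud: point-cloud loss is 0", stacklevel=2)
        return np.zeros((len(set0), len(set1)))
    d0 = np.minimum(set0.surface_distances(frame.points), config.clip_dist)
    d1 = np.minimum(set1.surface_distances(frame.points), config.clip_dist)
    return _min_combine(d0, d1, frame.weights, config.point_chunk)


def keypoint_loss(frame: PointCloudFrame, set0: CandidateSet,
                  set1: CandidateSet, config: LossConfig) -> np.ndarray:
    """(m, n) key-point loss; each key-point is assigned to the closer body.

    The per-key-point contribution is the clipped distance to the mapped
    landmark, optionally weighted by the detector's pseudo-posterior.  Ties
    between the two bodies resolve to body 0 (index order), which cannot
    change the loss value.
    """
    if frame.kp_count == 0:
        return np.zeros((len(set0), len(set1)))
    d0 = np.minimum(set0.keypoint_distances(frame), config.clip_dist)
    d1 = np.minimum(set1.keypoint_distances(frame), config.clip_dist)
    w = frame.kp_posterior if config.use_posterior_weights \
        else np.ones(frame.kp_count)
    return _min_combine(d0, d1, w, config.point_chunk)


def _cross_overlap(c0: np.ndarray, r0: np.ndarray, c1: np.ndarray,
                   r1: np.ndarray, factor: float) -> np.ndarray:
    """(m, n) bool: any cross-body sphere pair strictly inside the limit."""
    diff = c0[:, None, :, None, :] - c1[None, :, None, :, :]
    d = np.linalg.norm(diff, axis=-1)                       # (m, n, S0, S1)
    lim = factor * (r0[:, None, :, None] + r1[None, :, None, :])
    return np.any(d < lim, axis=(2, 3))


def overlap_barrier(set0: CandidateSet, set1: CandidateSet,
                    config: LossConfig) -> np.ndarray:
    """(m, n) overlap penalties between the two candidate sets."""
    c0, r0 = set0.barrier_spheres()
    c1, r1 = set1.barrier_spheres()
    hit = _cross_overlap(c0, r0, c1, r1, config.overlap_factor)
    return np.where(hit, config.barrier_penalty, 0.0)


def flip_barrier(set0: CandidateSet, set1: CandidateSet,
                 previous: tuple[CandidateSet, CandidateSet] | None,
                 config: LossConfig) -> np.ndarray:
    """(m, n) identity-flip penalties against the previous frame's skeletons.

    Body 0 candidates are tested against the previous frame's body 1 and vice
    versa; overlap with where the OTHER animal just was marks an identity
    flip.  Zero when no previous frame is available.
    """
    if previous is None:
        return np.zeros((len(set0), len(set1)))
    prev0, prev1 = previous
    c0, r0 = set0.barrier_spheres()
    c1, r1 = set1.barrier_spheres()
    p0c, p0r = prev0.barrier_spheres()
    p1c, p1r = prev1.barrier_spheres()
    hit0 = _cross_overlap(c0, r0, p1c[:1], p1r[:1], config.overlap_factor)[:, 0]
    hit1 = _cross_overlap(c1, r1, p0c[:1], p0r[:1], config.overlap_factor)[:, 0]
    hit = hit0[:, None] | hit1[None, :]
    return np.where(hit, config.barrier_penalty, 0.0)


def total_loss(frame: PointCloudFrame, set0: CandidateSet, set1: CandidateSet,
               previous: tuple[CandidateSet, CandidateSet] | None,
               config: LossConfig) -> np.ndarray:
    """(m, n) total loss over all joint pairings of the two candidate sets."""
    w_kp = config.w_keypoint
    if w_kp is None:
        w_kp = frame.n_points / max(frame.kp_count, 1)
    loss = config.w_pointcloud * pointcloud_loss(frame, set0, set1, config)
    loss += w_kp * keypoint_loss(frame, set0, set1, config)
    loss += overlap_barrier(set0, set1, config)
    loss += flip_barrier(set0, set1, previous, config)
    return loss
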