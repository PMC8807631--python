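"""Synthetic depth-scene generator.

Stands in for the multi-camera depth rig and the key-point detection network:
produces smooth two-mouse pose sequences (with scripted close-interaction
episodes), renders weighted 3D point clouds sampled on the body-model
surfaces, places noisy typed key-points at skeleton landmarks, and round-trips
everything through the packed per-frame "jagged array" container.

Emulated features of real data: surface-point density falling off with camera
distance (points are assigned to virtual cameras with probability 1/d^2 and
weighted by the squared camera distance), camera-facing hemisphere occlusion,
Gaussian surface noise, key-point jitter and dropout.  Not emulated: sensor-
specific noise models, inter-body ray-cast occlusion, imaging artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d

from .body_model import BodyConstants, JointPose, MousePose, build_skeletons_batch

__all__ = [
    "KP_TYPES", "PointCloudFrame", "SceneConfig", "PoseSequence",
    "sample_pose_sequence", "render_frame", "render_sequence",
    "pack_frame", "unpack_frame", "write_frames", "read_frames",
    "save_scene", "load_scene",
]

# Key-point type codes, in the order the detector emits them.
KP_TYPES = ("nose", "ear", "tail", "implant")
KP_CODE = {name: i for i, name in enumerate(KP_TYPES)}


@dataclass
class PointCloudFrame:
    """One pre-processed frame: weighted cloud points plus typed key-points."""

    points: np.ndarray       # (N, 3) m
    weights: np.ndarray      # (N,) positive, squared camera distance m^2
    keypoints: np.ndarray    # (M, 3) m
    kp_posterior: np.ndarray  # (M,) in [0, 1]
    kp_type: np.ndarray      # (M,) int codes into KP_TYPES

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(-1, 3)
        self.kp_posterior = np.asarray(self.kp_posterior, dtype=float).reshape(-1)
        self.kp_type = np.asarray(self.kp_type, dtype=np.int64).reshape(-1)
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points and weights length mismatch")
        if not (self.keypoints.shape[0] == self.kp_posterior.shape[0]
                == self.kp_type.shape[0]):
            raise ValueError("key-point arrays length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if np.any((self.kp_posterior < 0) | (self.kp_posterior > 1)):
            raise ValueError("kp_posterior must lie in [0, 1]")

    @property
    def kp_count(self) -> int:
        return int(self.keypoints.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def pack_frame(frame: PointCloudFrame) -> np.ndarray:
    """Pack a frame into the single 1-D jagged record.

    Layout (in order): raveled cloud points (3N), weights (N), raveled
    key-points (3M), pseudo-posteriors (M), key-point type codes (M), and the
    key-point count (1).
    """
    return np.concatenate([
        frame.points.ravel(), frame.weights,
        frame.keypoints.ravel(), frame.kp_posterior,
        frame.kp_type.astype(float), [float(frame.kp_count)],
    ])


def unpack_frame(packed: np.ndarray, frame_index: int | None = None) -> PointCloudFrame:
    """Inverse of :func:`pack_frame`; validates the layout arithmetic."""
    packed = np.asarray(packed, dtype=float).ravel()
    where = f" (frame {frame_index})" if frame_index is not None else ""
    if packed.size < 1:
        raise ValueError(f"empty packed record{where}")
    m = packed[-1]
    if m < 0 or m != int(m):
        raise ValueError(f"corrupt key-point count{where}")
    m = int(m)
    rest = packed.size - 1 - 5 * m
    if rest < 0 or rest % 4 != 0:
        raise ValueError(f"truncated or corrupt packed record{where}")
    n = rest // 4
    pos = 0
    points = packed[pos:pos + 3 * n].reshape(n, 3); pos += 3 * n
    weights = packed[pos:pos + n]; pos += n
    keypoints = packed[pos:pos + 3 * m].reshape(m, 3); pos += 3 * m
    posterior = packed[pos:pos + m]; pos += m
    kp_type = packed[pos:pos + m].astype(np.int64)
    return PointCloudFrame(points, weights, keypoints, posterior, kp_type)


@dataclass
class SceneConfig:
    """Study conditions of the synthetic scene.

    Defaults match the desk-scale reference scene: 60 Hz, ~2000 surface points
    per frame, 1 mm surface noise, 2 mm key-point noise, 10% key-point dropout,
    four virtual cameras around a 30 cm-radius arena.
    """

    n_frames: int = 300
    frame_rate: float = 60.0
    points_per_frame: int = 2000
    kp_noise_sd: float = 0.002
    kp_dropout_prob: float = 0.10
    pc_noise_sd: float = 0.001
    camera_positions: tuple = (
        (0.55, 0.0, 0.35), (0.0, 0.55, 0.35), (-0.55, 0.0, 0.35), (0.0, -0.55, 0.35),
    )
    occlusion: bool = True
    seed: int = 0
    arena_radius: float = 0.30
    scripted: bool = True
    dynamics_pos_noise: float = 0.006   # m, band-limited hip-center jitter
    dynamics_angle_noise: float = 0.08  # rad, band-limited angle jitter
    dynamics_s_noise: float = 0.05
    noise_bandwidth_frames: float = 20.0
    ear_azimuth: float = np.deg2rad(60.0)
    ear_elevation: float = np.deg2rad(30.0)
    constants: BodyConstants = field(default_factory=BodyConstants)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not (0 <= self.kp_dropout_prob <= 1):
            raise ValueError("kp_dropout_prob must lie in [0, 1]")
        if self.arena_radius < 0.12:
            raise ValueError("arena too small for two mouse bodies")
        if len(self.camera_positions) == 0:
            raise ValueError("at least one camera required")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["constants"] = dataclasses.asdict(self.constants)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        d = json.loads(text)
        d["constants"] = BodyConstants(**d["constants"])
        d["camera_positions"] = tuple(tuple(c) for c in d["camera_positions"])
        return cls(**d)


@dataclass
class PoseSequence:
    """Ground-truth pose sequence with scripted-episode annotations."""

    params_implanted: np.ndarray  # (T, 9)
    params_partner: np.ndarray    # (T, 8)
    episodes: list = field(default_factory=list)  # dicts: kind, start, end

    def __len__(self) -> int:
        return self.params_implanted.shape[0]

    def __getitem__(self, t: int) -> JointPose:
        return JointPose(MousePose.from_array(self.params_implanted[t]),
                         MousePose.from_array(self.params_partner[t]))


# ---------------------------------------------------------------------------
# Pose choreography
# ---------------------------------------------------------------------------

def _nose_reach(bc: BodyConstants, s: float = 0.5) -> float:
    """Distance from the hip center to the nose tip along the body axis."""
    a_hip = bc.a_hip_min + (bc.a_hip_max - bc.a_hip_min) * s
    return bc.d_hip_factor * a_hip + bc.d_nose + bc.a_nose


def _keyframes(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Scripted waypoints: wander, nose-to-nose, separate, nose-to-tail, apart.

    Returns (times in [0,1], keyframes0 (K, 4), keyframes1 (K, 4), episodes);
    keyframe columns are (x, y, z, gamma).
    """
    bc = config.constants.scaled()
    reach = _nose_reach(bc)
    a_hip = bc.a_hip_min + 0.5 * (bc.a_hip_max - bc.a_hip_min)
    z0 = 0.02
    # Face-to-face with a 1 cm tip gap.
    half_nn = reach + 0.005
    # Mouse 0 nose tip 0.5 cm behind mouse 1's tail pole, both heading +x.
    hip1_nt_x = 0.06
    hip0_nt_x = hip1_nt_x - a_hip - 0.005 - reach
    times = np.array([0.00, 0.15, 0.30, 0.38, 0.52, 0.62, 0.70, 0.84, 0.92, 1.00])
    kf0 = np.array([
        [-0.16, -0.06, z0, 0.3],
        [-0.14, 0.02, z0, -0.2],
        [-0.10, 0.00, z0, 0.0],
        [-half_nn, 0.00, z0, 0.0],
        [-half_nn, 0.00, z0, 0.0],
        [-0.12, -0.08, z0, 0.2],
        [hip0_nt_x, 0.00, z0, 0.0],
        [hip0_nt_x, 0.00, z0, 0.0],
        [-0.10, -0.10, z0, -0.4],
        [-0.14, -0.04, z0, 0.1],
    ])
    kf1 = np.array([
        [0.16, 0.06, z0, np.pi + 0.2],
        [0.14, -0.02, z0, np.pi - 0.1],
        [0.10, 0.00, z0, np.pi],
        [half_nn, 0.00, z0, np.pi],
        [half_nn, 0.00, z0, np.pi],
        [0.12, 0.10, z0, np.pi / 2],
        [hip1_nt_x, 0.00, z0, 0.0],
        [hip1_nt_x, 0.00, z0, 0.0],
        [0.12, 0.08, z0, -0.5],
        [0.15, 0.02, z0, 0.0],
    ])
    episodes = [
        {"kind": "nose_nose", "start": 0.38, "end": 0.52},
        {"kind": "nose0_tail1", "start": 0.70, "end": 0.84},
    ]
    return times, kf0, kf1, episodes


def _band_limited_noise(rng: np.random.Generator, n: int, sd: float,
                        bandwidth: float) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    x = gaussian_filter1d(rng.standard_normal(n), bandwidth, mode="nearest")
    x = x - np.mean(x)
    norm = np.std(x)
    return sd * x / norm if norm > 1e-9 else np.zeros(n)


def sample_pose_sequence(config: SceneConfig) -> PoseSequence:
    """Generate a smooth, physically valid two-mouse pose sequence.

    Scripted mode drives the hip centers and headings through a choreography
    containing one nose-to-nose and one nose-to-tail episode; band-limited
    noise is added on top of every coordinate.  With scripting off the
    sequence is a band-limited random walk around a separated rest posture
    (zero noise then yields a constant sequence).
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_frames
    t = np.linspace(0.0, 1.0, T) if T > 1 else np.zeros(1)
    bc = config.constants.scaled()

    if config.scripted:
        times, kf0, kf1, eps = _keyframes(config)
        base0 = np.stack([PchipInterpolator(times, kf0[:, j])(t) for j in range(4)], 1)
        base1 = np.stack([PchipInterpolator(times, kf1[:, j])(t) for j in range(4)], 1)
        episodes = [{"kind": e["kind"],
                     "start": int(round(e["start"] * (T - 1))),
                     "end": int(round(e["end"] * (T - 1)))} for e in eps]
    else:
        base0 = np.tile([-0.12, -0.02, 0.02, 0.0], (T, 1))
        base1 = np.tile([0.12, 0.02, 0.02, np.pi], (T, 1))
        episodes = []

    bw = config.noise_bandwidth_frames

    def body_params(base: np.ndarray, implanted: bool) -> np.ndarray:
        cols = 9 if implanted else 8
        p = np.zeros((T, cols))
        for j in range(3):
            scale = config.dynamics_pos_noise * (0.3 if j == 2 else 1.0)
            p[:, j] = base[:, j] + _band_limited_noise(rng, T, scale, bw)
        p[:, 2] = np.clip(p[:, 2], 0.012, 0.08)
        p[:, 3] = _band_limited_noise(rng, T, 0.3 * config.dynamics_angle_noise, bw)
        p[:, 4] = base[:, 3] + _band_limited_noise(rng, T, config.dynamics_angle_noise, bw)
        p[:, 5] = np.clip(_band_limited_noise(rng, T, config.dynamics_angle_noise, bw),
                          -0.9 * bc.theta_max, 0.9 * bc.theta_max)
        p[:, 6] = np.clip(_band_limited_noise(rng, T, config.dynamics_angle_noise, bw),
                          -0.9 * bc.phi_max, 0.9 * bc.phi_max)
        p[:, 7] = np.clip(0.5 + _band_limited_noise(rng, T, config.dynamics_s_noise, bw),
                          0.05, 0.95)
        if implanted:
            p[:, 8] = 0.2 + _band_limited_noise(rng, T, config.dynamics_angle_noise, bw)
        return p

    p0 = body_params(base0, implanted=True)
    p1 = body_params(base1, implanted=False)
    _repair_overlaps(p0, p1, bc)

    r_max = np.max(np.linalg.norm(np.vstack([p0[:, :2], p1[:, :2]]), axis=1))
    if r_max > config.arena_radius:
        raise ValueError("choreography does not fit the arena radius")
    return PoseSequence(p0, p1, episodes)


def _body_centers(params: np.ndarray, bc: BodyConstants,
                  implanted: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame sphere centers and radii used by the overlap barrier."""
    sk = build_skeletons_batch(params, bc, implanted)
    centers = [sk["c_hip"], sk["c_nose"]]
    radii = [sk["b_hip"], np.full(len(params), bc.b_nose)]
    if implanted:
        centers.append(sk["c_impl"])
        radii.append(np.full(len(params), bc.r_impl))
    return np.stack(centers, 1), np.stack(radii, 1)  # (T, S, 3), (T, S)


def _repair_overlaps(p0: np.ndarray, p1: np.ndarray, bc: BodyConstants,
                     factor: float = 0.8, margin: float = 1.08,
                     max_iter: int = 8) -> None:
    """Push hip centers apart (in place) until no barrier sphere pair overlaps."""
    for _ in range(max_iter):
        c0, r0 = _body_centers(p0, bc, True)
        c1, r1 = _body_centers(p1, bc, False)
        d = np.linalg.norm(c0[:, :, None, :] - c1[:, None, :, :], axis=-1)
        lim = margin * factor * (r0[:, :, None] + r1[:, None, :])
        deficit = np.max(lim - d, axis=(1, 2))
        bad = deficit > 0
        if not np.any(bad):
            return
        sep = p1[bad, :2] - p0[bad, :2]
        norm = np.linalg.norm(sep, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        push = 0.5 * (deficit[bad, None] + 1e-4) * sep / norm
        p0[bad, :2] -= push
        p1[bad, :2] += push


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _sample_ellipsoid_surface(rng: np.random.Generator, n: int, center: np.ndarray,
                              R: np.ndarray, axes: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Sample n surface points and outward normals of an ellipsoid."""
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    local = u * axes  # radial map of the unit sphere onto the ellipsoid
    pts = local @ R.T + center
    # Outward normal ~ grad of the quadratic form: R diag(1/a^2) local
    nrm = (local / axes**2) @ R.T
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return pts, nrm


def _ear_offsets(bc: BodyConstants, azimuth: float,
                 elevation: float = 0.0) -> np.ndarray:
    """Two ear landmarks in the head-ellipsoid frame (origin at c_nose).

    The ears sit on the head-ellipsoid surface at +-azimuth from the nose
    axis, raised dorsally by ``elevation`` so their mean defines the head-up
    direction.
    """
    out = []
    for sign in (+1.0, -1.0):
        u = np.array([np.cos(azimuth) * np.cos(elevation),
                      sign * np.sin(azimuth) * np.cos(elevation),
                      np.sin(elevation)])
        scale = 1.0 / np.sqrt((u[0] / bc.a_nose) ** 2 + (u[1] / bc.b_nose) ** 2
                              + (u[2] / bc.b_nose) ** 2)
        out.append(scale * u)
    return np.array(out)


def ear_landmarks(skeleton_batch: dict, bc: BodyConstants,
                  azimuth: float, elevation: float = 0.0) -> np.ndarray:
    """World-frame ear landmark positions, shape (K, 2, 3)."""
    offs = _ear_offsets(bc, azimuth, elevation)  # (2, 3)
    R_wh = skeleton_batch["R_hip"] @ skeleton_batch["R_head"]
    return np.einsum("kij,ej->kei", R_wh, offs) + skeleton_batch["c_nose"][:, None, :]


def render_frame(joint: JointPose, config: SceneConfig,
                 rng: np.random.Generator | None = None) -> PointCloudFrame:
    """Render one frame: surface point cloud plus noisy typed key-points."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bc = config.constants.scaled()
    cams = np.asarray(config.camera_positions, dtype=float).reshape(-1, 3)

    surfaces = []  # (center, R, axes, share)
    for pose in joint.poses:
        sk = build_skeletons_batch(pose.to_array()[None, :], bc, pose.implanted)
        a_hip, b_hip = float(sk["a_hip"][0]), float(sk["b_hip"][0])
        surfaces.append((sk["c_hip"][0], sk["R_hip"][0],
                         np.array([a_hip, b_hip, b_hip]), 0.32))
        R_wh = (sk["R_hip"] @ sk["R_head"])[0]
        surfaces.append((sk["c_nose"][0], R_wh,
                         np.array([bc.a_nose, bc.b_nose, bc.b_nose]), 0.13))
        if pose.implanted:
            surfaces.append((sk["c_impl"][0], np.eye(3),
                             np.full(3, bc.r_impl), 0.10))

    shares = np.array([s[3] for s in surfaces])
    counts = np.round(config.points_per_frame * shares / shares.sum()).astype(int)
    pts_all, w_all = [], []
    for (center, R, axes, _), n in zip(surfaces, counts):
        if n == 0:
            continue
        # Oversample, then keep camera-visible points, density falling with
        # squared camera distance.
        pts, nrm = _sample_ellipsoid_surface(rng, 3 * n, center, R, axes)
        to_cam = cams[None, :, :] - pts[:, None, :]          # (P, C, 3)
        d2 = np.sum(to_cam**2, axis=-1)
        visible = (np.einsum("pcx,px->pc", to_cam, nrm) > 0) if config.occlusion \
            else np.ones_like(d2, dtype=bool)
        prob = np.where(visible, 1.0 / d2, 0.0)
        row_tot = prob.sum(axis=1)
        ok = row_tot > 0
        pts, prob, row_tot = pts[ok], prob[ok], row_tot[ok]
        if pts.shape[0] == 0:
            continue
        keep = np.sort(rng.permutation(pts.shape[0])[:n])
        pts, prob, row_tot = pts[keep], prob[keep], row_tot[keep]
        cum = np.cumsum(prob / row_tot[:, None], axis=1)
        cam_idx = (rng.random(pts.shape[0])[:, None] < cum).argmax(axis=1)
        if config.pc_noise_sd > 0:
            pts = pts + rng.normal(0.0, config.pc_noise_sd, pts.shape)
        w = np.sum((cams[cam_idx] - pts) ** 2, axis=1)
        pts_all.append(pts)
        w_all.append(w)

    points = np.vstack(pts_all) if pts_all else np.zeros((0, 3))
    weights = np.concatenate(w_all) if w_all else np.zeros(0)

    kp_pos, kp_type = [], []
    for pose in joint.poses:
        sk = build_skeletons_batch(pose.to_array()[None, :], bc, pose.implanted)
        kp_pos += [sk["c_tip"][0], sk["c_tail"][0]]
        kp_type += [KP_CODE["nose"], KP_CODE["tail"]]
        ears = ear_landmarks(sk, bc, config.ear_azimuth, config.ear_elevation)[0]
        kp_pos += [ears[0], ears[1]]
        kp_type += [KP_CODE["ear"], KP_CODE["ear"]]
        if pose.implanted:
            kp_pos.append(sk["c_impl"][0])
            kp_type.append(KP_CODE["implant"])
    kp_pos = np.array(kp_pos)
    kp_type = np.array(kp_type)
    kept = rng.random(len(kp_pos)) >= config.kp_dropout_prob
    kp_pos, kp_type = kp_pos[kept], kp_type[kept]
    if config.kp_noise_sd > 0 and len(kp_pos):
        kp_pos = kp_pos + rng.normal(0.0, config.kp_noise_sd, kp_pos.shape)
    posterior = rng.uniform(0.5, 1.0, len(kp_pos))
    return PointCloudFrame(points, weights, kp_pos, posterior, kp_type)


def render_sequence(seq: PoseSequence, config: SceneConfig) -> list[PointCloudFrame]:
    """Render every frame of a pose sequence with a single seeded stream."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    return [render_frame(seq[t], config, rng) for t in range(len(seq))]


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def write_frames(frames: list[PointCloudFrame], path: str | Path) -> None:
    """Write frames as packed jagged records to an HDF5 container."""
    with h5py.File(path, "w") as f:
        dt = h5py.vlen_dtype(np.float64)
        dset = f.create_dataset("jagged_frames", (len(frames),), dtype=dt)
        for i, frame in enumerate(frames):
            dset[i] = pack_frame(frame)
        f.create_dataset("n_frames", data=len(frames))


def read_frames(path: str | Path) -> list[PointCloudFrame]:
    with h5py.File(path, "r") as f:
        records = f["jagged_frames"]
        return [unpack_frame(records[i], frame_index=i) for i in range(len(records))]


def save_scene(path: str | Path, frames: list[PointCloudFrame],
               seq: PoseSequence, config: SceneConfig) -> None:
    """Write frames plus a JSON sidecar with the config and ground truth."""
    path = Path(path)
    write_frames(frames, path)
    sidecar = {
        "config": json.loads(config.to_json()),
        "episodes": seq.episodes,
        "params_implanted": seq.params_implanted.tolist(),
        "params_partner": seq.params_partner.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_scene(path: str | Path) -> tuple[list[PointCloudFrame], PoseSequence, SceneConfig]:
    path = Path(path)
    frames = read_frames(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    config = SceneConfig.from_json(json.dumps(sidecar["config"]))
    seq = PoseSequence(np.array(sidecar["params_implanted"]),
                       np.array(sidecar["params_partner"]),
                       sidecar["episodes"])
    return frames, seq, config
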