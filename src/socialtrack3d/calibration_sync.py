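"""Multi-camera geometric alignment and clock synchronization.

Pinhole depth-pixel deprojection and color projection, robust (RANSAC) sphere
fitting to partial calibration-ball surfaces, rigid alignment of per-camera
ball trajectories, arena floor/cylinder detection on merged clouds, and
blink/TTL shift-and-drift estimation with a Theil-Sen fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import theilslopes

from .body_model import rotation_aligning

__all__ = [
    "CameraCalibration", "SyncFit", "deproject_depth_pixel", "project_to_color",
    "fit_sphere_robust", "align_camera_trajectories", "detect_floor_and_cylinder",
    "sync_clocks", "simulate_pulse_train", "read_trace_csv",
]


@dataclass
class CameraCalibration:
    """Pinhole intrinsics/extrinsics of one depth+color camera pair."""

    f_depth: np.ndarray = field(default_factory=lambda: np.array([380.0, 380.0]))
    p_depth: np.ndarray = field(default_factory=lambda: np.array([160.0, 120.0]))
    f_color: np.ndarray = field(default_factory=lambda: np.array([450.0, 450.0]))
    p_color: np.ndarray = field(default_factory=lambda: np.array([160.0, 105.0]))
    d_scale: float = 0.001  # m per 16-bit depth unit
    R_d2c: np.ndarray = field(default_factory=lambda: np.eye(3))
    t_d2c: np.ndarray = field(default_factory=lambda: np.zeros(3))
    R_world: np.ndarray = field(default_factory=lambda: np.eye(3))
    t_world: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("R_d2c", "R_world"):
            R = np.asarray(getattr(self, name), dtype=float)
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
                raise ValueError(f"{name} is not orthonormal")
        if self.d_scale <= 0:
            raise ValueError("d_scale must be > 0")

    def save_json(self, path: str | Path) -> None:
        d = {k: (np.asarray(v).tolist() if not np.isscalar(v) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load_json(cls, path: str | Path) -> "CameraCalibration":
        d = json.loads(Path(path).read_text())
        return cls(**{k: (np.array(v) if isinstance(v, list) else v)
                      for k, v in d.items()})


def deproject_depth_pixel(i: np.ndarray, j: np.ndarray, d: np.ndarray,
                          calib: CameraCalibration) -> np.ndarray:
    """3D point(s) in the depth-camera frame from pixel indices and raw depth.

    ``z = d * d_scale``; ``x = (j - p_x) z / f_x``; ``y = (i - p_y) z / f_y``.
    Zero depth marks an invalid pixel and deprojects to NaN.
    """
    i, j, d = (np.asarray(v, dtype=float) for v in (i, j, d))
    z = d * calib.d_scale
    x = (j - calib.p_depth[0]) * z / calib.f_depth[0]
    y = (i - calib.p_depth[1]) * z / calib.f_depth[1]
    xyz = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
    invalid = np.broadcast_to(d == 0, xyz.shape[:-1])
    xyz = np.where(invalid[..., None], np.nan, xyz)
    return xyz


def project_to_color(xyz: np.ndarray, calib: CameraCalibration) -> np.ndarray:
    """Color-pixel indices (i_c, j_c) of 3D depth-frame points, rounded."""
    xyz = np.asarray(xyz, dtype=float)
    cam = xyz @ calib.R_d2c.T + calib.t_d2c
    i_c = calib.f_color[1] * cam[..., 1] / cam[..., 2] + calib.p_color[1]
    j_c = calib.f_color[0] * cam[..., 0] / cam[..., 2] + calib.p_color[0]
    return np.rint(np.stack([i_c, j_c], axis=-1)).astype(int)


# ---------------------------------------------------------------------------
# Sphere fitting
# ---------------------------------------------------------------------------

def _sphere_center_lsq(points: np.ndarray) -> np.ndarray:
    """Algebraic (free-radius) sphere fit; returns the center."""
    A = np.column_stack([2 * points, np.ones(len(points))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def fit_sphere_robust(points: np.ndarray, radius: float = 0.040,
                      inlier_threshold: float = 0.002, n_iters: int = 200,
                      min_inlier_fraction: float = 0.3,
                      seed: int = 0) -> np.ndarray:
    """RANSAC center of a fixed-radius sphere from a (partial) surface.

    Minimal samples of 4 points give an algebraic candidate center; consensus
    counts points whose radial residual is below ``inlier_threshold``; the
    final center is refined on the inliers with the radius held fixed.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 points to fit a sphere")
    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    for _ in range(n_iters):
        sample = points[rng.choice(len(points), 4, replace=False)]
        try:
            center = _sphere_center_lsq(sample)
        except np.linalg.LinAlgError:
            continue
        resid = np.abs(np.linalg.norm(points - center, axis=1) - radius)
        inliers = resid < inlier_threshold
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < min_inlier_fraction * len(points):
        raise RuntimeError("sphere fit failed: consensus below minimum inlier fraction")
    inlier_pts = points[best_inliers]
    x0 = _sphere_center_lsq(inlier_pts)
    fit = least_squares(
        lambda c: np.linalg.norm(inlier_pts - c, axis=1) - radius, x0)
    return fit.x


# ---------------------------------------------------------------------------
# Rigid trajectory alignment
# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal-Procrustes rigid transform mapping src onto dst."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return R, mu_d - R @ mu_s


def align_camera_trajectories(trajs: list[np.ndarray], reference_cam: int = 0,
                              inlier_threshold: float = 0.005,
                              n_iters: int = 200, seed: int = 0
                              ) -> tuple[list[tuple[np.ndarray, np.ndarray]],
                                         list[np.ndarray]]:
    """Robust rigid transforms bringing each camera trajectory onto the reference.

    RANSAC over frame correspondences with an orthogonal-Procrustes refit on
    the consensus set makes the estimate insensitive to segments where one
    camera lost the calibration ball.  Returns per-camera (R, t) with the
    reference mapped by the identity, and per-camera per-frame residuals.
    """
    ref = np.asarray(trajs[reference_cam], dtype=float)
    rng = np.random.default_rng(seed)
    transforms, residuals = [], []
    for c, traj in enumerate(trajs):
        traj = np.asarray(traj, dtype=float)
        if c == reference_cam:
            transforms.append((np.eye(3), np.zeros(3)))
            residuals.append(np.zeros(len(traj)))
            continue
        valid = np.all(np.isfinite(traj), axis=1) & np.all(np.isfinite(ref), axis=1)
        src, dst = traj[valid], ref[valid]
        if len(src) < 3:
            raise ValueError("fewer than 3 common points for alignment")
        if np.linalg.matrix_rank(src - src.mean(0), tol=1e-10) < 2:
            raise ValueError("degenerate (collinear) trajectory")
        best_inliers = None
        for _ in range(n_iters):
            pick = rng.choice(len(src), 4, replace=False)
            R, t = _kabsch(src[pick], dst[pick])
            resid = np.linalg.norm(src @ R.T + t - dst, axis=1)
            inliers = resid < inlier_threshold
            if best_inliers is None or inliers.sum() > best_inliers.sum():
                best_inliers = inliers
        if best_inliers.sum() < 3:
            raise RuntimeError("rigid alignment failed: too few inliers")
        R, t = _kabsch(src[best_inliers], dst[best_inliers])
        transforms.append((R, t))
        resid_full = np.full(len(traj), np.nan)
        resid_full[valid] = np.linalg.norm(src @ R.T + t - dst, axis=1)
        residuals.append(resid_full)
    return transforms, residuals


# ---------------------------------------------------------------------------
# Arena detection
# ---------------------------------------------------------------------------

def detect_floor_and_cylinder(cloud: np.ndarray, plane_threshold: float = 0.004,
                              n_iters: int = 300, min_plane_fraction: float = 0.2,
                              wall_band: float = 0.01, seed: int = 0):
    """Detect the arena floor plane and the acrylic cylinder wall.

    Returns ``(plane, R, (cyl_center_xy, cyl_radius), inside_mask)`` where
    ``plane = (normal, offset)`` with ``normal . p = offset``, ``R`` rotates
    the floor into the xy-plane (z = 0), and the mask keeps points above the
    floor and strictly inside the cylinder (the animal surfaces).
    """
    cloud = np.asarray(cloud, dtype=float)
    if len(cloud) < 10:
        raise ValueError("cloud too small for arena detection")
    rng = np.random.default_rng(seed)
    best_inliers = None
    best_plane = None
    for _ in range(n_iters):
        p = cloud[rng.choice(len(cloud), 3, replace=False)]
        n = np.cross(p[1] - p[0], p[2] - p[0])
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        dist = np.abs((cloud - p[0]) @ n)
        inliers = dist < plane_threshold
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers, best_plane = inliers, (n, float(n @ p[0]))
    if best_plane is None or best_inliers.sum() < min_plane_fraction * len(cloud):
        raise RuntimeError("no dominant plane found")
    # Least-squares plane refit on inliers.
    pts = cloud[best_inliers]
    centroid = pts.mean(0)
    _, _, Vt = np.linalg.svd(pts - centroid)
    normal = Vt[2]
    if normal[2] < 0:
        normal = -normal
    offset = float(normal @ centroid)
    R = rotation_aligning(normal, np.array([0.0, 0.0, 1.0]))
    rotated = cloud @ R.T
    floor_z = float(np.median(rotated[best_inliers, 2]))
    above = rotated[:, 2] > floor_z + plane_threshold

    # Cylinder: RANSAC circle fit in the xy-plane of the non-floor points.
    xy = rotated[above, :2]
    best_circ, best_count = None, -1
    for _ in range(n_iters):
        pick = xy[rng.choice(len(xy), 3, replace=False)]
        A = np.column_stack([2 * pick, np.ones(3)])
        b = np.sum(pick**2, axis=1)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        center = sol[:2]
        radius = np.sqrt(sol[2] + center @ center)
        resid = np.abs(np.linalg.norm(xy - center, axis=1) - radius)
        count = int((resid < wall_band).sum())
        if count > best_count:
            best_count, best_circ = count, (center, radius)
    cyl_center, cyl_radius = best_circ
    inside = above & (np.linalg.norm(rotated[:, :2] - cyl_center, axis=1)
                      < cyl_radius - wall_band)
    return (normal, offset), R, (cyl_center, float(cyl_radius)), inside


# ---------------------------------------------------------------------------
# Clock synchronization
# ---------------------------------------------------------------------------

@dataclass
class SyncFit:
    shift: float          # s: ttl_time ~ shift + (1 + drift) * blink_time
    drift: float          # s per s
    residuals: np.ndarray  # per paired event, s


def _rising_edges(trace: np.ndarray, rate: float) -> np.ndarray:
    trace = np.asarray(trace) > 0.5
    idx = np.flatnonzero(~trace[:-1] & trace[1:]) + 1
    return idx / rate


def _nearest(sorted_ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Index of the nearest element of sorted_ref for each query value."""
    pos = np.searchsorted(sorted_ref, query)
    pos = np.clip(pos, 1, len(sorted_ref) - 1)
    left = sorted_ref[pos - 1]
    right = sorted_ref[pos]
    return np.where(query - left <= right - query, pos - 1, pos)


def sync_clocks(led_trace: np.ndarray, ttl_events: np.ndarray,
                led_rate: float = 60.0, coarse_step: float = 0.010,
                search_window: float = 5.0, zscore_cutoff: float = 2.0,
                min_events: int = 10, max_regression_points: int = 6000,
                seed: int = 0) -> SyncFit:
    """Estimate the clock shift and drift between camera blinks and TTL flips.

    Coarse alignment by the first event, refinement by cross-correlating the
    event trains in 10 ms steps, pairing each blink with the nearest TTL flip
    (blinks with a paired time difference of |z| >= 2 are discarded as missed
    by the camera), and a final Theil-Sen robust regression of the pair
    differences on blink time gives shift and drift.  Very long recordings
    are decimated to ``max_regression_points`` pairs before the Theil-Sen
    step, which is quadratic in the pair count.
    """
    blinks = _rising_edges(led_trace, led_rate)
    ttl = np.sort(np.asarray(ttl_events, dtype=float))
    if len(blinks) == 0 or len(ttl) == 0:
        raise ValueError("no events to synchronize")
    coarse = ttl[0] - blinks[0]
    # Cross-correlation refinement on a coarse_step grid.
    lags = np.arange(-search_window, search_window + coarse_step, coarse_step)
    scores = np.empty(len(lags))
    for k, lag in enumerate(lags):
        shifted = blinks + coarse + lag
        d = np.abs(ttl[_nearest(ttl, shifted)] - shifted)
        scores[k] = np.sum(d < coarse_step)
    shift0 = coarse + lags[np.argmax(scores)]

    # Pair every TTL flip with the closest detected blink.  When the camera
    # missed a blink the nearest-blink pairing is off by a whole pulse gap,
    # which the z-score cutoff on the pair differences removes.
    shifted = blinks + shift0
    nearest = _nearest(shifted, ttl)
    diffs = ttl - shifted[nearest]
    z = (diffs - np.mean(diffs)) / max(np.std(diffs), 1e-12)
    keep = np.abs(z) < zscore_cutoff
    if keep.sum() < min_events:
        raise ValueError(f"fewer than {min_events} paired events after outlier rejection")
    x = blinks[nearest[keep]]
    y = ttl[keep] - blinks[nearest[keep]]
    if len(x) > max_regression_points:
        sel = np.sort(np.random.default_rng(seed).choice(
            len(x), max_regression_points, replace=False))
        x, y = x[sel], y[sel]
    drift, shift, *_ = theilslopes(y, x)
    residuals = y - (shift + drift * x)
    return SyncFit(shift=float(shift), drift=float(drift), residuals=residuals)


def simulate_pulse_train(duration: float, rng: np.random.Generator,
                         pulse_len: float = 0.150,
                         gap_range: tuple[float, float] = (0.150, 0.350)
                         ) -> np.ndarray:
    """Event (pulse onset) times of the calibration LED: 150 ms pulses with
    uniform 150-350 ms gaps."""
    times, t = [], 0.0
    while t < duration:
        times.append(t)
        t += pulse_len + rng.uniform(*gap_range)
    return np.array(times)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time, value) trace from plain CSV."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1]
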