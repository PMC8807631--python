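"""Post-hoc state-space smoothing of raw tracks.

The particle-filter fit of each frame is noisy, and the map from pose
parameters to 3D space is nonlinear, so smoothing happens in landmark space:
each skeleton landmark trajectory is filtered with a 3D constant-acceleration
Kalman filter and fixed-lag Rauch-Tung-Striebel smoothing; the spine stretch
is filtered with a 1D position+velocity model; ellipsoid rotations are
recomputed from the smoothed landmark vectors, converted to unit quaternions,
and averaged inside a boxcar window via the principal eigenvector of the
quaternion outer-product matrix; finally the nose tip and tail pole are
recomputed from the smoothed centers, rotations, and spine stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .body_model import BodyConstants, build_skeletons_batch
from .tracker import RawTrack

__all__ = ["KalmanConfig", "SmoothedTrack", "kalman_rts_3d", "smooth_spine",
           "smooth_rotations", "rebuild_skeletons"]


@dataclass
class KalmanConfig:
    dt: float = 1.0 / 60.0
    sigma_measurement: float = 0.015        # m; landmark position noise
    sigma_measurement_impl: float = 0.02    # m; the implant center is noisier
    sigma_process: float = 0.01             # m
    sigma_cov2: float = 0.0011              # m^2; initial covariance fill
    rts_lag: int = 16                       # frames
    spine_sigma_measurement: float = 0.3
    spine_sigma_process: float = 0.05
    spine_sigma_cov2: float = 0.0011
    quat_boxcar: int = 10                   # frames

    def __post_init__(self) -> None:
        if self.dt <= 0 or min(self.sigma_measurement, self.sigma_process,
                               self.sigma_cov2) <= 0:
            raise ValueError("dt and all sigmas must be > 0")

    @classmethod
    def for_synthetic_tracker(cls, **overrides) -> "KalmanConfig":
        """Noise scales matched to the synthetic-scene particle-filter fits.

        The default sigmas describe a depth-sensor pipeline whose raw
        per-frame estimates jitter by 1-2 cm.  The synthetic tracker is much
        less noisy (millimeter jitter), and freely behaving mice accelerate
        at ~1 m/s^2, so smoothing synthetic tracks uses a measurement noise
        matched to the measured fit jitter and a process noise matched to
        body-scale accelerations; otherwise the filter over-smooths real
        motion into corner-cutting distortion.
        """
        base = dict(sigma_measurement=0.003, sigma_measurement_impl=0.004,
                    sigma_process=1.0)
        base.update(overrides)
        return cls(**base)


def _dwn_q(dt: float, order: int) -> np.ndarray:
    """Discrete white-noise process covariance block (unit variance)."""
    if order == 3:
        return np.array([[dt**4 / 4, dt**3 / 2, dt**2 / 2],
                         [dt**3 / 2, dt**2, dt],
                         [dt**2 / 2, dt, 1.0]])
    return np.array([[dt**4 / 4, dt**3 / 2],
                     [dt**3 / 2, dt**2]])


def _kalman_fixed_lag(z: np.ndarray, F: np.ndarray, H: np.ndarray,
                      P0: np.ndarray, R: np.ndarray, Q: np.ndarray,
                      lag: int) -> np.ndarray:
    """Generic linear Kalman forward pass + fixed-lag RTS smoothing.

    For each frame t the filter is run to min(t + lag, T - 1) and the RTS
    recursion is carried back to t, so the smoothed estimate uses ``lag``
    frames of future context.
    """
    T, dim = z.shape[0], F.shape[0]
    if not np.all(np.isfinite(z)):
        bad = np.flatnonzero(~np.all(np.isfinite(z.reshape(T, -1)), axis=1))
        raise ValueError(f"non-finite input at frames {bad[:10].tolist()}")
    x_f = np.zeros((T, dim))
    P_f = np.zeros((T, dim, dim))
    x_p = np.zeros((T, dim))
    P_p = np.zeros((T, dim, dim))
    m = H.shape[0]
    # Initialize position states at the first measurement.
    x = H.T @ np.atleast_1d(z[0])
    P = P0.copy()
    for t in range(T):
        if t > 0:
            x = F @ x
            P = F @ P @ F.T + Q
        x_p[t], P_p[t] = x, P
        zt = np.atleast_1d(z[t])
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (zt - H @ x)
        P = (np.eye(dim) - K @ H) @ P
        x_f[t], P_f[t] = x, P
    out = np.zeros((T, m))
    for t in range(T):
        k = min(t + lag, T - 1)
        xs, Ps = x_f[k], P_f[k]
        for j in range(k - 1, t - 1, -1):
            C = P_f[j] @ F.T @ np.linalg.inv(P_p[j + 1])
            xs = x_f[j] + C @ (xs - x_p[j + 1])
            Ps = P_f[j] + C @ (Ps - P_p[j + 1]) @ C.T
        out[t] = H @ xs
    return out


def kalman_rts_3d(positions: np.ndarray, config: KalmanConfig,
                  sigma_measurement: float | None = None) -> np.ndarray:
    """Smooth a T x 3 trajectory with the constant-acceleration model.

    State is (p, v, a) per axis (9 states); measurements are the three
    positions; process noise follows the discrete constant-white-noise model.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] < 2:
        raise ValueError("positions must be (T >= 2, 3)")
    sm = sigma_measurement if sigma_measurement is not None \
        else config.sigma_measurement
    dt = config.dt
    Fb = np.array([[1.0, dt, dt**2 / 2], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    F = np.kron(np.eye(3), Fb)
    H = np.zeros((3, 9))
    H[0, 0] = H[1, 3] = H[2, 6] = 1.0
    P0 = np.eye(9) * config.sigma_cov2
    R = np.eye(3) * sm**2
    Q = np.kron(np.eye(3), _dwn_q(dt, 3)) * config.sigma_process**2
    return _kalman_fixed_lag(positions, F, H, P0, R, Q, config.rts_lag)


def smooth_spine(s_series: np.ndarray, config: KalmanConfig) -> np.ndarray:
    """Smooth the spine-stretch series with a 1D position+velocity model."""
    s = np.asarray(s_series, dtype=float).reshape(-1, 1)
    if s.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    dt = config.dt
    F = np.array([[1.0, dt], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    P0 = np.eye(2) * config.spine_sigma_cov2
    R = np.array([[config.spine_sigma_measurement**2]])
    Q = _dwn_q(dt, 2) * config.spine_sigma_process**2
    out = _kalman_fixed_lag(s, F, H, P0, R, Q, config.rts_lag)
    return np.clip(out[:, 0], 0.0, 1.0)


def smooth_rotations(quaternions: np.ndarray, window: int = 10) -> np.ndarray:
    """Boxcar-average unit quaternions via the principal eigenvector.

    Each output quaternion is the dominant eigenvector of the accumulation
    matrix sum_i q_i q_i^T over the window (shrunk at the sequence edges).
    Quaternions are sign-aligned to their predecessor first, so q and -q
    average identically.
    """
    q = np.asarray(quaternions, dtype=float).copy()
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError("quaternions must be (T, 4)")
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero quaternion in input")
    q /= norms[:, None]
    for t in range(1, len(q)):
        if q[t] @ q[t - 1] < 0:
            q[t] = -q[t]
    half = window // 2
    out = np.empty_like(q)
    for t in range(len(q)):
        lo, hi = max(0, t - half), min(len(q), t + half + 1)
        M = q[lo:hi].T @ q[lo:hi]
        vals, vecs = np.linalg.eigh(M)
        avg = vecs[:, -1]
        if avg @ q[t] < 0:
            avg = -avg
        out[t] = avg / np.linalg.norm(avg)
    return out


@dataclass
class SmoothedTrack:
    """Smoothed per-frame skeletons of both animals.

    ``landmarks0``/``landmarks1`` map landmark names to (T, 3) arrays;
    quaternions give the smoothed hip and head rotations; ``s`` the smoothed
    spine stretch of each body.
    """

    landmarks0: dict
    landmarks1: dict
    quat_hip: tuple[np.ndarray, np.ndarray]
    quat_head: tuple[np.ndarray, np.ndarray]
    s: tuple[np.ndarray, np.ndarray]
    psi0: np.ndarray
    constants: BodyConstants = field(default_factory=BodyConstants)

    def __len__(self) -> int:
        return self.landmarks0["c_hip"].shape[0]

    def landmarks(self, body: int) -> dict:
        return self.landmarks0 if body == 0 else self.landmarks1

    def hip_axis(self, body: int) -> np.ndarray:
        """Unit forward axis of the hip ellipsoid, (T, 3)."""
        lm = self.landmarks(body)
        v = lm["c_mid"] - lm["c_hip"]
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def head_axis(self, body: int) -> np.ndarray:
        lm = self.landmarks(body)
        v = lm["c_nose"] - lm["c_mid"]
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def export_csv(self, path: str | Path) -> None:
        rows = ["frame,body,landmark,x,y,z"]
        for body, lm in ((0, self.landmarks0), (1, self.landmarks1)):
            for name, arr in lm.items():
                for t in range(arr.shape[0]):
                    rows.append(f"{t},{body},{name},"
                                f"{arr[t, 0]:.6f},{arr[t, 1]:.6f},{arr[t, 2]:.6f}")
        Path(path).write_text("\n".join(rows) + "\n")


def _interpolate_flagged(arr: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    """Linear interpolation across flagged frames (per column)."""
    if not np.any(flagged):
        return arr
    out = arr.copy()
    good = ~flagged
    if not np.any(good):
        return out
    idx = np.arange(arr.shape[0])
    for c in range(arr.shape[1]):
        out[flagged, c] = np.interp(idx[flagged], idx[good], arr[good, c])
    return out


def _axis_to_quat(axes: np.ndarray) -> np.ndarray:
    """Quaternion of the roll-free rotation taking e_x onto each unit axis."""
    T = axes.shape[0]
    quats = np.empty((T, 4))
    e_x = np.array([1.0, 0.0, 0.0])
    for t in range(T):
        v = np.cross(e_x, axes[t])
        c = float(e_x @ axes[t])
        if c < -1 + 1e-12:
            quats[t] = [0.0, 0.0, 1.0, 0.0]  # 180 deg about z, (x, y, z, w)
        else:
            w = np.sqrt((1 + c) / 2)
            quats[t] = [*(v / (2 * w)), w]
    return quats


def rebuild_skeletons(raw: RawTrack, config: KalmanConfig | None = None,
                      constants: BodyConstants | None = None) -> SmoothedTrack:
    """Smooth a raw track and rebuild consistent skeletons.

    Flagged frames are linearly interpolated in landmark space before
    filtering.  Hip and head rotations are recomputed from the smoothed
    c_hip -> c_mid and c_mid -> c_nose vectors, quaternion-averaged, and the
    nose tip / tail pole are rebuilt from the smoothed geometry so the
    skeleton distance invariants hold exactly.
    """
    config = config or KalmanConfig()
    constants = (constants or BodyConstants()).scaled()
    T = len(raw)
    if T == 0:
        raise ValueError("empty track")
    flagged = np.zeros(T, dtype=bool)
    for fr in raw.flagged_frames():
        flagged[fr] = True
    if np.all(flagged):
        flagged[:] = False

    out_landmarks = []
    out_qhip, out_qhead, out_s = [], [], []
    for body, params, implanted in ((0, raw.params_implanted, True),
                                    (1, raw.params_partner, False)):
        # Flagged frames may hold arbitrary (even non-finite) fit results;
        # replace them with the nearest clean frame before skeletonization —
        # they are bridged by landmark-space interpolation below anyway.
        params = params.copy()
        bad = flagged | ~np.all(np.isfinite(params), axis=1)
        if np.any(bad) and not np.all(bad):
            good_idx = np.flatnonzero(~bad)
            nearest = good_idx[np.searchsorted(
                good_idx, np.clip(np.flatnonzero(bad), good_idx[0], good_idx[-1]))]
            params[bad] = params[nearest]
        params[:, 7] = np.clip(params[:, 7], 0.0, 1.0)
        sk = build_skeletons_batch(params, constants, implanted)
        names = ["c_hip", "c_mid", "c_nose"] + (["c_impl"] if implanted else [])
        smoothed = {}
        for name in names:
            traj = _interpolate_flagged(sk[name], flagged)
            sigma = config.sigma_measurement_impl if name == "c_impl" else None
            smoothed[name] = kalman_rts_3d(traj, config, sigma)
        s_raw = _interpolate_flagged(params[:, 7:8], flagged)[:, 0]
        s_smooth = smooth_spine(s_raw, config)

        hip_axis = smoothed["c_mid"] - smoothed["c_hip"]
        hip_axis /= np.linalg.norm(hip_axis, axis=1, keepdims=True)
        head_axis = smoothed["c_nose"] - smoothed["c_mid"]
        head_axis /= np.linalg.norm(head_axis, axis=1, keepdims=True)
        q_hip = smooth_rotations(_axis_to_quat(hip_axis), config.quat_boxcar)
        q_head = smooth_rotations(_axis_to_quat(head_axis), config.quat_boxcar)
        hip_dir = Rotation.from_quat(q_hip).apply(np.array([1.0, 0.0, 0.0]))
        head_dir = Rotation.from_quat(q_head).apply(np.array([1.0, 0.0, 0.0]))

        a_hip = constants.a_hip_min + (constants.a_hip_max - constants.a_hip_min) * s_smooth
        d_hip = constants.d_hip_factor * a_hip
        c_hip = smoothed["c_hip"]
        c_mid = c_hip + d_hip[:, None] * hip_dir
        c_nose = c_mid + constants.d_nose * head_dir
        c_tip = c_mid + (constants.d_nose + constants.a_nose) * head_dir
        c_tail = c_hip - a_hip[:, None] * hip_dir
        lm = {"c_hip": c_hip, "c_mid": c_mid, "c_nose": c_nose,
              "c_tip": c_tip, "c_tail": c_tail}
        if implanted:
            lm["c_impl"] = smoothed["c_impl"]
        out_landmarks.append(lm)
        out_qhip.append(q_hip)
        out_qhead.append(q_head)
        out_s.append(s_smooth)

    psi0 = gaussian_filter1d(
        _interpolate_flagged(np.unwrap(raw.params_implanted[:, 8])[:, None],
                             flagged)[:, 0], 3.0, mode="nearest")
    return SmoothedTrack(out_landmarks[0], out_landmarks[1],
                         (out_qhip[0], out_qhip[1]),
                         (out_qhead[0], out_qhead[1]),
                         (out_s[0], out_s[1]), psi0, constants)
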