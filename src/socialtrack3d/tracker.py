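"""Frame-sequential joint-pose estimation.

Two-layer tracking: within a frame, an annealed particle filter minimizes the
joint loss — each body proposes ``n_particles`` candidates by quasi-random
(scrambled Sobol) perturbation, the loss of all m x n joint pairings is
evaluated at once, and the best k pairings are kept by top-k resampling
(duplicates of a row or column are allowed, so the two body subspaces can
collapse at different rates).  Between frames, a recursive-least-squares
filter bank trained on the preceding frames proposes the next hip-center
positions; the angular and stretch coordinates are carried over.

Tracking is initialized from the first frame where the key-points of the two
animals separate into two clusters at least ``init_min_separation`` apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.stats import qmc
from sklearn.cluster import KMeans

from .body_model import BodyConstants, build_skeletons_batch
from .fit_loss import CandidateSet, LossConfig, total_loss
from .scene_synthesis import KP_CODE, PointCloudFrame

__all__ = ["TrackerConfig", "RawTrack", "RLSFilterBank", "find_init_frame",
           "propose_particles", "topk_resample", "fit_frame", "track_sequence"]

# Per-dimension particle perturbation scales for a 9-parameter pose:
# (x, y, z, beta, gamma, theta, phi, s, psi)
_DEFAULT_SCALES = np.array([0.01, 0.01, 0.01, 0.3, 0.3, 0.3, 0.3, 0.1, 0.3])


@dataclass
class TrackerConfig:
    n_particles: int = 200
    n_anneal_iters: int = 5
    anneal_factor: float = 0.5
    init_scales: np.ndarray = field(default_factory=lambda: _DEFAULT_SCALES.copy())
    rls_embedding: int = 5
    rls_mu: float = 0.99
    rls_eps: float = 0.1
    rls_warmup_frames: int = 150
    init_min_separation: float = 0.05
    speed_cap: float = 1.5        # m/s; above documented mouse locomotion
    flag_mad_mult: float = 5.0
    flag_window: int = 121
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not (0 < self.anneal_factor < 1):
            raise ValueError("anneal_factor must lie in (0, 1)")
        self.init_scales = np.asarray(self.init_scales, dtype=float)


@dataclass
class RawTrack:
    """Per-frame fitted joint poses with losses and anomaly flags."""

    params_implanted: np.ndarray          # (T, 9)
    params_partner: np.ndarray            # (T, 8)
    losses: np.ndarray                    # (T,)
    flags: list = field(default_factory=list)   # (frame, reason) tuples
    diagnostics: list = field(default_factory=list)  # per-frame loss-per-iter
    init_frame: int = 0

    def __len__(self) -> int:
        return self.params_implanted.shape[0]

    def flagged_frames(self) -> set[int]:
        return {f for f, _ in self.flags}

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("params_implanted", data=self.params_implanted)
            f.create_dataset("params_partner", data=self.params_partner)
            f.create_dataset("losses", data=self.losses)
            f.create_dataset("init_frame", data=self.init_frame)
            if self.flags:
                frames = np.array([fr for fr, _ in self.flags])
                reasons = np.array([r.encode() for _, r in self.flags])
                f.create_dataset("flag_frames", data=frames)
                f.create_dataset("flag_reasons", data=reasons)

    @classmethod
    def load(cls, path: str | Path) -> "RawTrack":
        with h5py.File(path, "r") as f:
            flags = []
            if "flag_frames" in f:
                flags = [(int(fr), r.decode()) for fr, r in
                         zip(f["flag_frames"][:], f["flag_reasons"][:])]
            return cls(f["params_implanted"][:], f["params_partner"][:],
                       f["losses"][:], flags, [], int(f["init_frame"][()]))

    def export_flags_csv(self, path: str | Path) -> None:
        lines = ["frame,reason"] + [f"{fr},{r}" for fr, r in self.flags]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _init_pose_from_cluster(kp: np.ndarray, types: np.ndarray,
                            constants: BodyConstants,
                            implanted: bool) -> np.ndarray | None:
    """Estimate a starting pose vector from one animal's key-points."""
    bc = constants.scaled()
    noses = kp[types == KP_CODE["nose"]]
    tails = kp[types == KP_CODE["tail"]]
    if len(noses) == 0 or len(tails) == 0:
        return None
    nose, tail = noses.mean(0), tails.mean(0)
    axis = nose - tail
    horiz = np.linalg.norm(axis[:2])
    if horiz < 1e-6:
        return None
    gamma = np.arctan2(axis[1], axis[0])
    a_hip = bc.a_hip_min + 0.5 * (bc.a_hip_max - bc.a_hip_min)
    direction = np.array([np.cos(gamma), np.sin(gamma), 0.0])
    c_hip = tail + a_hip * direction
    c_hip[2] = max(c_hip[2], 0.012)
    params = np.array([*c_hip, 0.0, gamma, 0.0, 0.0, 0.5])
    if not implanted:
        return params
    psi = 0.0
    impls = kp[types == KP_CODE["implant"]]
    if len(impls) > 0:
        # Recover psi from the implant offset in the head frame.
        sk = build_skeletons_batch(np.append(params, 0.0)[None, :], bc, True)
        R_total = (sk["R_hip"] @ sk["R_head"])[0]
        local = R_total.T @ (impls.mean(0) - sk["c_mid"][0])
        if np.hypot(local[1], local[2]) > 1e-9:
            psi = float(np.arctan2(local[2], local[1]))
    return np.append(params, psi)


def find_init_frame(frames: list[PointCloudFrame], config: TrackerConfig,
                    constants: BodyConstants | None = None
                    ) -> tuple[int, np.ndarray, np.ndarray]:
    """Scan forward for the first frame with two well-separated animals.

    Key-point positions are split into two clusters; the frame is accepted
    when the inter-cluster centroid distance reaches
    ``config.init_min_separation``.  Returns (frame index, 9-parameter pose of
    the implanted animal, 8-parameter pose of the partner).
    """
    constants = constants or BodyConstants()
    for t, frame in enumerate(frames):
        if frame.kp_count < 4:
            continue
        km = KMeans(n_clusters=2, n_init=3,
                    random_state=config.seed).fit(frame.keypoints)
        centers = km.cluster_centers_
        if np.linalg.norm(centers[0] - centers[1]) < config.init_min_separation:
            continue
        labels = km.labels_
        # The cluster holding implant key-points is the implanted animal.
        impl_mask = frame.kp_type == KP_CODE["implant"]
        if np.any(impl_mask):
            impl_cluster = int(np.bincount(labels[impl_mask]).argmax())
        else:
            impl_cluster = 0
        p_impl = _init_pose_from_cluster(
            frame.keypoints[labels == impl_cluster],
            frame.kp_type[labels == impl_cluster], constants, True)
        p_part = _init_pose_from_cluster(
            frame.keypoints[labels != impl_cluster],
            frame.kp_type[labels != impl_cluster], constants, False)
        if p_impl is None or p_part is None:
            continue
        return t, p_impl, p_part
    raise ValueError("no frame with two separated animals found")


# ---------------------------------------------------------------------------
# Particle proposal and resampling
# ---------------------------------------------------------------------------

def _clamp_pose_params(params: np.ndarray, constants: BodyConstants) -> np.ndarray:
    """Enforce pose invariants: clamp s and the neck cone, wrap free angles."""
    bc = constants.scaled()
    params = np.array(params, dtype=float)
    for j in (3, 4):  # beta, gamma
        params[:, j] = np.mod(params[:, j] + np.pi, 2 * np.pi) - np.pi
    params[:, 5] = np.clip(params[:, 5], -bc.theta_max, bc.theta_max)
    params[:, 6] = np.clip(params[:, 6], -bc.phi_max, bc.phi_max)
    params[:, 7] = np.clip(params[:, 7], 0.0, 1.0)
    if params.shape[1] == 9:
        params[:, 8] = np.mod(params[:, 8] + np.pi, 2 * np.pi) - np.pi
    return params


def propose_particles(center: np.ndarray, scales: np.ndarray, n: int,
                      rng: np.random.Generator,
                      constants: BodyConstants | None = None) -> np.ndarray:
    """n quasi-random perturbations of a pose; particle 0 is the center.

    Perturbations come from a scrambled Sobol low-discrepancy sequence,
    mapped to [-scale, +scale] per dimension.
    """
    center = np.asarray(center, dtype=float).ravel()
    d = center.size
    scales = np.asarray(scales, dtype=float)[:d]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Sobol balance warning for n != 2^k
        engine = qmc.Sobol(d=d, scramble=True,
                           seed=int(rng.integers(0, 2**31 - 1)))
        u = engine.random(n)
    particles = center[None, :] + (2.0 * u - 1.0) * scales[None, :]
    particles[0] = center
    return _clamp_pose_params(particles, constants or BodyConstants())


def topk_resample(loss_matrix: np.ndarray, k: int) -> np.ndarray:
    """Index pairs of the k smallest entries, via partial selection.

    No full sort of the matrix is performed; ties at the k-th value break
    deterministically by flattened index order.  Returns (k, 2) int array of
    (row, col) pairs ordered by increasing loss.
    """
    flat = loss_matrix.ravel()
    if k > flat.size:
        raise ValueError("k exceeds the number of joint pairings")
    if k == flat.size:
        idx = np.lexsort((np.arange(flat.size), flat))
    else:
        part = np.argpartition(flat, k - 1)[:k]
        kth_val = flat[part].max()
        strictly = np.flatnonzero(flat < kth_val)
        ties = np.flatnonzero(flat == kth_val)[: k - strictly.size]
        idx = np.concatenate([strictly, ties])
        idx = idx[np.lexsort((idx, flat[idx]))]
    return np.stack(np.unravel_index(idx, loss_matrix.shape), axis=1)


# ---------------------------------------------------------------------------
# Within-frame annealed particle filter
# ---------------------------------------------------------------------------

def fit_frame(frame: PointCloudFrame, proposal: tuple[np.ndarray, np.ndarray],
              previous: tuple[CandidateSet, CandidateSet] | None,
              config: TrackerConfig, loss_config: LossConfig,
              rng: np.random.Generator,
              scale_mult: float = 1.0
              ) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Annealed particle-filter fit of one frame.

    Starting from the proposal joint pose, repeat for ``n_anneal_iters``
    iterations: perturb each body's current candidates quasi-randomly (scales
    shrinking geometrically by ``anneal_factor``), evaluate the full m x n
    joint loss matrix, and keep the best ``n_particles`` pairings.  The best
    pairing survives unperturbed, so the best loss never increases across
    iterations.
    """
    bc = loss_config.constants
    n = config.n_particles
    p0, p1 = (np.asarray(p, dtype=float).copy() for p in proposal)
    cand0, cand1 = p0[None, :], p1[None, :]
    best_per_iter: list[float] = []
    best0, best1, best_loss = p0, p1, np.inf
    for it in range(config.n_anneal_iters):
        scale = scale_mult * config.init_scales * config.anneal_factor**it
        base0 = cand0[np.minimum(np.arange(n), cand0.shape[0] - 1)]
        base1 = cand1[np.minimum(np.arange(n), cand1.shape[0] - 1)]
        # Perturb every candidate with its own quasi-random offset; keep the
        # incumbent best (index 0) unperturbed.
        for base, dim, out in ((base0, 9, 0), (base1, 8, 1)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                engine = qmc.Sobol(d=dim, scramble=True,
                                   seed=int(rng.integers(0, 2**31 - 1)))
                u = engine.random(n)
            pert = base + (2.0 * u - 1.0) * scale[None, :dim]
            pert[0] = base[0]
            pert = _clamp_pose_params(pert, bc)
            if out == 0:
                parts0 = pert
            else:
                parts1 = pert
        set0 = CandidateSet(parts0, bc, True)
        set1 = CandidateSet(parts1, bc, False)
        losses = total_loss(frame, set0, set1, previous, loss_config)
        if not np.all(np.isfinite(losses)):
            return p0, p1, np.inf, {"converged": False,
                                    "loss_per_iter": best_per_iter,
                                    "non_finite": True}
        pairs = topk_resample(losses, n)
        cand0 = parts0[pairs[:, 0]]
        cand1 = parts1[pairs[:, 1]]
        best0, best1 = cand0[0], cand1[0]
        best_loss = float(losses[pairs[0, 0], pairs[0, 1]])
        best_per_iter.append(best_loss)
    return best0, best1, best_loss, {"converged": True,
                                     "loss_per_iter": best_per_iter,
                                     "non_finite": False}


# ---------------------------------------------------------------------------
# Between-frame RLS proposal bank
# ---------------------------------------------------------------------------

class RLSFilterBank:
    """Bank of independent recursive-least-squares one-step predictors.

    Each scalar signal is predicted from its last ``embedding`` values with
    forgetting factor ``mu`` and inverse-covariance initialization
    ``R = I / eps``.  Outlier observations move the weights only weakly once
    the gain has converged, which keeps single bad fits from derailing the
    proposals.
    """

    def __init__(self, n_signals: int, embedding: int = 5, mu: float = 0.99,
                 eps: float = 0.1):
        self.n_signals = n_signals
        self.embedding = embedding
        self.mu = mu
        self.w = np.zeros((n_signals, embedding))
        self.R = np.tile(np.eye(embedding) / eps, (n_signals, 1, 1))
        self.history: list[np.ndarray] = []

    @property
    def ready(self) -> bool:
        return len(self.history) >= self.embedding

    def predict(self) -> np.ndarray:
        if not self.ready:
            return self.history[-1].copy()
        x = np.stack(self.history[-self.embedding:], axis=1)  # (S, E)
        return np.einsum("se,se->s", self.w, x)

    def update(self, observed: np.ndarray) -> None:
        observed = np.asarray(observed, dtype=float)
        if self.ready:
            x = np.stack(self.history[-self.embedding:], axis=1)
            for s in range(self.n_signals):
                xs = x[s]
                R = self.R[s]
                Rx = R @ xs
                denom = self.mu + xs @ Rx
                self.R[s] = (R - np.outer(Rx, Rx) / denom) / self.mu
                err = observed[s] - self.w[s] @ xs
                self.w[s] += (self.R[s] @ xs) * err
        self.history.append(observed.copy())
        if len(self.history) > self.embedding + 1:
            self.history.pop(0)


# ---------------------------------------------------------------------------
# Sequence tracking
# ---------------------------------------------------------------------------

def _rolling_median_mad(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd
    s = pd.Series(x)
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    mad = (s - pd.Series(med)).abs().rolling(
        window, center=True, min_periods=1).median().to_numpy()
    return med, mad


def track_sequence(frames: list[PointCloudFrame], config: TrackerConfig,
                   loss_config: LossConfig | None = None,
                   frame_rate: float = 60.0) -> RawTrack:
    """Track a full sequence: init, per-frame fits with RLS proposals, flags."""
    loss_config = loss_config or LossConfig()
    T = len(frames)
    if T == 0:
        return RawTrack(np.zeros((0, 9)), np.zeros((0, 8)), np.zeros(0))
    rng = np.random.default_rng(config.seed)
    t0, p_impl, p_part = find_init_frame(frames, config, loss_config.constants)

    params0 = np.zeros((T, 9))
    params1 = np.zeros((T, 8))
    losses = np.full(T, np.nan)
    diagnostics: list[dict] = []
    flags: list[tuple[int, str]] = []

    rls = RLSFilterBank(6, config.rls_embedding, config.rls_mu, config.rls_eps)
    previous = None
    cur0, cur1 = p_impl, p_part
    n_fitted = 0
    for t in range(t0, T):
        if n_fitted > config.rls_warmup_frames and rls.ready:
            pred = rls.predict()
            prop0, prop1 = cur0.copy(), cur1.copy()
            prop0[:3], prop1[:3] = pred[:3], pred[3:]
        else:
            prop0, prop1 = cur0, cur1
        mult = 2.0 if t == t0 else 1.0  # wider first-frame search
        if frames[t].n_points == 0:
            flags.append((t, "empty_cloud"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-cloud warning already flagged
            b0, b1, loss, diag = fit_frame(frames[t], (prop0, prop1), previous,
                                           config, loss_config, rng,
                                           scale_mult=mult)
        if not diag["converged"]:
            flags.append((t, "non_finite_loss"))
            b0, b1 = prop0, prop1
        params0[t], params1[t], losses[t] = b0, b1, loss
        diagnostics.append(diag)
        rls.update(np.concatenate([b0[:3], b1[:3]]))
        previous = (CandidateSet(b0[None, :], loss_config.constants, True),
                    CandidateSet(b1[None, :], loss_config.constants, False))
        cur0, cur1 = b0, b1
        n_fitted += 1
    params0[:t0] = params0[t0]
    params1[:t0] = params1[t0]
    losses[:t0] = losses[t0]

    # Anomaly flags: loss spikes over a rolling robust baseline, and
    # displacement above the physical speed cap.
    med, mad = _rolling_median_mad(losses, config.flag_window)
    spikes = losses > med + config.flag_mad_mult * np.maximum(mad, 1e-12)
    for t in np.flatnonzero(spikes):
        flags.append((int(t), "loss_anomaly"))
    for pp in (params0, params1):
        disp = np.linalg.norm(np.diff(pp[:, :3], axis=0), axis=1) * frame_rate
        for t in np.flatnonzero(disp > config.speed_cap):
            flags.append((int(t) + 1, "speed_cap"))
    flags = sorted(set(flags))
    return RawTrack(params0, params1, losses, flags, diagnostics, t0)
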