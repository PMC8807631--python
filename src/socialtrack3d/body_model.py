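"""Deformable two-ellipsoid mouse body model.

A mouse is modeled as two prolate spheroids — a deformable "hip" ellipsoid and
a rigid "head" (nose) ellipsoid — joined at a neck joint that sits on the major
axis of the hip ellipsoid.  A scalar spine coordinate ``s`` in [0, 1] morphs the
hip ellipsoid from long-and-narrow (s = 1) to short-and-wide (s = 0).  An
implanted animal additionally carries a rigid sphere (the head-mounted neural
implant) attached to the head ellipsoid, free to rotate about its major axis.

Pose parametrization (exploiting the rotational symmetry of the spheroids):

* ``c_hip`` = (x, y, z): center of the hip ellipsoid, world frame, meters.
* ``beta``, ``gamma``: rotation of the hip major axis about the y- and z-axis.
* ``theta``, ``phi``: head left/right and up/down rotation within a neck cone.
* ``s``: spine stretch in [0, 1].
* ``psi``: implant rotation angle about the head axis (implanted animals only).

This gives 8 free parameters for a plain animal, 9 for an implanted one.

Rotation convention: ``rotation_from_angles(ax, ay, az)`` composes extrinsic
rotations as ``Rz(az) @ Ry(ay) @ Rx(ax)`` (x first, then y, then z).  The hip
rotation is ``R(0, beta, gamma) = Rz(gamma) @ Ry(beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "BodyConstants",
    "MousePose",
    "JointPose",
    "Skeleton",
    "rotation_from_angles",
    "rotation_aligning",
    "build_skeleton",
    "build_skeletons_batch",
    "approx_surface_distance",
]


@dataclass(frozen=True)
class BodyConstants:
    """Physical dimensions of the body model, SI units (meters).

    Defaults correspond to an average adult laboratory mouse; ``body_scale``
    multiplies every length for other strains or juveniles.
    """

    a_nose: float = 0.0200
    b_nose: float = 0.0120
    a_hip_min: float = 0.0050
    a_hip_max: float = 0.0250
    b_hip_min: float = 0.0120
    b_hip_max: float = 0.0150
    d_nose: float = 0.0100
    d_hip_factor: float = 0.75
    body_scale: float = 1.0
    # Neck cone half-angles (rad); the physical movement limit of the neck.
    theta_max: float = np.pi / 2
    phi_max: float = np.pi / 3

    def __post_init__(self) -> None:
        lengths = (self.a_nose, self.b_nose, self.a_hip_min, self.a_hip_max,
                   self.b_hip_min, self.b_hip_max, self.d_nose)
        if not all(v > 0 for v in lengths):
            raise ValueError("all body lengths must be > 0")
        if not (self.a_hip_min < self.a_hip_max and self.b_hip_min < self.b_hip_max):
            raise ValueError("hip axis ranges must satisfy min < max")

    # Derived implant geometry (scales with b_nose / a_nose / d_nose).
    @property
    def r_impl(self) -> float:
        return 0.9 * self.b_nose

    @property
    def x_impl(self) -> float:
        return self.d_nose + 0.5 * self.a_nose

    @property
    def z_impl(self) -> float:
        return 1.5 * self.r_impl

    def scaled(self) -> "BodyConstants":
        """Return a copy with body_scale folded into every length."""
        k = self.body_scale
        if k == 1.0:
            return self
        return replace(
            self,
            a_nose=self.a_nose * k, b_nose=self.b_nose * k,
            a_hip_min=self.a_hip_min * k, a_hip_max=self.a_hip_max * k,
            b_hip_min=self.b_hip_min * k, b_hip_max=self.b_hip_max * k,
            d_nose=self.d_nose * k, body_scale=1.0,
        )

    @classmethod
    def from_config(cls, path: str | Path) -> "BodyConstants":
        """Load constants from a plain-text ``key = value`` file (SI units)."""
        values: dict[str, float] = {}
        names = {f.name for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in names:
                raise KeyError(f"unknown body constant {key!r}")
            values[key] = float(val)
        return cls(**values)


@dataclass
class MousePose:
    """Pose of one animal: 8 free parameters, 9 if ``psi`` is present."""

    c_hip: np.ndarray  # (3,) world position of the hip-ellipsoid center, m
    beta: float = 0.0
    gamma: float = 0.0
    theta: float = 0.0
    phi: float = 0.0
    s: float = 0.5
    psi: float | None = None

    FREE_PARAMS_PLAIN = 8
    FREE_PARAMS_IMPLANTED = 9

    def __post_init__(self) -> None:
        self.c_hip = np.asarray(self.c_hip, dtype=float).reshape(3)

    @property
    def implanted(self) -> bool:
        return self.psi is not None

    @property
    def n_free_params(self) -> int:
        return 9 if self.implanted else 8

    def to_array(self) -> np.ndarray:
        """Flat parameter vector (x, y, z, beta, gamma, theta, phi, s[, psi])."""
        base = [*self.c_hip, self.beta, self.gamma, self.theta, self.phi, self.s]
        if self.implanted:
            base.append(self.psi)
        return np.array(base, dtype=float)

    @classmethod
    def from_array(cls, params: np.ndarray) -> "MousePose":
        params = np.asarray(params, dtype=float).ravel()
        if params.size not in (8, 9):
            raise ValueError("pose vector must have 8 or 9 entries")
        psi = float(params[8]) if params.size == 9 else None
        return cls(c_hip=params[:3], beta=float(params[3]), gamma=float(params[4]),
                   theta=float(params[5]), phi=float(params[6]), s=float(params[7]),
                   psi=psi)

    def validate(self, constants: BodyConstants | None = None) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite pose parameters")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"spine stretch s={self.s} outside [0, 1]")
        if constants is not None:
            if abs(self.theta) > constants.theta_max + 1e-12:
                raise ValueError("theta outside the neck cone")
            if abs(self.phi) > constants.phi_max + 1e-12:
                raise ValueError("phi outside the neck cone")


@dataclass
class JointPose:
    """Joint pose of the implanted animal and its partner: 17 free parameters."""

    pose_implanted: MousePose
    pose_partner: MousePose

    def __post_init__(self) -> None:
        if not self.pose_implanted.implanted:
            raise ValueError("pose_implanted must carry psi (9 parameters)")
        if self.pose_partner.implanted:
            raise ValueError("pose_partner must be a plain 8-parameter pose")

    @property
    def n_free_params(self) -> int:
        return self.pose_implanted.n_free_params + self.pose_partner.n_free_params

    @property
    def poses(self) -> tuple[MousePose, MousePose]:
        return (self.pose_implanted, self.pose_partner)


@dataclass
class Skeleton:
    """Derived landmark coordinates and ellipsoid matrices of one posed body."""

    c_hip: np.ndarray
    c_mid: np.ndarray
    c_nose: np.ndarray
    c_tip: np.ndarray
    c_tail: np.ndarray
    R_hip: np.ndarray
    R_head: np.ndarray
    Q_hip: np.ndarray
    Q_nose: np.ndarray
    a_hip: float
    b_hip: float
    c_impl: np.ndarray | None = None

    LANDMARK_NAMES = ("c_hip", "c_mid", "c_nose", "c_tip", "c_tail")

    def landmarks(self) -> dict[str, np.ndarray]:
        """Flat record of named 3-vectors (export surface)."""
        out = {name: getattr(self, name) for name in self.LANDMARK_NAMES}
        if self.c_impl is not None:
            out["c_impl"] = self.c_impl
        return out


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def rotation_from_angles(alpha_x: float, alpha_y: float, alpha_z: float) -> np.ndarray:
    """Rotation composing extrinsic axis rotations as Rz(az) @ Ry(ay) @ Rx(ax)."""
    cx, sx = np.cos(alpha_x), np.sin(alpha_x)
    cy, sy = np.cos(alpha_y), np.sin(alpha_y)
    cz, sz = np.cos(alpha_z), np.sin(alpha_z)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rotation_aligning(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector v1 onto unit vector v2.

    Uses the Rodrigues construction about the axis v1 x v2.  For antipodal
    inputs (v2 = -v1) the rotation axis is degenerate; a fixed perpendicular
    axis is chosen deterministically (the coordinate axis least aligned with
    v1, projected orthogonal to it).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cannot align zero vectors")
    a, b = v1 / n1, v2 / n2
    c = float(a @ b)
    v = np.cross(a, b)
    if c < -1.0 + 1e-12:
        # 180 degree rotation about a fixed perpendicular axis.
        helper = np.zeros(3)
        helper[np.argmin(np.abs(a))] = 1.0
        axis = helper - (helper @ a) * a
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + (K @ K) / (1.0 + c)


# ---------------------------------------------------------------------------
# Skeleton construction (batched core, scalar wrapper)
# ---------------------------------------------------------------------------

def _rotation_hip_batch(beta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """R(0, beta, gamma) = Rz(gamma) @ Ry(beta) for arrays of angles: (K, 3, 3)."""
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    K = beta.shape[0]
    R = np.empty((K, 3, 3))
    R[:, 0, 0] = cg * cb
    R[:, 0, 1] = -sg
    R[:, 0, 2] = cg * sb
    R[:, 1, 0] = sg * cb
    R[:, 1, 1] = cg
    R[:, 1, 2] = sg * sb
    R[:, 2, 0] = -sb
    R[:, 2, 1] = 0.0
    R[:, 2, 2] = cb
    return R


def _rotation_aligning_ex_batch(e: np.ndarray) -> np.ndarray:
    """Batched rotation_aligning(e_x, e) for unit vectors e of shape (K, 3)."""
    K = e.shape[0]
    c = e[:, 0]
    # v = e_x x e = (0, -e_z, e_y)
    vy, vz = -e[:, 2], e[:, 1]
    R = np.zeros((K, 3, 3))
    denom = 1.0 + c
    safe = denom > 1e-12
    d = np.where(safe, denom, 1.0)
    R[:, 0, 0] = 1.0 - (vy**2 + vz**2) / d
    R[:, 0, 1] = -e[:, 1]
    R[:, 0, 2] = -e[:, 2]
    R[:, 1, 0] = e[:, 1]
    R[:, 1, 1] = 1.0 - vz**2 / d
    R[:, 1, 2] = vy * vz / d
    R[:, 2, 0] = e[:, 2]
    R[:, 2, 1] = vy * vz / d
    R[:, 2, 2] = 1.0 - vy**2 / d
    if not np.all(safe):
        # Antipodal head direction (theta = pi); outside the neck cone in
        # practice but handled for robustness: 180 deg about z.
        R[~safe] = np.diag([-1.0, -1.0, 1.0])
    return R


def build_skeletons_batch(params: np.ndarray, constants: BodyConstants,
                          implanted: bool) -> dict[str, np.ndarray]:
    """Vectorized skeleton geometry for K stacked pose vectors.

    Parameters
    ----------
    params : (K, 8) or (K, 9) array of pose vectors (x, y, z, beta, gamma,
        theta, phi, s[, psi]).

    Returns a dict of stacked arrays: landmarks (K, 3), rotations (K, 3, 3),
    characteristic matrices Q_hip / Q_nose (K, 3, 3), and axes (K,).
    """
    bc = constants.scaled()
    params = np.atleast_2d(np.asarray(params, dtype=float))
    expected = 9 if implanted else 8
    if params.shape[1] != expected:
        raise ValueError(f"expected {expected} pose parameters, got {params.shape[1]}")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite pose parameters")
    s = params[:, 7]
    if np.any((s < 0) | (s > 1)):
        raise ValueError("spine stretch s outside [0, 1]")

    c_hip = params[:, 0:3]
    beta, gamma = params[:, 3], params[:, 4]
    theta, phi = params[:, 5], params[:, 6]

    a_hip = bc.a_hip_min + (bc.a_hip_max - bc.a_hip_min) * s
    b_hip = bc.b_hip_min + (bc.b_hip_max - bc.b_hip_min) * (1.0 - s)
    d_hip = bc.d_hip_factor * a_hip

    R_hip = _rotation_hip_batch(beta, gamma)
    e_nose = np.stack([np.cos(theta),
                       np.sin(theta) * np.cos(phi),
                       np.sin(theta) * np.sin(phi)], axis=1)
    R_head = _rotation_aligning_ex_batch(e_nose)

    # Landmarks in the mouse body frame, then world.
    neck = np.zeros_like(c_hip)
    neck[:, 0] = d_hip
    c_nose_mouse = neck + bc.d_nose * e_nose  # R_head @ [d_nose,0,0] = d_nose*e_nose
    c_tip_mouse = neck + (bc.d_nose + bc.a_nose) * e_nose
    c_mid = np.einsum("kij,kj->ki", R_hip, neck) + c_hip
    c_nose = np.einsum("kij,kj->ki", R_hip, c_nose_mouse) + c_hip
    c_tip = np.einsum("kij,kj->ki", R_hip, c_tip_mouse) + c_hip
    c_tail = c_hip - a_hip[:, None] * R_hip[:, :, 0]

    out = {
        "c_hip": c_hip, "c_mid": c_mid, "c_nose": c_nose,
        "c_tip": c_tip, "c_tail": c_tail,
        "R_hip": R_hip, "R_head": R_head,
        "a_hip": a_hip, "b_hip": b_hip,
    }

    # Characteristic ellipsoid matrices Q = R diag(1/a^2, 1/b^2, 1/b^2) R^T.
    inv_a2 = 1.0 / a_hip**2
    inv_b2 = 1.0 / b_hip**2
    D_hip = np.zeros((params.shape[0], 3, 3))
    D_hip[:, 0, 0], D_hip[:, 1, 1], D_hip[:, 2, 2] = inv_a2, inv_b2, inv_b2
    out["Q_hip"] = R_hip @ D_hip @ np.swapaxes(R_hip, 1, 2)

    R_world_head = R_hip @ R_head
    D_nose = np.zeros((1, 3, 3)) + np.diag(
        [1.0 / bc.a_nose**2, 1.0 / bc.b_nose**2, 1.0 / bc.b_nose**2])
    out["Q_nose"] = R_world_head @ D_nose @ np.swapaxes(R_world_head, 1, 2)

    if implanted:
        psi = params[:, 8]
        offset = np.stack([np.full_like(psi, bc.x_impl),
                           bc.z_impl * np.cos(psi),
                           bc.z_impl * np.sin(psi)], axis=1)
        c_impl_mouse = np.einsum("kij,kj->ki", R_head, offset) + neck
        out["c_impl"] = np.einsum("kij,kj->ki", R_hip, c_impl_mouse) + c_hip
    return out


def build_skeleton(pose: MousePose, constants: BodyConstants,
                   implanted: bool | None = None) -> Skeleton:
    """Build the skeleton (landmarks, rotations, ellipsoid matrices) of a pose."""
    if implanted is None:
        implanted = pose.implanted
    if implanted and not pose.implanted:
        raise ValueError("implanted skeleton requested for a pose without psi")
    pose.validate(constants.scaled())
    batch = build_skeletons_batch(pose.to_array()[None, :], constants, implanted)
    return Skeleton(
        c_hip=batch["c_hip"][0], c_mid=batch["c_mid"][0], c_nose=batch["c_nose"][0],
        c_tip=batch["c_tip"][0], c_tail=batch["c_tail"][0],
        R_hip=batch["R_hip"][0], R_head=batch["R_head"][0],
        Q_hip=batch["Q_hip"][0], Q_nose=batch["Q_nose"][0],
        a_hip=float(batch["a_hip"][0]), b_hip=float(batch["b_hip"][0]),
        c_impl=batch["c_impl"][0] if implanted else None,
    )


# ---------------------------------------------------------------------------
# Approximate point-to-ellipsoid surface distance
# ---------------------------------------------------------------------------

def approx_surface_distance(points: np.ndarray, center: np.ndarray,
                            Q: np.ndarray) -> np.ndarray:
    """Fast approximate distance from points to an ellipsoid surface.

    The distance is measured along the ray through the centroid:
    ``d = |1 - 1/||p'||_Q| * ||p'||`` with ``p' = p - center`` and
    ``||p'||_Q = sqrt(p'^T Q p')``.  Exact for spheres; for prolate spheroids
    it over-estimates slightly away from the axes but is accurate on average,
    which is what the point-cloud loss needs.

    A point exactly at the center is assigned the smallest semi-axis (the
    limit of the expression along any ray through the center).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p = points - np.asarray(center, dtype=float)
    qnorm2 = np.einsum("ni,ij,nj->n", p, Q, p)
    r = np.linalg.norm(p, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs(1.0 - 1.0 / np.sqrt(qnorm2)) * r
    at_center = qnorm2 <= 0.0
    if np.any(at_center):
        smallest_axis = 1.0 / np.sqrt(np.linalg.eigvalsh(Q)[-1])
        d = np.where(at_center, smallest_axis, d)
    return d
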