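"""Kinematic and social feature extraction from smoothed tracks.

Produces egocentric speed components, the three instantaneous social
distances, template-matched social events (nose-to-nose and the two directed
nose-to-tail contacts), ear-key-point-based 3D head direction of the partner,
and the 45-column behavioral predictor matrix used for neural tuning-curve
modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_opening, gaussian_filter1d

from .scene_synthesis import KP_CODE, PointCloudFrame
from .trajectory_smoothing import SmoothedTrack

__all__ = ["SocialEvent", "FeatureMatrix", "egocentric_speeds",
           "social_distances", "detect_social_events",
           "head_direction_partner", "head_direction_implanted",
           "build_feature_matrix"]

EVENT_KINDS = ("nose_nose", "nose0_tail1", "nose1_tail0")


@dataclass
class SocialEvent:
    kind: str
    start: int   # frame index, inclusive
    end: int     # frame index, exclusive

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError("event must satisfy start < end")


@dataclass
class FeatureMatrix:
    """T x 45 named per-frame behavioral predictors."""

    data: pd.DataFrame
    circular: tuple = ()
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="frame")


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return -np.mod(-np.asarray(a) + np.pi, 2 * np.pi) + np.pi


def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(np.asarray(x, dtype=float), dt, axis=0)


def egocentric_speeds(track: SmoothedTrack, body: int,
                      dt: float = 1.0 / 60.0) -> np.ndarray:
    """(T, 3) forward / left / up speed of one animal.

    Hip-center velocity (central differences) projected onto the horizontal
    forward axis of the hip ellipsoid, its horizontal left perpendicular, and
    the global z-axis.
    """
    c_hip = track.landmarks(body)["c_hip"]
    v = _central_diff(c_hip, dt)
    axis = track.hip_axis(body)
    fwd = axis.copy()
    fwd[:, 2] = 0.0
    fwd /= np.maximum(np.linalg.norm(fwd, axis=1, keepdims=True), 1e-12)
    left = np.stack([-fwd[:, 1], fwd[:, 0], np.zeros(len(fwd))], axis=1)
    return np.stack([np.sum(v * fwd, axis=1),
                     np.sum(v * left, axis=1),
                     v[:, 2]], axis=1)


def social_distances(track: SmoothedTrack) -> np.ndarray:
    """(T, 3): nose-to-nose, nose0-to-tail1, nose1-to-tail0 distances (m)."""
    tip0 = track.landmarks0["c_tip"]
    tip1 = track.landmarks1["c_tip"]
    tail0 = track.landmarks0["c_tail"]
    tail1 = track.landmarks1["c_tail"]
    return np.stack([np.linalg.norm(tip0 - tip1, axis=1),
                     np.linalg.norm(tip0 - tail1, axis=1),
                     np.linalg.norm(tip1 - tail0, axis=1)], axis=1)


def detect_social_events(distances: np.ndarray, contact_dist: float = 0.02,
                         apart_dist: float = 0.06, open_frames: int = 3,
                         close_frames: int = 30) -> list[SocialEvent]:
    """Template-match social contacts from the three social distances.

    nose-to-nose: nose-nose < 2 cm while both nose-tail distances exceed
    6 cm; directed nose-to-tail: that nose-tail distance < 2 cm while
    nose-nose exceeds 6 cm.  Each binary trace is cleaned by binary opening
    (3-frame kernel) then binary closing (30-frame kernel); runs become
    events.
    """
    d = np.asarray(distances, dtype=float)
    nn, n0t1, n1t0 = d[:, 0], d[:, 1], d[:, 2]
    masks = {
        "nose_nose": (nn < contact_dist) & (n0t1 > apart_dist) & (n1t0 > apart_dist),
        "nose0_tail1": (n0t1 < contact_dist) & (nn > apart_dist),
        "nose1_tail0": (n1t0 < contact_dist) & (nn > apart_dist),
    }
    events: list[SocialEvent] = []
    for kind, mask in masks.items():
        mask = binary_opening(mask, structure=np.ones(open_frames))
        mask = binary_closing(mask, structure=np.ones(close_frames))
        padded = np.concatenate([[False], mask, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        events += [SocialEvent(kind, int(s), int(e)) for s, e in zip(starts, ends)]
    return sorted(events, key=lambda e: (e.start, e.kind))


def _assigned_ear_mean(track: SmoothedTrack, frames: list[PointCloudFrame],
                       body: int, max_dist: float = 0.03) -> np.ndarray:
    """Per-frame mean position of the ear key-points assigned to one body.

    An ear key-point belongs to a body when that body's head-ellipsoid center
    is the closer of the two AND within ``max_dist``.  Frames without
    assigned ears are linearly interpolated.
    """
    T = len(track)
    own = track.landmarks(body)["c_nose"]
    other = track.landmarks(1 - body)["c_nose"]
    means = np.full((T, 3), np.nan)
    for t, frame in enumerate(frames[:T]):
        ears = frame.keypoints[frame.kp_type == KP_CODE["ear"]]
        if len(ears) == 0:
            continue
        d_own = np.linalg.norm(ears - own[t], axis=1)
        d_other = np.linalg.norm(ears - other[t], axis=1)
        sel = (d_own < d_other) & (d_own < max_dist)
        if np.any(sel):
            means[t] = ears[sel].mean(axis=0)
    good = np.all(np.isfinite(means), axis=1)
    if not np.any(good):
        raise ValueError("no ear key-points assigned in the entire sequence")
    idx = np.arange(T)
    for c in range(3):
        means[:, c] = np.interp(idx, idx[good], means[good, c])
    return means


def _head_direction_from_ears(track: SmoothedTrack, ear_mean: np.ndarray,
                              body: int, sigma_pre: float = 3.0,
                              sigma_post: float = 10.0) -> np.ndarray:
    c_mid = track.landmarks(body)["c_mid"]
    c_nose = gaussian_filter1d(track.landmarks(body)["c_nose"], sigma_pre,
                               axis=0, mode="nearest")
    ear_mean = gaussian_filter1d(ear_mean, sigma_pre, axis=0, mode="nearest")
    v_nose = c_nose - c_mid
    v_nose /= np.maximum(np.linalg.norm(v_nose, axis=1, keepdims=True), 1e-12)
    v_ear = ear_mean - c_mid
    v_ear /= np.maximum(np.linalg.norm(v_ear, axis=1, keepdims=True), 1e-12)
    rej = v_ear - np.sum(v_ear * v_nose, axis=1, keepdims=True) * v_nose
    rej /= np.maximum(np.linalg.norm(rej, axis=1, keepdims=True), 1e-12)
    rej = gaussian_filter1d(rej, sigma_post, axis=0, mode="nearest")
    return rej / np.maximum(np.linalg.norm(rej, axis=1, keepdims=True), 1e-12)


def head_direction_partner(track: SmoothedTrack,
                           frames: list[PointCloudFrame],
                           body: int = 1) -> np.ndarray:
    """(T, 3) head-up direction of the partner from its ear key-points.

    The head-up vector is the unit rejection of the neck-to-ear-mean
    direction from the nose axis, Gaussian-smoothed and renormalized.
    """
    ear_mean = _assigned_ear_mean(track, frames, body)
    return _head_direction_from_ears(track, ear_mean, body)


def head_direction_implanted(track: SmoothedTrack) -> np.ndarray:
    """(T, 3) head-up direction of the implanted animal from the implant.

    The implant is rigidly attached dorsally to the head, so the unit
    rejection of the neck-to-implant direction from the nose axis gives the
    head-up vector directly.
    """
    c_mid = track.landmarks0["c_mid"]
    c_impl = track.landmarks0["c_impl"]
    v_nose = track.head_axis(0)
    v_impl = c_impl - c_mid
    v_impl /= np.maximum(np.linalg.norm(v_impl, axis=1, keepdims=True), 1e-12)
    rej = v_impl - np.sum(v_impl * v_nose, axis=1, keepdims=True) * v_nose
    norm = np.maximum(np.linalg.norm(rej, axis=1, keepdims=True), 1e-12)
    return rej / norm


def _signed_horizontal_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed angle from a to b in the xy-plane; negative when b is to the
    right of a."""
    return np.arctan2(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0],
                      a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1])


def _per_animal_features(track: SmoothedTrack, body: int, head_up: np.ndarray,
                         dt: float, arena_radius: float) -> dict[str, np.ndarray]:
    lm = track.landmarks(body)
    hip_axis = track.hip_axis(body)
    head_axis = track.head_axis(body)
    fwd = hip_axis.copy()
    fwd[:, 2] = 0.0
    fwd /= np.maximum(np.linalg.norm(fwd, axis=1, keepdims=True), 1e-12)

    heading = np.arctan2(hip_axis[:, 1], hip_axis[:, 0])
    body_pitch = np.arcsin(np.clip(hip_axis[:, 2], -1, 1))
    head_yaw = _signed_horizontal_angle(fwd, head_axis)
    head_pitch = np.arcsin(np.clip(head_axis[:, 2], -1, 1))
    left = np.stack([-head_axis[:, 1], head_axis[:, 0],
                     np.zeros(len(head_axis))], axis=1)
    left /= np.maximum(np.linalg.norm(left, axis=1, keepdims=True), 1e-12)
    head_roll = np.arcsin(np.clip(np.sum(head_up * left, axis=1), -1, 1))
    s = track.s[body]
    speeds = egocentric_speeds(track, body, dt)
    r = np.linalg.norm(lm["c_hip"][:, :2], axis=1)

    feats = {
        # posture
        "head_yaw": _wrap_angle(head_yaw),
        "head_pitch": head_pitch,
        "head_roll": head_roll,
        "spine_stretch": s,
        "body_pitch": body_pitch,
        "z_hip": lm["c_hip"][:, 2],
        "z_nose": lm["c_nose"][:, 2],
        # spatial
        "x_hip": lm["c_hip"][:, 0],
        "y_hip": lm["c_hip"][:, 1],
        "dist_to_wall": arena_radius - r,
        "heading": _wrap_angle(heading),
        # movement
        "forward_speed": speeds[:, 0],
        "left_speed": speeds[:, 1],
        "up_speed": speeds[:, 2],
        "d_head_yaw": _central_diff(np.unwrap(head_yaw), dt),
        "d_head_pitch": _central_diff(head_pitch, dt),
        "d_head_roll": _central_diff(head_roll, dt),
        "d_body_pitch": _central_diff(body_pitch, dt),
        "d_heading": _central_diff(np.unwrap(heading), dt),
        "d_spine_stretch": _central_diff(s, dt),
    }
    return feats


def build_feature_matrix(track: SmoothedTrack,
                         head_up0: np.ndarray | None = None,
                         head_up1: np.ndarray | None = None,
                         dt: float = 1.0 / 60.0,
                         arena_radius: float = 0.30) -> FeatureMatrix:
    """Assemble the 45-column behavioral predictor matrix.

    5 social columns (nose-to-nose distance, the two directed nose-to-tail
    distances, hip-center range rate, and the head-center-to-head-center
    orientation angle) plus 20 posture/spatial/movement columns per animal
    (suffix _0 for the implanted subject, _1 for the partner).
    """
    if head_up0 is None:
        head_up0 = head_direction_implanted(track)
    if head_up1 is None:
        # Without ear key-points the partner's roll is taken as level: the
        # head-up vector is the rejection of vertical from the nose axis.
        v_nose = track.head_axis(1)
        up = np.tile([0.0, 0.0, 1.0], (len(track), 1))
        rej = up - np.sum(up * v_nose, axis=1, keepdims=True) * v_nose
        head_up1 = rej / np.maximum(np.linalg.norm(rej, axis=1, keepdims=True),
                                    1e-12)
    d = social_distances(track)
    center_range = np.linalg.norm(track.landmarks0["c_hip"]
                                  - track.landmarks1["c_hip"], axis=1)
    head0 = track.head_axis(0)
    to_partner = track.landmarks1["c_nose"] - track.landmarks0["c_nose"]
    cols: dict[str, np.ndarray] = {
        "nose_nose_distance": d[:, 0],
        "nose0_tail1_distance": d[:, 1],
        "nose1_tail0_distance": d[:, 2],
        "hip_range_rate": _central_diff(center_range, dt),
        "orientation_angle": _wrap_angle(
            _signed_horizontal_angle(head0, to_partner)),
    }
    groups = {name: "social" for name in cols}
    per_group = (["head_yaw", "head_pitch", "head_roll", "spine_stretch",
                  "body_pitch", "z_hip", "z_nose"],
                 ["x_hip", "y_hip", "dist_to_wall", "heading"],
                 ["forward_speed", "left_speed", "up_speed", "d_head_yaw",
                  "d_head_pitch", "d_head_roll", "d_body_pitch", "d_heading",
                  "d_spine_stretch"])
    for body, head_up in ((0, head_up0), (1, head_up1)):
        feats = _per_animal_features(track, body, head_up, dt, arena_radius)
        for gname, members in zip(("posture", "spatial", "movement"), per_group):
            for m in members:
                cols[f"{m}_{body}"] = feats[m]
                groups[f"{m}_{body}"] = gname
    df = pd.DataFrame(cols)
    circular = ("orientation_angle", "heading_0", "heading_1",
                "head_yaw_0", "head_yaw_1")
    return FeatureMatrix(df, circular, groups)


def export_events_csv(events: list[SocialEvent], path: str | Path,
                      frame_rate: float = 60.0) -> None:
    lines = ["kind,start_s,end_s"]
    for e in events:
        lines.append(f"{e.kind},{e.start / frame_rate:.4f},{e.end / frame_rate:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
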