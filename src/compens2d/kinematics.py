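"""Geometric primitives and per-scenario kinematic variables.

Compensation shows up in 2D keypoints as a handful of scalar series
computed against the first-frame baseline pose:

* frontal view (S1): relative head-area change ΔH (trunk leaning toward /
  away from the camera), angular displacement of each shoulder about the
  baseline neck (rotation / shoulder hike), and the spine's angular sweep
  about the mid-hip (trunk tilt);
* side views (S2/S3): the spine sweep angle, horizontal neck and
  shoulder displacements, vertical shoulder displacement relative to the
  neck, observed chest-length change (oblique view), and |ΔH|.

All series are smoothed with a centred moving average (window 5 frames
by default) before thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from . import body25
from .normalization import NormalizedSequence, smooth

S1_VARIABLES = ("head_area_change", "shoulder_angle_affected",
                "shoulder_angle_unaffected", "trunk_tilt_angle")
S23_VARIABLES = ("spine_angle", "neck_x_disp", "shoulder_x_disp",
                 "shoulder_y_disp", "chest_len_change", "head_area_change")


class DegenerateGeometryError(ValueError):
    """Zero-length vector where a direction is required."""


def angle(j1, j2, j3) -> float:
    """Angle in degrees at vertex ``j2`` between rays to ``j1`` and ``j3``.

    arccos of the normalized dot product, clamped to [-1, 1]; result in
    [0, 180]. Raises on zero-length rays.
    """
    v1 = np.asarray(j1, float) - np.asarray(j2, float)
    v2 = np.asarray(j3, float) - np.asarray(j2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError("zero-length vector in angle()")
    cos = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def displacement(j1, j2) -> tuple[float, float]:
    """(Δx, Δy) from ``j2`` to ``j1`` (i.e. j1 − j2)."""
    d = np.asarray(j1, float) - np.asarray(j2, float)
    return float(d[0]), float(d[1])


def distance(j1, j2) -> float:
    """Euclidean distance between two points."""
    return float(np.linalg.norm(np.asarray(j1, float) - np.asarray(j2, float)))


@dataclass(frozen=True)
class HeadModel:
    """How the observed head size H is computed.

    Default: area of the convex hull of the detected head keypoints
    (nose, eyes, ears). With fewer than 3 detected points the squared
    inter-eye distance is used as an area proxy (``fallback=True``);
    with fewer than 2 points the head is unusable.
    """

    joint_ids: tuple[int, ...] = body25.HEAD_JOINTS
    fallback: bool = True
    tag: str = "convex-hull"


def head_area(xy: np.ndarray, conf: np.ndarray,
              model: HeadModel = HeadModel()) -> float:
    """Observed head size from one frame's (25, 2) coords + confidences."""
    ids = [j for j in model.joint_ids if conf[j] > 0]
    pts = xy[ids]
    if len(ids) < 2:
        raise DegenerateGeometryError(
            f"only {len(ids)} usable head keypoints")
    if len(ids) < 3:
        if not model.fallback:
            raise DegenerateGeometryError(
                "fewer than 3 head keypoints and fallback disabled")
        return float(np.sum((pts[0] - pts[1]) ** 2))
    try:
        return float(ConvexHull(pts).volume)   # 2D hull "volume" is area
    except QhullError:
        if model.fallback:
            return float(np.sum((pts[0] - pts[-1]) ** 2))
        warnings.warn("collinear head keypoints: zero head area")
        return 0.0


def _smooth_trajectories(xy: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average over time of every joint coordinate."""
    if window <= 1:
        return xy
    out = np.empty_like(xy)
    for j in range(xy.shape[1]):
        for k in range(2):
            out[:, j, k] = smooth(xy[:, j, k], window)
    return out


@dataclass
class KinematicSeries:
    """Per-frame kinematic variable values for one trial.

    ``values`` is a DataFrame indexed by frame number with one column per
    variable of the active scenario, already smoothed.
    """

    values: pd.DataFrame
    scenario: str
    affected_side: str
    facing: int
    smoothing_window: int = 5

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, var: str) -> np.ndarray:
        return self.values[var].to_numpy()


def compute_series(seq: NormalizedSequence, *, window: int = 5,
                   baseline_frames: int = 5,
                   head_model: HeadModel = HeadModel()) -> KinematicSeries:
    """All kinematic variables of the sequence's scenario, smoothed.

    Requires a cleaned, body-frame, spine-scaled, un-mirrored sequence
    (the rule-based path works on true-side geometry). Baseline
    quantities are taken from the first kept frame. Horizontal
    displacements in side views are multiplied by the facing sign so that
    "toward the camera/forward" is positive regardless of orientation.
    """
    if seq.mirrored:
        raise ValueError("kinematic variables require un-mirrored keypoints")
    # the moving-average filter is applied to the keypoint trajectories
    # themselves, before any variable is derived: nonlinear quantities
    # (hull areas, angles) computed from raw noisy points carry an
    # upward bias that filtering the derived series cannot remove
    xy = _smooth_trajectories(seq.xy, window)
    conf = seq.conf
    n = seq.n_frames
    sh_a = body25.shoulder(seq.affected_side)
    sh_u = body25.shoulder(body25.other_side(seq.affected_side))
    # baseline pose: mean of the first few smoothed frames — a single
    # noisy frame as reference would bias every relative quantity of
    # the whole trial, the head-area ratio worst of all
    b = max(1, min(baseline_frames, n))
    xy0 = xy[:b].mean(axis=0)
    neck0 = xy0[body25.NECK]
    hip0 = xy0[body25.MID_HIP]
    h0 = float(np.mean([head_area(xy[t], conf[t], head_model)
                        for t in range(b)]))

    def safe_angle(j1, j2, j3) -> float:
        try:
            return angle(j1, j2, j3)
        except DegenerateGeometryError:
            return 0.0

    cols: dict[str, np.ndarray] = {}
    dh = np.array([(head_area(xy[t], conf[t], head_model) - h0) / h0
                   if h0 > 0 else 0.0 for t in range(n)])
    cols["head_area_change"] = dh

    if seq.scenario == "S1":
        cols["shoulder_angle_affected"] = np.array([
            safe_angle(xy0[sh_a], neck0, xy[t, sh_a]) for t in range(n)])
        cols["shoulder_angle_unaffected"] = np.array([
            safe_angle(xy0[sh_u], neck0, xy[t, sh_u]) for t in range(n)])
        # spine sweep about the mid-hip: baseline neck vs current neck
        cols["trunk_tilt_angle"] = np.array([
            safe_angle(neck0, hip0, xy[t, body25.NECK]) for t in range(n)])
        order = S1_VARIABLES
    else:
        cols["spine_angle"] = np.array([
            safe_angle(neck0, hip0, xy[t, body25.NECK]) for t in range(n)])
        cols["neck_x_disp"] = seq.facing * (
            xy[:, body25.NECK, 0] - neck0[0])
        cols["shoulder_x_disp"] = seq.facing * (
            xy[:, sh_a, 0] - xy[:, body25.NECK, 0])
        cols["shoulder_y_disp"] = xy[:, sh_a, 1] - xy[:, body25.NECK, 1]
        chest0 = distance(xy0[body25.R_SHOULDER], xy0[body25.L_SHOULDER])
        cols["chest_len_change"] = np.array([
            distance(xy[t, body25.R_SHOULDER], xy[t, body25.L_SHOULDER])
            - chest0 for t in range(n)])
        order = S23_VARIABLES

    df = pd.DataFrame({v: cols[v] for v in order},
                      index=pd.Index(seq.frame_numbers, name="t"))
    return KinematicSeries(values=df, scenario=seq.scenario,
                           affected_side=seq.affected_side,
                           facing=seq.facing, smoothing_window=window)
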