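"""Keypoint normalization: body-frame transform, spine scaling, mirroring.

Raw keypoints live in image pixels with y growing downward, and patients
differ in body size and placement. Normalization proceeds in three steps:

1. *transformation* — translate every joint so the mid-hip is the origin
   and flip the y axis to up-positive (body frame {B});
2. *normalization* — divide all coordinates by the spine length
   ``d(neck, mid-hip)`` measured at the first kept frame, so one body
   unit is one spine length;
3. *mirror* — for learned classifiers only, reflect x so that the
   affected limb always lies in the positive-x half-plane, giving the
   healthy side as a common reference. The rule-based path never mirrors.

A centred moving-average smoother (default window: 5 frames) for
trajectory series also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import body25
from .pose_io import RawSequence, Skeleton


class DegeneratePoseError(ValueError):
    """Pose unusable for normalization (missing mid-hip, zero spine)."""


@dataclass(frozen=True)
class BodyFrameSkeleton:
    """A skeleton in body-frame coordinates (origin mid-hip, y up)."""

    xy: np.ndarray     # (25, 2)
    conf: np.ndarray   # (25,)

    def point(self, joint_id: int) -> np.ndarray:
        return self.xy[joint_id]


@dataclass(frozen=True)
class NormalizedSequence:
    """Body-frame, spine-scaled keypoint trajectories of one trial.

    ``xy`` has shape (T, 25, 2); ``conf`` (T, 25). Frame metadata is
    carried over from the raw sequence; ``spine_len_ref`` is the pixel
    spine length at the first kept frame.
    """

    xy: np.ndarray
    conf: np.ndarray
    frame_numbers: tuple[int, ...]
    fps: float
    subject_id: str
    exercise_id: str
    scenario: str
    affected_side: str
    facing: int
    spine_len_ref: float
    mirrored: bool = False

    def __post_init__(self):
        if self.spine_len_ref <= 0:
            raise DegeneratePoseError("spine_len_ref must be positive")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def joint_xy(self, joint_id: int) -> np.ndarray:
        """(T, 2) trajectory of one joint."""
        return self.xy[:, joint_id, :]


def to_body_frame(skel: Skeleton) -> BodyFrameSkeleton:
    """Translate to mid-hip origin and flip y to up-positive."""
    if skel.conf[body25.MID_HIP] <= 0:
        raise DegeneratePoseError("mid-hip not detected")
    xy = skel.xy - skel.point(body25.MID_HIP)
    xy = xy * np.array([1.0, -1.0])
    return BodyFrameSkeleton(xy=xy, conf=skel.conf.copy())


def scale_by_spine(seq: RawSequence, *, rotate_to_spine: bool = False
                   ) -> NormalizedSequence:
    """Body-frame transform + spine-length scaling of a cleaned sequence.

    Every frame must hold exactly one (patient) skeleton. The reference
    spine length is ``‖neck − mid-hip‖`` at the first kept frame; at that
    frame the normalized neck therefore sits at distance 1 from origin.

    ``rotate_to_spine`` additionally rotates each frame so the spine is
    aligned with +y (off by default: plain translation suffices when the
    camera is level).
    """
    if not seq.frames:
        raise DegeneratePoseError("empty sequence")
    body = []
    conf = []
    for frame in seq.frames:
        if len(frame.skeletons) != 1:
            raise ValueError(
                f"frame t={frame.t} not reduced to a single skeleton")
        bf = to_body_frame(frame.skeletons[0])
        xy = bf.xy
        if rotate_to_spine:
            xy = _rotate_spine_up(xy)
        body.append(xy)
        conf.append(bf.conf)
    xy = np.stack(body)
    spine_ref = float(np.linalg.norm(xy[0, body25.NECK]))
    if spine_ref <= 0:
        raise DegeneratePoseError("zero spine length at baseline frame")
    return NormalizedSequence(
        xy=xy / spine_ref, conf=np.stack(conf),
        frame_numbers=tuple(seq.frame_numbers), fps=seq.fps,
        subject_id=seq.subject_id, exercise_id=seq.exercise_id,
        scenario=seq.scenario, affected_side=seq.affected_side,
        facing=seq.facing, spine_len_ref=spine_ref, mirrored=False)


def _rotate_spine_up(xy: np.ndarray) -> np.ndarray:
    neck = xy[body25.NECK]
    norm = np.linalg.norm(neck)
    if norm == 0:
        raise DegeneratePoseError("zero spine length")
    c, s = neck[1] / norm, neck[0] / norm   # rotate neck onto +y
    rot = np.array([[c, -s], [s, c]])
    return xy @ rot.T


def mirror_to_reference(seq: NormalizedSequence) -> NormalizedSequence:
    """Reflect x so the affected limb lies in the positive-x half-plane.

    The decision is taken from the affected shoulder's x sign at the
    baseline frame; if it is already positive the coordinates are left
    untouched. Either way the result is flagged ``mirrored`` (the marker
    the feature encoder requires). Applying the operation twice equals
    applying it once (and never flips back: involution on coordinates).
    """
    sh = body25.shoulder(seq.affected_side)
    xy = seq.xy
    if xy[0, sh, 0] < 0:
        xy = xy * np.array([-1.0, 1.0])
    return replace(seq, xy=xy, mirrored=True)


def smooth(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    ``window`` must be odd so the window is symmetric about each sample;
    edge samples average whatever part of the window exists.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()
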