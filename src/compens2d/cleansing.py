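"""Dataset cleansing for raw multi-person keypoint streams.

Pose estimators on consumer webcams produce three kinds of contamination:
bystanders in frame, spurious "ghost" skeletons hallucinated from
furniture, and low-confidence keypoint misdetections.  The pipeline here
(1) drops ghosts — skeletons with no detected spine joints, (2) keeps the
person closest to the image centre as the patient, (3) drops frames whose
relevant joints fall below a confidence threshold, and (4) exposes a
programmatic keypoint-correction hook.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import body25
from .pose_io import FrameObservation, RawSequence, Skeleton


class NoPatientError(ValueError):
    """Frame contains no skeleton after ghost removal."""


@dataclass
class CleansingReport:
    frames_in: int = 0
    frames_kept: int = 0
    skeletons_removed: int = 0
    frames_dropped_low_confidence: int = 0
    corrected_keypoints: int = 0

    def __post_init__(self):
        if self.frames_kept > self.frames_in:
            raise ValueError("frames_kept cannot exceed frames_in")


def default_relevant_joints(affected_side: str) -> frozenset[int]:
    """Joints held to the strict confidence threshold.

    Affected-side shoulder/elbow/wrist, the opposite shoulder, and the
    spine joints (nose, neck, mid-hip).
    """
    opp = body25.other_side(affected_side)
    return frozenset({
        body25.shoulder(affected_side), body25.elbow(affected_side),
        body25.wrist(affected_side), body25.shoulder(opp),
        body25.NOSE, body25.NECK, body25.MID_HIP,
    })


@dataclass(frozen=True)
class CleansingConfig:
    """Confidence filter settings.

    ``s_min_relevant`` is the strict lower bound (exclusive) on the
    detection confidence of relevant joints; the default 0.36 was chosen
    for webcam-grade pose output. Non-relevant joints only need s > 0.
    """

    s_min_relevant: float = 0.36
    relevant_joints: frozenset[int] = field(
        default_factory=lambda: default_relevant_joints("right"))

    def __post_init__(self):
        if not 0.0 <= self.s_min_relevant <= 1.0:
            raise ValueError("s_min_relevant must lie in [0, 1]")

    @classmethod
    def for_side(cls, affected_side: str,
                 s_min_relevant: float = 0.36) -> "CleansingConfig":
        return cls(s_min_relevant=s_min_relevant,
                   relevant_joints=default_relevant_joints(affected_side))


def is_ghost(skel: Skeleton) -> bool:
    """True when all spine joints (nose, neck, mid-hip) are undetected."""
    return bool(np.all(skel.conf[list(body25.SPINE_JOINTS)] == 0.0))


def remove_ghost_skeletons(frame: FrameObservation) -> FrameObservation:
    """Drop skeletons with zero confidence at every spine joint."""
    kept = tuple(s for s in frame.skeletons if not is_ghost(s))
    return replace(frame, skeletons=kept)


def select_patient(frame: FrameObservation) -> Skeleton:
    """Return the skeleton whose mid-hip is closest to the image centre.

    Distance ties are broken by person index (first wins).
    """
    if not frame.skeletons:
        raise NoPatientError(f"no skeletons in frame t={frame.t}")
    w, h = frame.image_size
    center = np.array([w / 2.0, h / 2.0])
    dists = [float(np.linalg.norm(s.point(body25.MID_HIP) - center))
             for s in frame.skeletons]
    return frame.skeletons[int(np.argmin(dists))]


def frame_passes_confidence(skel: Skeleton, cfg: CleansingConfig) -> bool:
    relevant = sorted(cfg.relevant_joints)
    rest = [j for j in range(body25.N_JOINTS) if j not in cfg.relevant_joints]
    return bool(np.all(skel.conf[relevant] > cfg.s_min_relevant)
                and np.all(skel.conf[rest] > 0.0))


def reduce_to_patient(seq: RawSequence) -> tuple[RawSequence, int]:
    """Ghost-remove and patient-select every frame.

    Frames left empty after ghost removal are dropped. Returns the reduced
    sequence and the number of discarded skeletons (ghosts + bystanders).
    """
    frames = []
    removed = 0
    for frame in seq.frames:
        cleaned = remove_ghost_skeletons(frame)
        removed += len(frame.skeletons) - len(cleaned.skeletons)
        if not cleaned.skeletons:
            continue
        patient = select_patient(cleaned)
        removed += len(cleaned.skeletons) - 1
        frames.append(replace(cleaned, skeletons=(patient,)))
    return seq.with_frames(frames), removed


def filter_frames(seq: RawSequence, cfg: CleansingConfig
                  ) -> tuple[RawSequence, CleansingReport]:
    """Drop frames failing the confidence rule; exact counts in the report.

    Every frame must already hold a single patient skeleton
    (see :func:`reduce_to_patient`). A frame is kept iff all relevant
    joints have s > ``s_min_relevant`` and all remaining joints s > 0.
    """
    kept = []
    for frame in seq.frames:
        if len(frame.skeletons) != 1:
            raise ValueError(
                f"frame t={frame.t} has {len(frame.skeletons)} skeletons; "
                "run reduce_to_patient first")
        if frame_passes_confidence(frame.skeletons[0], cfg):
            kept.append(frame)
    report = CleansingReport(
        frames_in=len(seq.frames),
        frames_kept=len(kept),
        frames_dropped_low_confidence=len(seq.frames) - len(kept),
    )
    return seq.with_frames(kept), report


def clean_sequence(seq: RawSequence, cfg: CleansingConfig | None = None
                   ) -> tuple[RawSequence, CleansingReport]:
    """Full cleansing pipeline: ghosts → patient selection → frame filter."""
    if cfg is None:
        cfg = CleansingConfig.for_side(seq.affected_side)
    reduced, removed = reduce_to_patient(seq)
    filtered, report = filter_frames(reduced, cfg)
    report.frames_in = len(seq.frames)
    report.skeletons_removed = removed
    report.frames_dropped_low_confidence = (
        report.frames_in - report.frames_kept)
    return filtered, report


def correct_keypoints(seq: RawSequence,
                      corrections: list[tuple[int, int, float, float]]
                      ) -> RawSequence:
    """Replace listed keypoint coordinates; confidences are preserved.

    ``corrections`` holds ``(t, joint_id, x, y)`` tuples. Unknown frame
    numbers or joint ids raise KeyError. Frames must hold one skeleton.
    """
    by_t = {f.t: i for i, f in enumerate(seq.frames)}
    frames = list(seq.frames)
    for t, joint_id, x, y in corrections:
        if t not in by_t:
            raise KeyError(f"no frame t={t} in sequence")
        if not 0 <= joint_id < body25.N_JOINTS:
            raise KeyError(f"joint id {joint_id} outside BODY_25")
        idx = by_t[t]
        frame = frames[idx]
        if len(frame.skeletons) != 1:
            raise ValueError(f"frame t={t} not reduced to one skeleton")
        joints = frame.skeletons[0].joints.copy()
        joints[joint_id, 0] = x
        joints[joint_id, 1] = y
        frames[idx] = replace(frame, skeletons=(Skeleton(joints),))
    return seq.with_frames(frames)
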