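"""Keypoint data containers and I/O.

Two on-disk dialects are supported:

* the per-frame JSON documents written by OpenPose-style pose estimators
  (``people[*].pose_keypoints_2d`` as a flat ``(x, y, s) * 25`` list), and
* an internal plain-text sequence format: one CSV row per
  ``(frame, person, joint)`` plus a JSON metadata sidecar — diff-able and
  stream-friendly.

Coordinates are kept exactly as read (image pixels, y growing downward);
every convention change happens in :mod:`compens2d.normalization`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import body25

logger = logging.getLogger(__name__)

EXERCISES = ("E1", "E2", "E3")
SCENARIOS = ("S1", "S2", "S3")
SIDES = ("left", "right")

#: Camera placements compatible with each exercise: the two tabletop
#: reaching tasks are filmed frontally, the cane task from the affected side.
EXERCISE_SCENARIOS = {"E1": ("S1",), "E2": ("S1",), "E3": ("S2", "S3")}


class PoseParseError(ValueError):
    """Malformed keypoint document."""


class SequenceFormatError(ValueError):
    """Missing or invalid sequence metadata."""


@dataclass(frozen=True)
class Skeleton:
    """One detected person in one frame: 25 BODY_25 keypoints.

    ``joints`` is a ``(25, 3)`` float array of ``(x, y, s)`` rows; an
    all-zero row encodes "not detected"; ``s`` is the detector confidence
    in [0, 1].
    """

    joints: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.joints, dtype=float)
        if arr.shape != (body25.N_JOINTS, 3):
            raise PoseParseError(
                f"skeleton needs shape (25, 3), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise PoseParseError("non-finite keypoint values")
        object.__setattr__(self, "joints", arr)

    @property
    def xy(self) -> np.ndarray:
        return self.joints[:, :2]

    @property
    def conf(self) -> np.ndarray:
        return self.joints[:, 2]

    def point(self, joint_id: int) -> np.ndarray:
        return self.joints[joint_id, :2]


@dataclass(frozen=True)
class FrameObservation:
    """All skeletons detected in one video frame (1-based frame number)."""

    t: int
    skeletons: tuple[Skeleton, ...]
    image_size: tuple[int, int] = (640, 480)

    def __post_init__(self):
        if self.t < 1:
            raise ValueError(f"frame numbers are 1-based, got t={self.t}")
        object.__setattr__(self, "skeletons", tuple(self.skeletons))


@dataclass(frozen=True)
class RawSequence:
    """A time-ordered keypoint recording of one exercise trial."""

    frames: tuple[FrameObservation, ...]
    fps: float
    subject_id: str
    exercise_id: str
    scenario: str
    affected_side: str
    #: +1 if the patient faces the image +x direction in side views, -1
    #: otherwise; irrelevant for the frontal scenario.
    facing: int = 1

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        if self.exercise_id not in EXERCISES:
            raise SequenceFormatError(f"unknown exercise {self.exercise_id!r}")
        if self.scenario not in SCENARIOS:
            raise SequenceFormatError(f"unknown scenario {self.scenario!r}")
        if self.scenario not in EXERCISE_SCENARIOS[self.exercise_id]:
            raise SequenceFormatError(
                f"scenario {self.scenario} incompatible with exercise "
                f"{self.exercise_id}")
        if self.affected_side not in SIDES:
            raise SequenceFormatError(
                f"affected_side must be 'left' or 'right', "
                f"got {self.affected_side!r}")
        ts = [f.t for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise SequenceFormatError("frame numbers must strictly increase")

    @property
    def frame_numbers(self) -> list[int]:
        return [f.t for f in self.frames]

    def with_frames(self, frames: Iterable[FrameObservation]) -> "RawSequence":
        return replace(self, frames=tuple(frames))


def parse_openpose_frame(doc: dict, t: int,
                         image_size: tuple[int, int] = (640, 480)
                         ) -> FrameObservation:
    """Parse one OpenPose-style JSON document into a FrameObservation.

    ``doc`` must carry a ``people`` list whose entries hold a flat
    75-number ``pose_keypoints_2d`` list. A missing or empty ``people``
    list yields zero skeletons; nothing is silently dropped.
    """
    people = doc.get("people", [])
    skeletons = []
    for i, person in enumerate(people):
        kp = person.get("pose_keypoints_2d")
        if kp is None:
            raise PoseParseError(f"person {i}: missing pose_keypoints_2d")
        kp = np.asarray(kp, dtype=float)
        if kp.shape != (body25.N_JOINTS * 3,):
            raise PoseParseError(
                f"person {i}: expected {body25.N_JOINTS * 3} numbers, "
                f"got {kp.size}")
        skeletons.append(Skeleton(kp.reshape(body25.N_JOINTS, 3)))
    return FrameObservation(t=t, skeletons=tuple(skeletons),
                            image_size=image_size)


def load_openpose_dir(path, *, fps: float, subject_id: str, exercise_id: str,
                      scenario: str, affected_side: str, facing: int = 1,
                      image_size: tuple[int, int] = (640, 480)) -> RawSequence:
    """Load a directory of per-frame OpenPose JSON files.

    Files are ordered by the trailing integer in their stem (falling back
    to lexicographic order); gaps in numbering are kept and logged.
    """
    path = Path(path)
    files = sorted(path.glob("*.json"), key=_frame_key)
    if not files:
        raise SequenceFormatError(f"no JSON frame files under {path}")
    frames = []
    for fallback_t, f in enumerate(files, start=1):
        t = _frame_key(f)
        t = t if isinstance(t, int) and t >= 1 else fallback_t
        with open(f) as fh:
            doc = json.load(fh)
        frames.append(parse_openpose_frame(doc, t, image_size=image_size))
    ts = [f.t for f in frames]
    if any(b != a + 1 for a, b in zip(ts, ts[1:])):
        logger.warning("gap(s) in frame numbering under %s", path)
    return RawSequence(frames=tuple(frames), fps=fps, subject_id=subject_id,
                       exercise_id=exercise_id, scenario=scenario,
                       affected_side=affected_side, facing=facing)


def _frame_key(p: Path):
    digits = "".join(ch for ch in p.stem if ch.isdigit())
    return int(digits) if digits else p.stem


def save_sequence(seq: RawSequence, path) -> None:
    """Write the internal CSV + JSON-sidecar sequence format.

    ``path`` names the CSV file; the metadata sidecar is written next to
    it as ``<path>.meta.json``. ``load_sequence(save_sequence(x)) == x``
    on all fields.
    """
    path = Path(path)
    rows = []
    for frame in seq.frames:
        for person, skel in enumerate(frame.skeletons):
            for j in range(body25.N_JOINTS):
                x, y, s = skel.joints[j]
                rows.append((frame.t, person, j, x, y, s))
    df = pd.DataFrame(rows, columns=["t", "person", "joint_id", "x", "y", "s"])
    df.to_csv(path, index=False)
    meta = {
        "fps": seq.fps,
        "subject_id": seq.subject_id,
        "exercise_id": seq.exercise_id,
        "scenario": seq.scenario,
        "affected_side": seq.affected_side,
        "facing": seq.facing,
        "frame_numbers": seq.frame_numbers,
        "image_sizes": {str(f.t): list(f.image_size) for f in seq.frames},
        "format_version": 1,
    }
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_sequence(path) -> RawSequence:
    """Load a sequence saved by :func:`save_sequence`."""
    path = Path(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise SequenceFormatError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("fps", "subject_id", "exercise_id", "scenario",
                "affected_side"):
        if key not in meta:
            raise SequenceFormatError(f"metadata missing {key!r}")
    df = pd.read_csv(path)
    sizes = meta.get("image_sizes", {})
    frames = []
    frame_numbers = meta.get("frame_numbers") or sorted(df["t"].unique())
    by_t = dict(iter(df.groupby("t", sort=True)))
    for t in frame_numbers:
        t = int(t)
        size = tuple(sizes.get(str(t), (640, 480)))
        sub = by_t.get(t)
        skels = []
        if sub is not None:
            for _, psub in sub.groupby("person", sort=True):
                joints = np.zeros((body25.N_JOINTS, 3))
                joints[psub["joint_id"].to_numpy(int)] = (
                    psub[["x", "y", "s"]].to_numpy(float))
                skels.append(Skeleton(joints))
        frames.append(FrameObservation(t=t, skeletons=tuple(skels),
                                       image_size=size))
    ts = [f.t for f in frames]
    if any(b != a + 1 for a, b in zip(ts, ts[1:])):
        logger.warning("gap(s) in frame numbering in %s", path)
    return RawSequence(frames=tuple(frames), fps=float(meta["fps"]),
                       subject_id=str(meta["subject_id"]),
                       exercise_id=meta["exercise_id"],
                       scenario=meta["scenario"],
                       affected_side=meta["affected_side"],
                       facing=int(meta.get("facing", 1)))


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")
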