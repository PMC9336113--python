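"""BODY_25 keypoint layout constants.

The 25-keypoint body layout used by common 2D pose estimators: index 0 is
the nose, 1 the neck (sternum top), 2/5 the right/left shoulders, 8 the
mid-hip, and so on.  All modules address joints by these integer ids.
"""

from __future__ import annotations

N_JOINTS = 25

NOSE = 0
NECK = 1
R_SHOULDER = 2
R_ELBOW = 3
R_WRIST = 4
L_SHOULDER = 5
L_ELBOW = 6
L_WRIST = 7
MID_HIP = 8
R_HIP = 9
R_KNEE = 10
R_ANKLE = 11
L_HIP = 12
L_KNEE = 13
L_ANKLE = 14
R_EYE = 15
L_EYE = 16
R_EAR = 17
L_EAR = 18
L_BIG_TOE = 19
L_SMALL_TOE = 20
L_HEEL = 21
R_BIG_TOE = 22
R_SMALL_TOE = 23
R_HEEL = 24

JOINT_NAMES = [
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
]

#: Joints whose simultaneous zero confidence marks a ghost skeleton.
SPINE_JOINTS = (NOSE, NECK, MID_HIP)

#: Head keypoints used by the default head-area model.
HEAD_JOINTS = (NOSE, R_EYE, L_EYE, R_EAR, L_EAR)


def shoulder(side: str) -> int:
    """BODY_25 id of the shoulder on the given side ('left'|'right')."""
    return L_SHOULDER if side == "left" else R_SHOULDER


def elbow(side: str) -> int:
    return L_ELBOW if side == "left" else R_ELBOW


def wrist(side: str) -> int:
    return L_WRIST if side == "left" else R_WRIST


def hip(side: str) -> int:
    return L_HIP if side == "left" else R_HIP


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"
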