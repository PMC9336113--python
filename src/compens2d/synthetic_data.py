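"""Synthetic seated-patient keypoint sequences with scripted compensation.

Real patient recordings of this kind are not shareable, so the package
ships a generator that emulates what the classifiers actually consume:
BODY_25 keypoint streams of a seated person under the three camera
placements (frontal S1, affected-side perpendicular S2 / oblique S3),
with compensation episodes injected as geometric effects, Gaussian pixel
noise, a confidence model, and optional detector artifacts (ghost
skeletons, a bystander, confidence dropouts).

Episode magnitudes are expressed as multiples of the matched rule
threshold: an episode of magnitude ``m`` drives the rule's kinematic
variable to exactly ``m x threshold`` at its plateau. With the default
square (step) profile and the 5-frame smoothing window this makes the
ground truth an exact oracle for the rule-based classifier at magnitude
2 on noiseless data: inside the episode the smoothed variable is at
least 1.2x the threshold, outside at most 0.8x.

Effects per label (frontal / side view):

* trunk forward (0): head-area growth / spine rotation about the
  mid-hip with the shoulder girdle carried ahead of the neck;
* trunk rotation (1): opposed angular shifts of both shoulders about
  the neck / horizontal shift of the visible shoulder;
* shoulder elevation (2): affected-shoulder raise about the neck /
  vertical shoulder raise relative to the neck;
* other (3): trunk tilt or head-area shrink / backward spine rotation
  or head-size change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import body25
from .labels import LabelSet, OTHER, SE, TF, TR
from .pose_io import FrameObservation, RawSequence, Skeleton
from .rb_classifier import ThresholdSet

IMAGE_SIZE = (640, 480)


@dataclass(frozen=True)
class SubjectTemplate:
    """Body geometry, camera placement and sensor model of one subject."""

    spine_len: float = 140.0          # pixels
    shoulder_halfwidth: float = 0.35  # fractions of spine length
    midhip: tuple[float, float] = (320.0, 340.0)
    scenario: str = "S1"
    affected_side: str = "right"
    facing: int = 1                   # side views: +1 faces image +x
    noise_sigma: float = 0.0          # pixel noise std
    conf_base: float = 0.9
    conf_jitter: float = 0.05
    fps: float = 30.0

    def __post_init__(self):
        if self.spine_len <= 0:
            raise ValueError("spine length must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class Episode:
    """One scripted compensation bout.

    ``magnitude`` is the plateau level in multiples of the matched rule
    threshold. ``mode`` selects the geometric mechanism for label 3
    ("tilt" | "shrink" in S1, "backward" | "head" in S2/S3); other
    labels ignore it.
    """

    label: int
    start: int
    end: int
    magnitude: float = 2.0
    mode: str = "default"

    def __post_init__(self):
        if self.label not in (TF, TR, SE, OTHER):
            raise ValueError(f"label must be 0..3, got {self.label}")
        if self.end < self.start or self.start < 1:
            raise ValueError("episode needs 1 <= start <= end")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")

    def intensity(self, t: int, ramp: int) -> float:
        if not self.start <= t <= self.end:
            return 0.0
        if ramp <= 0:
            return 1.0
        return min(1.0, (t - self.start + 1) / ramp,
                   (self.end - t + 1) / ramp)


@dataclass(frozen=True)
class CompensationScript:
    """Episodes plus the on/offset ramp length (frames; 0 = step)."""

    episodes: tuple[Episode, ...] = ()
    ramp: int = 0

    def __post_init__(self):
        object.__setattr__(self, "episodes", tuple(self.episodes))

    def validate(self, n_frames: int) -> None:
        for ep in self.episodes:
            if ep.end > n_frames:
                raise ValueError(
                    f"episode [{ep.start},{ep.end}] exceeds {n_frames} frames")

    def truth(self, t: int) -> LabelSet:
        return LabelSet(frozenset(ep.label for ep in self.episodes
                                  if ep.start <= t <= ep.end))


def _rot(p: np.ndarray, center: np.ndarray, deg: float) -> np.ndarray:
    """Rotate point about center by deg (image coords)."""
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    d = p - center
    return center + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _base_pose_s1(tpl: SubjectTemplate) -> np.ndarray:
    """Frontal seated pose, image coordinates (y down), (25, 2)."""
    L = tpl.spine_len
    hip = np.array(tpl.midhip)
    neck = hip + (0.0, -L)
    w = tpl.shoulder_halfwidth * L
    xy = np.zeros((body25.N_JOINTS, 2))
    xy[body25.MID_HIP] = hip
    xy[body25.NECK] = neck
    # facing the camera: the patient's right appears on the image left
    xy[body25.R_SHOULDER] = neck + (-w, 0.08 * L)
    xy[body25.L_SHOULDER] = neck + (w, 0.08 * L)
    nose = neck + (0.0, -0.30 * L)
    xy[body25.NOSE] = nose
    xy[body25.R_EYE] = nose + (-0.09 * L, -0.08 * L)
    xy[body25.L_EYE] = nose + (0.09 * L, -0.08 * L)
    xy[body25.R_EAR] = nose + (-0.17 * L, -0.03 * L)
    xy[body25.L_EAR] = nose + (0.17 * L, -0.03 * L)
    xy[body25.R_ELBOW] = xy[body25.R_SHOULDER] + (-0.10 * L, 0.45 * L)
    xy[body25.L_ELBOW] = xy[body25.L_SHOULDER] + (0.10 * L, 0.45 * L)
    xy[body25.R_WRIST] = xy[body25.R_ELBOW] + (0.0, 0.40 * L)
    xy[body25.L_WRIST] = xy[body25.L_ELBOW] + (0.0, 0.40 * L)
    xy[body25.R_HIP] = hip + (-0.20 * L, 0.05 * L)
    xy[body25.L_HIP] = hip + (0.20 * L, 0.05 * L)
    for side, sgn in ((body25.R_KNEE, -1), (body25.L_KNEE, 1)):
        xy[side] = hip + (sgn * 0.22 * L, 0.55 * L)
    for side, sgn in ((body25.R_ANKLE, -1), (body25.L_ANKLE, 1)):
        xy[side] = hip + (sgn * 0.22 * L, 1.05 * L)
    for j, ref, off in ((body25.R_BIG_TOE, body25.R_ANKLE, (-0.10, 0.05)),
                        (body25.R_SMALL_TOE, body25.R_ANKLE, (-0.14, 0.05)),
                        (body25.R_HEEL, body25.R_ANKLE, (0.03, 0.05)),
                        (body25.L_BIG_TOE, body25.L_ANKLE, (0.10, 0.05)),
                        (body25.L_SMALL_TOE, body25.L_ANKLE, (0.14, 0.05)),
                        (body25.L_HEEL, body25.L_ANKLE, (-0.03, 0.05))):
        xy[j] = xy[ref] + np.array(off) * L
    return xy


def _base_pose_side(tpl: SubjectTemplate) -> np.ndarray:
    """Side-view pose facing image +x; affected side toward the camera."""
    L = tpl.spine_len
    hip = np.array(tpl.midhip)
    neck = hip + (0.0, -L)
    xy = np.zeros((body25.N_JOINTS, 2))
    xy[body25.MID_HIP] = hip
    xy[body25.NECK] = neck
    vis = body25.shoulder(tpl.affected_side)
    hid = body25.shoulder(body25.other_side(tpl.affected_side))
    xy[vis] = neck            # near shoulder projects onto the neck
    xy[hid] = neck + (-0.40 * L, 0.0)
    # profile face: nose tip at the front, eyes above and behind it,
    # ears at the back of the head — a proper 2D spread, not a sliver
    nose = neck + (0.20 * L, -0.26 * L)
    xy[body25.NOSE] = nose
    eye_v = body25.R_EYE if tpl.affected_side == "right" else body25.L_EYE
    eye_h = body25.L_EYE if tpl.affected_side == "right" else body25.R_EYE
    ear_v = body25.R_EAR if tpl.affected_side == "right" else body25.L_EAR
    ear_h = body25.L_EAR if tpl.affected_side == "right" else body25.R_EAR
    xy[eye_v] = nose + (-0.07 * L, -0.11 * L)
    xy[eye_h] = nose + (-0.10 * L, -0.105 * L)
    xy[ear_v] = nose + (-0.26 * L, -0.07 * L)
    xy[ear_h] = nose + (-0.28 * L, -0.065 * L)
    xy[body25.elbow(tpl.affected_side)] = xy[vis] + (0.12 * L, 0.42 * L)
    xy[body25.wrist(tpl.affected_side)] = (
        xy[body25.elbow(tpl.affected_side)] + (0.30 * L, 0.05 * L))
    opp = body25.other_side(tpl.affected_side)
    xy[body25.elbow(opp)] = xy[hid] + (0.05 * L, 0.42 * L)
    xy[body25.wrist(opp)] = xy[body25.elbow(opp)] + (0.20 * L, 0.08 * L)
    xy[body25.hip(tpl.affected_side)] = hip + (0.05 * L, 0.03 * L)
    xy[body25.hip(opp)] = hip + (-0.05 * L, 0.03 * L)
    for j in (body25.R_KNEE, body25.L_KNEE):
        xy[j] = hip + (0.45 * L, 0.30 * L)
    for j in (body25.R_ANKLE, body25.L_ANKLE):
        xy[j] = hip + (0.42 * L, 0.85 * L)
    for j in (body25.R_BIG_TOE, body25.L_BIG_TOE):
        xy[j] = hip + (0.58 * L, 0.92 * L)
    for j in (body25.R_SMALL_TOE, body25.L_SMALL_TOE):
        xy[j] = hip + (0.60 * L, 0.93 * L)
    for j in (body25.R_HEEL, body25.L_HEEL):
        xy[j] = hip + (0.38 * L, 0.92 * L)
    return xy


HEAD_IDS = list(body25.HEAD_JOINTS)


def _apply_effects_s1(xy: np.ndarray, tpl: SubjectTemplate,
                      acts: dict, th: ThresholdSet) -> np.ndarray:
    L = tpl.spine_len
    neck0 = xy[body25.NECK].copy()
    hip0 = xy[body25.MID_HIP].copy()
    sh_a = body25.shoulder(tpl.affected_side)
    sh_u = body25.shoulder(body25.other_side(tpl.affected_side))
    out = xy.copy()

    def lift_sign(joint: int) -> float:
        # rotation sign that moves the shoulder upward in image coords
        return -1.0 if out[joint, 0] > neck0[0] else 1.0

    if acts.get("rotation", 0.0) > 0:
        theta = acts["rotation"] * th.th_se
        out[sh_a] = _rot(out[sh_a], neck0, lift_sign(sh_a) * theta)
        out[sh_u] = _rot(out[sh_u], neck0, -lift_sign(sh_u) * theta)
    if acts.get("elevation", 0.0) > 0:
        theta = acts["elevation"] * th.th_se
        out[sh_a] = _rot(out[sh_a], neck0, lift_sign(sh_a) * theta)
    if acts.get("tilt", 0.0) > 0:
        # lean toward the affected side (frontal view: the left-affected
        # patient's left appears at image +x)
        sign = 1.0 if tpl.affected_side == "left" else -1.0
        theta = sign * acts["tilt"] * th.th_o
        new_neck = _rot(neck0, hip0, theta)
        shift = new_neck - neck0
        out[body25.NECK] = new_neck
        out[HEAD_IDS] += shift     # head follows the neck; shoulders stay
    scale = 1.0
    if acts.get("head_grow", 0.0) > 0:
        scale *= 1.0 + acts["head_grow"] * th.th_tf
    if acts.get("head_shrink", 0.0) > 0:
        scale *= 1.0 - min(acts["head_shrink"] * th.th_tf, 0.9)
    if scale != 1.0:
        centroid = out[HEAD_IDS].mean(axis=0)
        out[HEAD_IDS] = centroid + (out[HEAD_IDS] - centroid) * math.sqrt(
            scale)
    return out


def _apply_effects_side(xy: np.ndarray, tpl: SubjectTemplate,
                        acts: dict, th: ThresholdSet) -> np.ndarray:
    L = tpl.spine_len
    neck0 = xy[body25.NECK].copy()
    hip0 = xy[body25.MID_HIP].copy()
    vis = body25.shoulder(tpl.affected_side)
    hid = body25.shoulder(body25.other_side(tpl.affected_side))
    out = xy.copy()
    lean = acts.get("lean_fwd", 0.0) * th.th_tf \
        - acts.get("lean_back", 0.0) * th.th_tf
    if lean != 0.0:
        # positive angle tips the top of the spine toward image +x
        new_neck = _rot(neck0, hip0, lean)
        shift = new_neck - neck0
        out[body25.NECK] = new_neck
        out[HEAD_IDS] += shift
        out[[vis, hid]] += shift   # shoulder girdle carried with the neck
        # small enough to stay clear of the side-view rotation threshold
        girdle = 0.03 * L * math.copysign(1.0, lean) * (abs(lean) / th.th_tf)
        out[[vis, hid]] += (girdle, 0.0)
    if acts.get("rotation", 0.0) > 0:
        out[vis] += (acts["rotation"] * th.th_tr * L, 0.0)
    if acts.get("elevation", 0.0) > 0:
        out[vis] += (0.0, -acts["elevation"] * th.th_se * L)
    if acts.get("head_grow", 0.0) or acts.get("head_shrink", 0.0):
        scale = 1.0 + acts.get("head_grow", 0.0) * th.th_ti \
            - min(acts.get("head_shrink", 0.0) * th.th_ti, 0.9)
        centroid = out[HEAD_IDS].mean(axis=0)
        out[HEAD_IDS] = centroid + (out[HEAD_IDS] - centroid) * math.sqrt(
            abs(scale))
    return out


def _episode_activations(script: CompensationScript, t: int,
                         scenario: str) -> dict:
    acts: dict[str, float] = {}
    for ep in script.episodes:
        i = ep.intensity(t, script.ramp) * ep.magnitude
        if i <= 0:
            continue
        if scenario == "S1":
            key = {TF: "head_grow", TR: "rotation", SE: "elevation",
                   OTHER: "shrink" if ep.mode == "shrink" else "tilt"}[
                       ep.label]
            key = "head_shrink" if key == "shrink" else key
        else:
            key = {TF: "lean_fwd", TR: "rotation", SE: "elevation",
                   OTHER: "head" if ep.mode == "head" else "lean_back"}[
                       ep.label]
            key = "head_shrink" if key == "head" else key
        acts[key] = acts.get(key, 0.0) + i
    return acts


def generate_sequence(template: SubjectTemplate, script: CompensationScript,
                      n_frames: int, seed: int = 0,
                      exercise_id: str | None = None,
                      subject_id: str = "synth"
                      ) -> tuple[RawSequence, list[LabelSet]]:
    """Render one trial and its frame-level ground truth.

    Deterministic given ``seed``. The affected wrist performs one smooth
    reach-and-return over the trial (benign task motion); compensation
    episodes add their geometric effects on top; Gaussian pixel noise
    and the confidence model are applied last.
    """
    script.validate(n_frames)
    rng = np.random.default_rng(seed)
    th = ThresholdSet.defaults(template.scenario)
    base = (_base_pose_s1(template) if template.scenario == "S1"
            else _base_pose_side(template))
    wrist = body25.wrist(template.affected_side)
    if template.scenario == "S1":
        reach_target = base[body25.NOSE] + (0.0, 0.15 * template.spine_len)
    else:
        reach_target = base[wrist] + (0.45 * template.spine_len,
                                      -0.10 * template.spine_len)
    frames, truth = [], []
    for t in range(1, n_frames + 1):
        acts = _episode_activations(script, t, template.scenario)
        if template.scenario == "S1":
            xy = _apply_effects_s1(base, template, acts, th)
        else:
            xy = _apply_effects_side(base, template, acts, th)
        phase = math.sin(math.pi * (t - 1) / max(n_frames - 1, 1)) ** 2
        xy[wrist] = xy[wrist] + phase * (reach_target - base[wrist])
        if template.facing == -1:
            xy = xy.copy()
            xy[:, 0] = IMAGE_SIZE[0] - xy[:, 0]
        if template.noise_sigma > 0:
            xy = xy + rng.normal(0.0, template.noise_sigma, xy.shape)
        conf = np.clip(template.conf_base
                       + rng.uniform(-template.conf_jitter,
                                     template.conf_jitter,
                                     body25.N_JOINTS), 0.0, 1.0)
        joints = np.column_stack([xy, conf])
        frames.append(FrameObservation(
            t=t, skeletons=(Skeleton(joints),), image_size=IMAGE_SIZE))
        truth.append(script.truth(t))
    if exercise_id is None:
        exercise_id = "E1" if template.scenario == "S1" else "E3"
    seq = RawSequence(frames=tuple(frames), fps=template.fps,
                      subject_id=subject_id, exercise_id=exercise_id,
                      scenario=template.scenario,
                      affected_side=template.affected_side,
                      facing=template.facing)
    return seq, truth


def random_script(n_frames: int, rng: np.random.Generator,
                  scenario: str = "S1",
                  label_weights: dict[int, float] | None = None,
                  n_episodes: tuple[int, int] = (1, 3),
                  magnitude: float = 2.0,
                  min_len: int = 15, max_len: int = 30,
                  gap: int = 6) -> CompensationScript:
    """Non-overlapping random episodes separated by at least ``gap`` frames.

    Episode labels are drawn from ``label_weights`` (uniform over the
    four categories by default); magnitudes are fixed at ``magnitude``
    threshold multiples.
    """
    if label_weights is None:
        label_weights = {TF: 1.0, TR: 1.0, SE: 1.0, OTHER: 1.0}
    labs = sorted(label_weights)
    w = np.array([label_weights[k] for k in labs], dtype=float)
    w = w / w.sum()
    k = int(rng.integers(n_episodes[0], n_episodes[1] + 1))
    episodes = []
    cursor = 1 + gap
    for _ in range(k):
        length = int(rng.integers(min_len, max_len + 1))
        if cursor + length + gap > n_frames:
            break
        start = int(rng.integers(cursor, cursor + gap))
        end = start + length - 1
        if end + gap > n_frames:
            break
        label = int(rng.choice(labs, p=w))
        mode = "default"
        if label == OTHER:
            if scenario == "S1":
                mode = "tilt" if rng.random() < 0.7 else "shrink"
            else:
                mode = "backward" if rng.random() < 0.7 else "head"
        episodes.append(Episode(label=label, start=start, end=end,
                                magnitude=magnitude, mode=mode))
        cursor = end + 1 + gap
    return CompensationScript(episodes=tuple(episodes))


@dataclass(frozen=True)
class Trial:
    sequence: RawSequence
    truth: tuple[LabelSet, ...]

    def __post_init__(self):
        object.__setattr__(self, "truth", tuple(self.truth))


def generate_dataset(n_subjects: int = 6, exercise_id: str = "E1",
                     trials: int = 10, n_frames: int = 120,
                     seed: int = 0, noise_sigma: float = 0.0,
                     scenario: str | None = None,
                     label_weights: dict[int, float] | None = None,
                     magnitude: float = 2.0) -> list[Trial]:
    """Multi-subject labeled benchmark dataset.

    Subject geometry (spine length, placement, affected side) is drawn
    per subject from realistic webcam ranges; each subject contributes
    ``trials`` trials of ``n_frames`` frames. ``label_weights`` skews
    the episode label distribution (e.g. to reproduce a strongly
    imbalanced regime with one rare label).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if scenario is None:
        scenario = "S1" if exercise_id in ("E1", "E2") else "S2"
    rng = np.random.default_rng(seed)
    out: list[Trial] = []
    for s in range(n_subjects):
        tpl = SubjectTemplate(
            spine_len=float(rng.uniform(120, 170)),
            midhip=(320.0 + float(rng.uniform(-25, 25)),
                    340.0 + float(rng.uniform(-15, 15))),
            scenario=scenario,
            affected_side="left" if s % 2 else "right",
            facing=1,
            noise_sigma=noise_sigma)
        for k in range(trials):
            script = random_script(n_frames, rng, scenario=scenario,
                                   label_weights=label_weights,
                                   magnitude=magnitude)
            seq, truth = generate_sequence(
                tpl, script, n_frames,
                seed=int(rng.integers(0, 2**31 - 1)),
                exercise_id=exercise_id,
                subject_id=f"P{s + 1:02d}")
            out.append(Trial(sequence=seq, truth=tuple(truth)))
    return out


@dataclass
class ContaminationLog:
    ghost_frames: list[int] = field(default_factory=list)
    extra_person_frames: list[int] = field(default_factory=list)
    dropout_frames: list[int] = field(default_factory=list)


def inject_artifacts(seq: RawSequence, ghost_rate: float = 0.0,
                     extra_person: bool = False, dropout: float = 0.0,
                     seed: int = 0) -> tuple[RawSequence, ContaminationLog]:
    """Contaminate a clean single-person sequence with detector artifacts.

    Ghosts are skeletons with zero confidence at every spine joint;
    the bystander is a full-confidence skeleton placed far off-centre
    (so patient selection still resolves correctly); dropouts lower one
    relevant joint's confidence of the patient below the 0.36 filter.
    Patient keypoint *positions* are never touched, so cleansing restores
    the unaffected frames exactly.
    """
    for r in (ghost_rate, dropout):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    log = ContaminationLog()
    frames = []
    for frame in seq.frames:
        skels = list(frame.skeletons)
        patient = skels[0]
        if dropout > 0 and rng.random() < dropout:
            joints = patient.joints.copy()
            j = int(rng.choice(list(body25.SPINE_JOINTS)
                               + [body25.R_SHOULDER, body25.L_SHOULDER]))
            joints[j, 2] = float(rng.uniform(0.01, 0.3))
            skels[0] = Skeleton(joints)
            log.dropout_frames.append(frame.t)
        if ghost_rate > 0 and rng.random() < ghost_rate:
            ghost = np.zeros((body25.N_JOINTS, 3))
            limbs = [j for j in range(body25.N_JOINTS)
                     if j not in body25.SPINE_JOINTS]
            ghost[limbs, 0] = rng.uniform(0, IMAGE_SIZE[0], len(limbs))
            ghost[limbs, 1] = rng.uniform(0, IMAGE_SIZE[1], len(limbs))
            ghost[limbs, 2] = rng.uniform(0.05, 0.5, len(limbs))
            skels.append(Skeleton(ghost))
            log.ghost_frames.append(frame.t)
        if extra_person:
            other = patient.joints.copy()
            other[:, :2] = other[:, :2] * 0.8 + np.array([-180.0, -150.0])
            skels.append(Skeleton(other))
            log.extra_person_frames.append(frame.t)
        frames.append(replace(frame, skeletons=tuple(skels)))
    return seq.with_frames(frames), log
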