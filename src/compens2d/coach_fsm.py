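"""Reflex-agent virtual coach.

An 8-state machine drives the coaching feedback loop: *out* (badly
positioned) → *in* (positioned) → *exercise* (trial starting) →
*normal* / *trunk-rotation* / *shoulder-elevation* /
*trunk-displacement* (assessment states) → *target* (goal reached,
absorbing until a new trial). Eleven transition rules attach an action —
a visual marker and/or a speech cue, emitted here as text events — to
each state change or timed self-loop:

 1. stay out too long → repeat the repositioning prompt (red rectangle);
 2. leave the valid position from any assessment state → back to out;
 3. become positioned → green rectangle + exercise directions;
 4. movement onset → show the target marker (green);
 5. movement stops mid-assessment → propose a repetition (back to e);
 6. exercise started → begin evaluating, ask to reach the target;
 7. linger in assessment without reaching the target → encourage;
 8. target reached → praise, target marker turns blue;
 9-11. compensation detected → posture-correction cue + red trunk or
       shoulder marker (one rule per compensation class).

Compensation ceasing (e.g. *tr* → *normal*) is a silent state update:
no rule attaches an action to it. When several compensation labels fire
in one frame the class priority is rotation > elevation > displacement
(configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from . import body25
from .labels import LabelSet, OTHER, SE, TF, TR
from .pose_io import RawSequence, Skeleton


class CoachState(str, Enum):
    OUT = "o"
    IN = "i"
    EXERCISE = "e"
    NORMAL = "n"
    TRUNK_ROTATION = "tr"
    SHOULDER_ELEVATION = "se"
    TRUNK_DISPLACEMENT = "td"
    TARGET = "tg"


ASSESSMENT_STATES = frozenset({CoachState.NORMAL, CoachState.TRUNK_ROTATION,
                               CoachState.SHOULDER_ELEVATION,
                               CoachState.TRUNK_DISPLACEMENT})

COMP_STATE = {TR: CoachState.TRUNK_ROTATION,
              SE: CoachState.SHOULDER_ELEVATION,
              TF: CoachState.TRUNK_DISPLACEMENT,
              OTHER: CoachState.TRUNK_DISPLACEMENT}


@dataclass(frozen=True)
class CoachConfig:
    """Timing, geometry and detection parameters of the coach.

    ``th_pos``/``th_tg`` are the seconds after which the repositioning
    prompt repeats / the encouragement fires. ``position_rect`` is the
    image rectangle (x0, y0, x1, y1) the tracked joints must occupy.
    Target geometry and movement onset/stop detection are in body units
    (spine lengths) and body-units-per-second.
    """

    th_pos: float = 5.0
    th_tg: float = 10.0
    position_rect: tuple[float, float, float, float] = (40, 20, 600, 460)
    target_point: tuple[float, float] = (0.0, 1.1)
    target_radius: float = 0.15
    onset_speed: float = 0.2
    onset_frames: int = 3
    stop_frames: int = 15
    #: class priority when several labels fire in one frame
    class_priority: tuple[int, ...] = (TR, SE, TF)

    def __post_init__(self):
        if self.th_pos <= 0 or self.th_tg <= 0:
            raise ValueError("th_pos and th_tg must be positive")
        if self.target_radius <= 0:
            raise ValueError("target_radius must be positive")


@dataclass(frozen=True)
class ActionEvent:
    """One emitted coaching action (visual marker or speech-as-text)."""

    kind: str                 # "marker" | "speech"
    tag: str                  # e.g. "position_rect", "reposition"
    color: str | None = None  # markers only
    rule: int | None = None   # transition rule that produced it
    timestamp: float = 0.0

    def as_dict(self) -> dict:
        return {"kind": self.kind, "tag": self.tag, "color": self.color,
                "rule": self.rule, "timestamp": self.timestamp}


SPEECH = {
    "reposition": "Please move back into the rectangle.",
    "directions": "Well positioned! Follow the exercise instructions.",
    "repeat": "Let's repeat the movement.",
    "evaluate": "I'm watching your movement - try to reach the target.",
    "encourage": "Keep going, you can reach the target!",
    "praise": "Great job, you reached the target!",
    "correct_rotation": "Try not to rotate your trunk.",
    "correct_elevation": "Keep your shoulder relaxed and low.",
    "correct_displacement": "Keep your trunk still against the backrest.",
}


@dataclass(frozen=True)
class CoachObservation:
    """Per-frame booleans the state machine consumes."""

    positioned: bool = True
    moving: bool = False
    stopped: bool = False
    target_reached: bool = False
    compensation: int | None = None  # dominant label or None
    new_trial: bool = False


def dominant_class(labels: LabelSet,
                   priority: Sequence[int] = (TR, SE, TF)) -> int | None:
    """Pick the single compensation class the coach reacts to.

    Labels 0 and 3 both map onto trunk displacement; with several labels
    active the configured priority decides.
    """
    if labels.normal:
        return None
    present = set(labels.labels)
    for lab in priority:
        if lab == TF and present & {TF, OTHER}:
            return TF
        if lab in present:
            return lab
    return sorted(present)[0]


def observe(skel: Skeleton, labels: LabelSet, cfg: CoachConfig,
            wrist_speed: float = 0.0, *, affected_side: str = "right",
            spine_len: float | None = None,
            new_trial: bool = False) -> CoachObservation:
    """Derive the coach's booleans from one frame.

    ``positioned`` checks the tracked joints (spine + shoulders) against
    the placement rectangle in image coordinates; ``target_reached``
    checks the affected wrist against the target in body units (mid-hip
    origin, y up, spine-scaled); ``wrist_speed`` (body units/s) is
    compared against the onset threshold.
    """
    x0, y0, x1, y1 = cfg.position_rect
    track = list(body25.SPINE_JOINTS) + [body25.R_SHOULDER,
                                         body25.L_SHOULDER]
    pts = skel.xy[track]
    positioned = bool(np.all((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                             & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)))
    if spine_len is None:
        spine_len = float(np.linalg.norm(skel.point(body25.NECK)
                                         - skel.point(body25.MID_HIP)))
    wrist = skel.point(body25.wrist(affected_side))
    hip = skel.point(body25.MID_HIP)
    wrist_body = (wrist - hip) * np.array([1.0, -1.0]) / max(spine_len, 1e-9)
    target_reached = bool(np.linalg.norm(
        wrist_body - np.asarray(cfg.target_point)) <= cfg.target_radius)
    return CoachObservation(
        positioned=positioned,
        moving=wrist_speed > cfg.onset_speed,
        stopped=wrist_speed <= cfg.onset_speed,
        target_reached=target_reached,
        compensation=dominant_class(labels, cfg.class_priority),
        new_trial=new_trial)


def _marker(tag: str, color: str, rule: int, ts: float) -> ActionEvent:
    return ActionEvent("marker", tag, color=color, rule=rule, timestamp=ts)


def _speech(tag: str, rule: int, ts: float) -> ActionEvent:
    return ActionEvent("speech", tag, rule=rule, timestamp=ts)


def step(state: CoachState, obs: CoachObservation, elapsed: float,
         cfg: CoachConfig, ts: float = 0.0
         ) -> tuple[CoachState, list[ActionEvent]]:
    """One transition of the reflex agent.

    ``elapsed`` is the time in seconds spent in the current state (for
    the timed self-loop rules 1 and 7); ``ts`` stamps emitted events.
    Returns the next state and the actions of the rule that fired, in
    rule order. A step that matches no rule keeps the state silently.
    """
    S = CoachState
    # rule 2: losing the position preempts everything (not from o/e/tg)
    if not obs.positioned and state not in (S.OUT, S.EXERCISE, S.TARGET):
        return S.OUT, [_speech("reposition", 2, ts),
                       _marker("position_rect", "red", 2, ts)]
    if state is S.OUT:
        if obs.positioned:   # rule 3
            return S.IN, [_marker("position_rect", "green", 3, ts),
                          _speech("directions", 3, ts)]
        if elapsed > cfg.th_pos:   # rule 1
            return S.OUT, [_speech("reposition", 1, ts),
                           _marker("position_rect", "red", 1, ts)]
        return S.OUT, []
    if state is S.IN:
        if obs.moving:   # rule 4
            return S.EXERCISE, [_marker("target", "green", 4, ts)]
        return S.IN, []
    if state is S.EXERCISE:
        # rule 6: evaluation starts as soon as the trial is underway
        return S.NORMAL, [_speech("evaluate", 6, ts)]
    if state in ASSESSMENT_STATES:
        if obs.target_reached:   # rule 8
            return S.TARGET, [_speech("praise", 8, ts),
                              _marker("target", "blue", 8, ts)]
        if obs.stopped:   # rule 5
            return S.EXERCISE, [_speech("repeat", 5, ts)]
        nxt = (COMP_STATE[obs.compensation]
               if obs.compensation is not None else S.NORMAL)
        if nxt is not state:
            if nxt is S.TRUNK_ROTATION:   # rule 9
                return nxt, [_speech("correct_rotation", 9, ts),
                             _marker("trunk", "red", 9, ts)]
            if nxt is S.SHOULDER_ELEVATION:   # rule 10
                return nxt, [_speech("correct_elevation", 10, ts),
                             _marker("shoulder", "red", 10, ts)]
            if nxt is S.TRUNK_DISPLACEMENT:   # rule 11
                return nxt, [_speech("correct_displacement", 11, ts),
                             _marker("trunk", "red", 11, ts)]
            return nxt, []   # compensation ceased: silent return to n
        if elapsed > cfg.th_tg:   # rule 7
            return state, [_speech("encourage", 7, ts)]
        return state, []
    if state is S.TARGET:
        # absorbing until a new trial is signalled; re-enter via rule 4
        if obs.new_trial:
            return S.EXERCISE, [_marker("target", "green", 4, ts)]
        return S.TARGET, []
    raise ValueError(f"unknown state {state!r}")


@dataclass
class LogEntry:
    frame: int
    state: CoachState
    events: tuple[ActionEvent, ...]


class _WristTracker:
    """Movement onset/stop detection over the affected wrist trajectory."""

    def __init__(self, cfg: CoachConfig, fps: float):
        self.cfg = cfg
        self.fps = fps
        self.prev: np.ndarray | None = None
        self.above = 0
        self.below = 10**9

    def update(self, wrist_body: np.ndarray) -> tuple[float, bool, bool]:
        speed = 0.0
        if self.prev is not None:
            speed = float(np.linalg.norm(wrist_body - self.prev) * self.fps)
        self.prev = wrist_body.copy()
        if speed > self.cfg.onset_speed:
            self.above += 1
            self.below = 0
        else:
            self.above = 0
            self.below += 1
        moving = self.above >= self.cfg.onset_frames
        stopped = self.below >= self.cfg.stop_frames
        return speed, moving, stopped


def run(seq: RawSequence, labels: Sequence[LabelSet],
        cfg: CoachConfig | None = None,
        new_trial_frames: Iterable[int] = ()) -> list[LogEntry]:
    """Offline replay of the coaching loop over a labeled sequence.

    Wall-clock time is frame number / fps. Returns the deterministic
    (frame, state, events) timeline. ``labels`` must align 1:1 with the
    sequence frames.
    """
    if len(labels) != len(seq.frames):
        raise ValueError("labels misaligned with frames")
    if cfg is None:
        cfg = CoachConfig()
    new_trials = set(new_trial_frames)
    state = CoachState.OUT
    entered = 0.0
    last_timed = 0.0   # last rule-1/7 self-loop prompt
    tracker = _WristTracker(cfg, seq.fps)
    spine_len = None
    log: list[LogEntry] = []
    for frame, labelset in zip(seq.frames, labels):
        ts = frame.t / seq.fps
        skel = frame.skeletons[0]
        if spine_len is None:
            spine_len = float(np.linalg.norm(
                skel.point(body25.NECK) - skel.point(body25.MID_HIP)))
        hip = skel.point(body25.MID_HIP)
        wrist = skel.point(body25.wrist(seq.affected_side))
        wrist_body = (wrist - hip) * np.array([1.0, -1.0]) / spine_len
        speed, moving, stopped = tracker.update(wrist_body)
        obs = observe(skel, labelset, cfg, wrist_speed=speed,
                      affected_side=seq.affected_side, spine_len=spine_len,
                      new_trial=frame.t in new_trials)
        obs = CoachObservation(
            positioned=obs.positioned, moving=moving, stopped=stopped,
            target_reached=obs.target_reached,
            compensation=obs.compensation, new_trial=obs.new_trial)
        elapsed = ts - max(entered, last_timed)
        new_state, events = step(state, obs, elapsed, cfg, ts=ts)
        if any(e.rule in (1, 7) for e in events):
            last_timed = ts
        if new_state is not state:
            entered = ts
            last_timed = ts
        state = new_state
        log.append(LogEntry(frame=frame.t, state=state,
                            events=tuple(events)))
    return log
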