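"""Virtual-coach state machine: transition rules and the event log."""

import itertools

import numpy as np
import pytest

import compens2d as c2
from compens2d import body25
from compens2d.coach_fsm import (CoachObservation, CoachState,
                                 dominant_class)
from compens2d.labels import LabelSet

CFG = c2.CoachConfig()
S = CoachState


def obs(**kw):
    base = dict(positioned=True, moving=False, stopped=False,
                target_reached=False, compensation=None, new_trial=False)
    base.update(kw)
    return CoachObservation(**base)


class TestObserve:
    def _skel(self, wrist_body=(0.5, 0.5), inside=True):
        joints = np.zeros((25, 3))
        joints[:, 2] = 0.9
        hip = np.array([320.0, 340.0])
        spine = 100.0
        joints[body25.MID_HIP, :2] = hip
        joints[body25.NECK, :2] = hip + (0, -spine)
        joints[body25.NOSE, :2] = hip + (0, -1.3 * spine)
        for j in (body25.R_SHOULDER, body25.L_SHOULDER):
            joints[j, :2] = hip + (0, -0.9 * spine)
        if not inside:
            joints[body25.NOSE, :2] = (-50.0, 10.0)
        w = np.asarray(wrist_body) * spine
        joints[body25.R_WRIST, :2] = hip + (w[0], -w[1])
        return c2.Skeleton(joints)

    def test_wrist_at_target_point_reaches(self):
        skel = self._skel(wrist_body=CFG.target_point)
        o = c2.observe(skel, LabelSet.normal_set(), CFG,
                       affected_side="right")
        assert o.target_reached

    def test_wrist_far_from_target(self):
        skel = self._skel(wrist_body=(0.5, 0.2))
        o = c2.observe(skel, LabelSet.normal_set(), CFG,
                       affected_side="right")
        assert not o.target_reached

    def test_positioned_iff_tracked_joints_inside_rect(self):
        inside = c2.observe(self._skel(), LabelSet.normal_set(), CFG)
        outside = c2.observe(self._skel(inside=False),
                             LabelSet.normal_set(), CFG)
        assert inside.positioned and not outside.positioned

    @pytest.mark.parametrize(
        "labels", [frozenset(s) for r in range(5)
                   for s in itertools.combinations(range(4), r)])
    def test_dominant_class_matches_priority_oracle(self, labels):
        """Enumerate every label subset against a brute-force oracle:
        rotation > elevation > displacement; 0 and 3 both map to
        displacement."""
        got = dominant_class(LabelSet(labels), CFG.class_priority)
        if not labels:
            expected = None
        elif 1 in labels:
            expected = 1
        elif 2 in labels:
            expected = 2
        else:
            expected = 0
        assert got == expected


def events_sig(events):
    return [(e.kind, e.tag, e.color, e.rule) for e in events]


class TestStep:
    def test_becoming_positioned_enters_in(self):
        state, ev = c2.step(S.OUT, obs(), elapsed=1.0, cfg=CFG)
        assert state is S.IN
        assert events_sig(ev) == [("marker", "position_rect", "green", 3),
                                  ("speech", "directions", None, 3)]

    def test_rotation_detected_from_normal(self):
        state, ev = c2.step(S.NORMAL, obs(compensation=1), 1.0, CFG)
        assert state is S.TRUNK_ROTATION
        assert events_sig(ev) == [("speech", "correct_rotation", None, 9),
                                  ("marker", "trunk", "red", 9)]

    def test_lingering_in_normal_encourages(self):
        state, ev = c2.step(S.NORMAL, obs(), CFG.th_tg + 1, CFG)
        assert state is S.NORMAL
        assert events_sig(ev) == [("speech", "encourage", None, 7)]

    def test_compensation_ceasing_is_silent(self):
        state, ev = c2.step(S.TRUNK_ROTATION, obs(), 1.0, CFG)
        assert state is S.NORMAL
        assert ev == []

    def test_target_preempts_compensation(self):
        state, ev = c2.step(S.NORMAL, obs(target_reached=True,
                                          compensation=2), 1.0, CFG)
        assert state is S.TARGET
        assert ev[0].rule == 8

    def test_target_state_absorbs_until_new_trial(self):
        state, ev = c2.step(S.TARGET, obs(compensation=1), 99.0, CFG)
        assert state is S.TARGET and ev == []
        state, ev = c2.step(S.TARGET, obs(new_trial=True), 1.0, CFG)
        assert state is S.EXERCISE
        assert events_sig(ev) == [("marker", "target", "green", 4)]


GOLDEN_STREAM = [
    # (state before, observation, elapsed) — exercises rules 1..11
    (S.OUT, obs(positioned=False), 6.0),                     # rule 1
    (S.OUT, obs(), 0.5),                                     # rule 3
    (S.IN, obs(moving=True), 0.5),                           # rule 4
    (S.EXERCISE, obs(moving=True), 0.1),                     # rule 6
    (S.NORMAL, obs(compensation=1), 0.2),                    # rule 9
    (S.TRUNK_ROTATION, obs(compensation=2), 0.2),            # rule 10
    (S.SHOULDER_ELEVATION, obs(compensation=0), 0.2),        # rule 11
    (S.TRUNK_DISPLACEMENT, obs(positioned=False), 0.2),      # rule 2
    (S.OUT, obs(), 0.3),                                     # rule 3
    (S.IN, obs(moving=True), 0.3),                           # rule 4
    (S.EXERCISE, obs(), 0.1),                                # rule 6
    (S.NORMAL, obs(stopped=True), 0.4),                      # rule 5
    (S.EXERCISE, obs(moving=True), 0.1),                     # rule 6
    (S.NORMAL, obs(), 11.0),                                 # rule 7
    (S.NORMAL, obs(target_reached=True), 0.5),               # rule 8
]

GOLDEN_LOG = [
    (S.OUT, [("speech", "reposition", None, 1),
             ("marker", "position_rect", "red", 1)]),
    (S.IN, [("marker", "position_rect", "green", 3),
            ("speech", "directions", None, 3)]),
    (S.EXERCISE, [("marker", "target", "green", 4)]),
    (S.NORMAL, [("speech", "evaluate", None, 6)]),
    (S.TRUNK_ROTATION, [("speech", "correct_rotation", None, 9),
                        ("marker", "trunk", "red", 9)]),
    (S.SHOULDER_ELEVATION, [("speech", "correct_elevation", None, 10),
                            ("marker", "shoulder", "red", 10)]),
    (S.TRUNK_DISPLACEMENT, [("speech", "correct_displacement", None, 11),
                            ("marker", "trunk", "red", 11)]),
    (S.OUT, [("speech", "reposition", None, 2),
             ("marker", "position_rect", "red", 2)]),
    (S.IN, [("marker", "position_rect", "green", 3),
            ("speech", "directions", None, 3)]),
    (S.EXERCISE, [("marker", "target", "green", 4)]),
    (S.NORMAL, [("speech", "evaluate", None, 6)]),
    (S.EXERCISE, [("speech", "repeat", None, 5)]),
    (S.NORMAL, [("speech", "evaluate", None, 6)]),
    (S.NORMAL, [("speech", "encourage", None, 7)]),
    (S.TARGET, [("speech", "praise", None, 8),
                ("marker", "target", "blue", 8)]),
]


def run_stream(stream):
    log = []
    for state, o, elapsed in stream:
        new_state, ev = c2.step(state, o, elapsed, CFG)
        log.append((new_state, events_sig(ev)))
    return log


def test_golden_log_covers_all_eleven_rules():
    log = run_stream(GOLDEN_STREAM)
    assert log == GOLDEN_LOG
    fired = {sig[3] for _, evs in log for sig in evs}
    assert fired == set(range(1, 12))


def test_step_is_deterministic():
    assert run_stream(GOLDEN_STREAM) == run_stream(GOLDEN_STREAM)


def test_fuzz_states_and_rules_stay_within_the_tables(rng):
    """Random observation streams never leave the 8-state space and
    never emit an action outside rules 1-11."""
    state = S.OUT
    for _ in range(2000):
        o = obs(positioned=bool(rng.random() < 0.8),
                moving=bool(rng.random() < 0.5),
                stopped=bool(rng.random() < 0.2),
                target_reached=bool(rng.random() < 0.05),
                compensation=(None if rng.random() < 0.5
                              else int(rng.integers(0, 4))),
                new_trial=bool(rng.random() < 0.05))
        state, ev = c2.step(state, o, float(rng.uniform(0, 15)), CFG)
        assert state in set(S)
        for e in ev:
            assert 1 <= e.rule <= 11 or e.rule == 4
        if state is S.TARGET:
            # no compensation feedback can be emitted from target
            assert all(e.tag not in ("correct_rotation",
                                     "correct_elevation",
                                     "correct_displacement")
                       for e in ev)


def test_run_replays_a_labeled_sequence(static_sequence):
    seq, truth = static_sequence
    log = c2.run(seq, list(truth))
    assert len(log) == len(seq.frames)
    assert [e.frame for e in log] == seq.frame_numbers
    # deterministic pure function of its inputs
    log2 = c2.run(seq, list(truth))
    assert [(a.frame, a.state, tuple(events_sig(a.events)))
            for a in log] == [(b.frame, b.state,
                               tuple(events_sig(b.events))) for b in log2]


def test_run_rejects_misaligned_labels(static_sequence):
    seq, truth = static_sequence
    with pytest.raises(ValueError, match="misalign"):
        c2.run(seq, list(truth)[:-1])
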