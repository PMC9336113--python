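"""Rule-based multilabel compensation classifier.

Each compensation category has an independent if-then rule on one or two
kinematic variables against a tunable threshold; the union of fired
rules labels the frame, and an empty union means Normal. Thresholds are
the clinician-facing sensitivity dials; defaults were calibrated once on
the synthetic generator's geometry and are all configuration-exposed.

Frontal view (S1):

* trunk forward / backward — relative head-area change above ``th_tf``
  (toward the camera, label 0) or below ``-th_tf`` (away, label 3);
* rotation vs shoulder hike — with (1) the affected- and (2) the
  unaffected-shoulder angular displacement: only (1) above ``th_se``
  means shoulder elevation (2); both above with (1)−(2) ≈ 0 means trunk
  rotation (1); both above with (1)−(2) ≫ 0 means both. The printed "≈0"
  and "≫0" are made concrete by ``eps_eq``/``eps_gg`` (the gap between
  them maps to rotation-dominant {1});
* trunk tilt — spine sweep angle above ``th_o`` (label 3).

Side views (S2/S3): spine sweep above ``th_tf`` with the shoulder ahead
of (label 0) or behind (label 3) the neck; shoulder x-displacement (S2)
or absolute chest-length change (S3) above ``th_tr`` (label 1);
shoulder y-displacement above ``th_se`` (label 2); |ΔH| above ``th_ti``
(label 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .kinematics import KinematicSeries
from .labels import LabelSet, OTHER, SE, TF, TR


@dataclass(frozen=True)
class ThresholdSet:
    """Rule thresholds for one scenario.

    Units: degrees for angle rules, body units (spine lengths) for
    displacement rules, relative area for head-size rules.
    """

    th_tf: float
    th_tr: float
    th_se: float
    th_o: float
    th_ti: float
    eps_eq: float = 5.0
    eps_gg: float = 15.0

    def __post_init__(self):
        for name in ("th_tf", "th_tr", "th_se", "th_o", "th_ti",
                     "eps_eq", "eps_gg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.eps_gg > self.eps_eq:
            raise ValueError("eps_gg must exceed eps_eq")

    @classmethod
    def defaults(cls, scenario: str) -> "ThresholdSet":
        if scenario == "S1":
            return cls(th_tf=0.2, th_tr=0.0, th_se=10.0, th_o=10.0,
                       th_ti=0.2, eps_eq=5.0, eps_gg=15.0)
        if scenario in ("S2", "S3"):
            return cls(th_tf=10.0, th_tr=0.1, th_se=0.05, th_o=10.0,
                       th_ti=0.2, eps_eq=5.0, eps_gg=15.0)
        raise ValueError(f"unknown scenario {scenario!r}")


def classify_frame_s1(vars: Mapping[str, float], th: ThresholdSet,
                      *, trunk_priority: bool = False) -> LabelSet:
    """Apply the frontal-view rules to one frame's variable values."""
    labels = set()
    dh = vars["head_area_change"]
    if dh > th.th_tf:
        labels.add(TF)
    elif dh < -th.th_tf:
        labels.add(OTHER)
    a_aff = vars["shoulder_angle_affected"]
    a_un = vars["shoulder_angle_unaffected"]
    if a_aff > th.th_se and a_un < th.th_se:
        labels.add(SE)
    elif a_aff > th.th_se and a_un > th.th_se:
        labels.add(TR)
        if a_aff - a_un >= th.eps_gg:
            labels.add(SE)
    if vars["trunk_tilt_angle"] > th.th_o:
        labels.add(OTHER)
    return _finalize(labels, trunk_priority)


def classify_frame_s2s3(vars: Mapping[str, float], th: ThresholdSet,
                        scenario: str,
                        *, trunk_priority: bool = False) -> LabelSet:
    """Apply the side-view rules to one frame's variable values."""
    if scenario not in ("S2", "S3"):
        raise ValueError(f"side-view rules need S2/S3, got {scenario!r}")
    labels = set()
    if vars["spine_angle"] > th.th_tf:
        if vars["shoulder_x_disp"] > 0:
            labels.add(TF)
        elif vars["shoulder_x_disp"] < 0:
            labels.add(OTHER)
    if scenario == "S2":
        if vars["shoulder_x_disp"] > th.th_tr:
            labels.add(TR)
    else:
        if abs(vars["chest_len_change"]) > th.th_tr:
            labels.add(TR)
    if vars["shoulder_y_disp"] > th.th_se:
        labels.add(SE)
    if abs(vars["head_area_change"]) > th.th_ti:
        labels.add(OTHER)
    return _finalize(labels, trunk_priority)


def _finalize(labels: set, trunk_priority: bool) -> LabelSet:
    # optional mode addressing the known tilt-vs-hike confusion: a trunk
    # label suppresses shoulder elevation in the same frame
    if trunk_priority and SE in labels and labels & {TF, TR, OTHER}:
        labels.discard(SE)
    return LabelSet(frozenset(labels))


def classify_sequence(series: KinematicSeries,
                      th: ThresholdSet | None = None,
                      *, trunk_priority: bool = False) -> list[LabelSet]:
    """Per-frame rule evaluation over a whole kinematic series.

    A pure function of the frame's variables and the thresholds: no
    temporal smoothing of labels (the variables themselves are already
    smoothed upstream).
    """
    if th is None:
        th = ThresholdSet.defaults(series.scenario)
    out = []
    for _, row in series.values.iterrows():
        vars = row.to_dict()
        if series.scenario == "S1":
            out.append(classify_frame_s1(vars, th,
                                         trunk_priority=trunk_priority))
        else:
            out.append(classify_frame_s2s3(vars, th, series.scenario,
                                           trunk_priority=trunk_priority))
    return out
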