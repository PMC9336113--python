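# Methods

## Problem setting

A seated post-stroke patient performs upper-extremity reaching
exercises in front of a single RGB camera. A 2D pose estimator turns
each video frame into 25 body keypoints with detection confidences.
The task is frame-level multilabel classification: which compensation
patterns — trunk forward (0), trunk rotation (1), shoulder elevation
(2), other trunk patterns such as moving backward or tilting (3) — are
visible in the frame, with an exclusive Normal class (4) when none is.
Three camera placements are supported: frontal (S1) for the two
tabletop reaching exercises, and affected-side perpendicular (S2) or
oblique (S3) for the cane-pushing exercise.

## Normalization model

Working in pixels would confound body size and camera placement with
movement. Every skeleton is therefore translated so the mid-hip is the
origin, the y axis is flipped to up-positive, and all coordinates are
divided by the baseline spine length ‖neck − mid-hip‖. One body unit
is then one spine length, and all downstream quantities are invariant
to global translation and uniform scaling of the raw pixels (asserted
in the test suite). The transform is translation-only: with a level
camera the image axes already align with the patient's frontal plane,
and rotating into a spine-fixed frame would fold trunk tilt — a signal
we want to measure — into the reference frame itself. A
rotate-to-spine option exists (`scale_by_spine(rotate_to_spine=True)`)
but is off by default.

For the learned classifier only, x is additionally reflected when
needed so the affected limb always lies in the positive-x half-plane.
This gives left- and right-affected patients a common feature space.
The rule-based path never mirrors: its variables are all relative
displacements between named joints, so side is handled by resolving
"affected shoulder" to joint 2 or 5 from the sequence metadata.

## Kinematic variables

All variables are computed against a baseline pose and smoothed. Two
numerical choices matter:

* **Smoothing order.** The 5-frame centred moving average is applied
  to the keypoint *trajectories*, not to the derived series. The head
  area is the convex hull of five near-coplanar face points; hull area
  is a convex function of point noise, so unsmoothed noisy points
  produce a systematic upward bias that no amount of filtering of the
  derived series can remove. Smoothing positions first attacks the
  noise before the nonlinearity.
* **Baseline estimation.** "First-frame" quantities (baseline joint
  positions, baseline head area, baseline chest length) are the mean
  of the first five smoothed frames rather than a literal single
  frame. A single noisy baseline biases every relative series of the
  whole trial; the head-area *ratio* is worst, since its numerator and
  denominator noise do not cancel. On noiseless input the choice is a
  no-op. The first frames of a trial are assumed compensation-free
  (true of the synthetic scripts and of trials that start from the
  rest pose).

Frontal view: relative head-area change ΔHᵗ = (Hᵗ − H¹)/H¹ proxies
distance to the camera (trunk forward/backward); the angular
displacement of each shoulder about the baseline neck separates
rotation (both shoulders sweep, one up one down) from shoulder hiking
(only the affected one); the spine's sweep angle about the mid-hip
captures trunk tilt. Side views: the spine sweep angle plus the
shoulder's horizontal offset from the neck (sign = lean direction),
the shoulder's vertical offset from the neck (elevation), the observed
chest length |d(p₂, p₅)| whose foreshortening changes under axial
rotation (oblique view), and |ΔH| as the tilt fallback.

One notational interpretation is worth recording: the spine-sweep
quantities are computed with the **mid-hip as the angle vertex**
(baseline neck ray vs current neck ray). Putting the vertex at the
baseline neck instead — reading the operand order literally — yields
an angle between the spine and the neck's own displacement chord,
which is undefined at rest and jumps to ≈90° under infinitesimal
noise; the mid-hip vertex is the quantity the phrase "spine angular
displacement" describes and is 0 at rest. The head-area model itself
(convex hull over detected nose/eyes/ears, squared inter-eye distance
as a two-point fallback) is pluggable via `HeadModel`, since "head
area" admits several reasonable operationalizations.

In side views, horizontal displacements are multiplied by a facing
sign recorded in the sequence metadata, so "forward" is positive
regardless of whether the patient faces image-left or image-right.

## Rule thresholds

Defaults (all exposed in `ThresholdSet`, the clinician's sensitivity
dials):

| threshold | S1 | S2/S3 | units |
|---|---|---|---|
| th_tf | 0.20 | 10 | rel. area / degrees |
| th_tr | — | 0.10 | body units |
| th_se | 10 | 0.05 | degrees / body units |
| th_o  | 10 | — | degrees |
| th_ti | — | 0.20 | rel. area |
| eps_eq / eps_gg | 5 / 15 | — | degrees |

They were calibrated once against the synthetic generator's geometry
(each value sits well above the smoothed noise floor of its variable
at 2 px pixel noise and well below the magnitude-2 episode plateau).
`eps_eq`/`eps_gg` make the frontal rotation-vs-elevation distinction
concrete: both shoulders above `th_se` with an angle difference within
`eps_eq` is pure rotation; a difference of at least `eps_gg` means
rotation plus a genuine hike of the affected shoulder; the gap between
the two maps to rotation-dominant, keeping the rule total. The
difference is used absolutely for the ≈0 branch and signed for the
≫0 branch. This compound rule is deliberately not monotone in
`th_se` (raising it can reclassify rotation as elevation); the
single-variable rules are monotone and property-tested as such.

An optional `trunk_priority` mode suppresses the shoulder-elevation
label whenever a trunk label fires in the same frame — a guard against
the known failure mode of reading trunk tilt as shoulder elevation —
and is off by default.

## Two-stage neural classifier

Normal frames dominate every recording, and rare patterns may come
from a single patient. The learned path therefore splits the problem:
C1, a binary MLP (ReLU), gates frames into compensation / Normal; C2,
a one-vs-rest battery of MLPs (tanh) trained **only on compensation
frames**, identifies the patterns. Both use Adam, mini-batches of 5,
at most 550 epochs, and an adaptive learning rate, via scikit-learn's
`MLPClassifier`. Per-exercise default architectures: E1 gate 1×16 @
1e-3 with identifier 1×64 @ 1e-3; E2 1×16 @ 1e-3 and 1×16 @ 1e-2; E3
1×96 @ 1e-2 and 1×16 @ 1e-3 (selected by grid search over 1–3 layers,
16–512 units, learning rates 1e-4–0.1; the grid constants are exposed
but the search is not rerun by default). Features are the raw
normalized, mirrored coordinates of nine keypoints (spine, both
shoulders, affected elbow and wrist, both hips) — 18 columns in a
fixed, documented order; confidences are never features. A
gated-positive frame takes every label scoring ≥ 0.5; if none does,
the top-scoring label is assigned, so the gate's verdict is never
contradicted. Class imbalance is not reweighted by default (a
class-weight switch exists), matching the plain one-vs-rest training
the approach is defined with.

## Evaluation

Metrics are micro-averaged over the 5-slot one-hot space: precision
ΣTP/(ΣTP+ΣFP), recall ΣTP/(ΣTP+ΣFN), F1 their harmonic mean, and
Hamming loss (ΣFP+ΣFN)/(N·L) with L = 5. The Normal slot participates
in the counters — an all-Normal prediction is scored, not skipped —
which is the main comparability caveat when relating these numbers to
published figures that may have pooled only compensation labels.
Zero-division returns 0 with a warning. Cross-validation is
leave-one-subject-out (one fold per subject; the held-out subject
contributes no training frames) and leave-one-exercise-out across the
two frontal exercises; fold metrics are averaged unweighted. Dataset
structure is summarized by P_min (fraction of single-label frames) and
IRLbl (modal-label count over each label's count; modal = 1, rare ≫ 1).

## Synthetic benchmark

The patient videos this class of system is developed on cannot be
redistributed, so the generator emulates the statistical structure the
classifiers assume: a 2D articulated stick figure of a seated subject
(no 3D renderer — every consumer sees only 2D keypoints), per-subject
geometry drawn from webcam-plausible ranges (spine 120–170 px,
placement jitter, alternating affected side), a smooth reach-return
wrist trajectory as benign task motion, and scripted compensation
episodes realized as geometric effects on exactly the joints each
rule measures:

* trunk forward: head-point spread scaled about its centroid (frontal)
  / spine rotation about the mid-hip with the shoulder girdle carried
  slightly ahead of the neck (side);
* rotation: opposed rotations of both shoulders about the neck
  (frontal) / horizontal shift of the visible shoulder (side);
* elevation: rotation of the affected shoulder about the neck
  (frontal) / vertical raise of the visible shoulder (side);
* other: spine tilt toward the affected side or head-area shrink
  (frontal) / backward lean or head-size change (side).

Episode magnitude is expressed in multiples of the matched rule
threshold: magnitude m drives the rule's variable to exactly m× its
threshold at plateau. Episodes are **square steps** by default. With
the 5-frame centred smoother, a magnitude-2 step crosses the threshold
exactly at the labeled boundary (3 of 5 window samples on the plateau
give 1.2×, 2 of 5 give 0.8×), so on noiseless data the rule-based
classifier reproduces the ground truth frame-for-frame — the property
that makes the generator an independent oracle. A linear on/offset
ramp is available (`CompensationScript(ramp=...)`) for exercising
smoothing behaviour at episode edges, at the cost of that exactness.
Default scripts place episodes non-overlapping with ≥ 5-frame gaps and
an episode-free first ~10 frames (the baseline window); overlapping
episodes are supported and compose additively.

Noise model: isotropic Gaussian pixel noise (benchmark condition
σ = 2 px) on every keypoint, confidence 0.9 ± 0.05. Artifact injection
adds ghost skeletons (zero spine confidence), a bystander (a scaled
copy placed far off-centre, so centre-based selection still resolves),
and confidence dropouts below the 0.36 filter on relevant joints —
dropouts alter only confidences, never positions, which is what makes
the cleansing round-trip exactly checkable.

What passing these benchmarks shows: the pipeline's geometry, rules,
training loop, metrics and state machine are internally consistent and
noise-robust at webcam-scale jitter. What it does not show: real
post-stroke kinematic signatures (tremor, segmented reaches,
patient-specific baselines), real pose-estimator error structure
(correlated, heavy-tailed, occlusion-driven), or annotator
disagreement. Published frame-level F1 on real patient data sits in
the 0.6–0.8 band; the synthetic scores here are upper bounds by
construction, not comparable estimates.

## Virtual coach

A reflex agent: action depends only on the previous state, the
current observation and elapsed time. The 8 states and 11
transition-rule actions are listed in `coach_fsm`'s module docstring.
Parameters the original description names but does not fix were set
as: repositioning re-prompt `th_pos` = 5 s; encouragement `th_tg` =
10 s; target reached = affected wrist within 0.15 body units of the
target point; movement onset = wrist speed above 0.2 body units/s for
3 consecutive frames; stop = below it for 15 frames. Transitions with
no attached rule (compensation ceasing, tr→n) update the state
silently. The target state absorbs until an explicit `new_trial`
signal, which re-enters the exercise state with the rule-4 action
(fresh target marker). When several compensation labels fire at once
the coach reacts to one class, priority rotation > elevation >
displacement (configurable); labels 0 and 3 both map to the
trunk-displacement state. Speech is emitted as text tags with a
subtitle string table; audio synthesis, the web UI and remote
deployment are out of scope.

## Problem sizes

Default benchmark: 6 subjects × 10 trials × 120 frames (7 200 frames)
per exercise for the recovery and cross-validation runs; 3 × 4 × 100
for the fast in-suite neural tests; 1 000 random prediction pairs of
500 frames for the metric-oracle check. These sizes were chosen so the
full pipeline, including fold-wise MLP training, runs comfortably on a
single CPU while keeping per-fold label counts large enough that F1
differences of a few points are meaningful.

## Known limitations

* The head-area proxy is the weakest variable: five near-coplanar
  face points make a small, flat hull whose relative area is noisy;
  in profile views doubly so. Its thresholds (th_tf frontal, th_ti
  side) are correspondingly the least transferable to real detectors.
* Thresholds are population-level; no per-patient personalization.
* The rule set evaluates frames independently — no temporal label
  smoothing, no hysteresis — so borderline episodes can flicker.
* The LOEO harness assumes the two exercises share a camera scenario;
  it refuses otherwise rather than attempting cross-scenario feature
  alignment.
* Sequence-level models (RNNs, temporal convolutions) and velocity /
  smoothness metrics are out of scope.
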