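# compens2d

Frame-level assessment of **compensatory motion** in upper-extremity
stroke rehabilitation from plain 2D video keypoints — the sensing a
laptop webcam plus an off-the-shelf pose estimator can provide, with no
depth camera or marker setup.

After a stroke, patients often complete a reaching task by recruiting
extra body segments: leaning the trunk forward, rotating it, hiking the
shoulder. Detecting these *compensation patterns* in real time is what
lets an unsupervised home-exercise system give corrective feedback
instead of silently reinforcing bad movement. `compens2d` implements
the full pipeline for therapists' tooling and movement-analysis
research:

* **pose I/O** — per-frame BODY_25 keypoint JSON (25 joints, each
  `(x, y, s)` with detection confidence `s`) and a diff-able CSV
  sequence format;
* **cleansing** — removal of ghost skeletons (no detected spine
  joints), centre-of-image patient selection in multi-person frames,
  and a confidence frame filter (relevant joints must exceed
  `s > 0.36`, all others `s > 0`);
* **normalization** — translation to a body frame `{B}` with the
  mid-hip as origin and y up, scaling by the baseline spine length
  `d¹(p₁, p₈)`, and (for the learned classifier only) mirroring so the
  affected limb always lies at positive x;
* **kinematics** — per-frame variables per camera scenario (frontal S1,
  affected-side perpendicular S2 / oblique S3): relative head-area
  change ΔHᵗ, shoulder angular displacements `aᵗ(p¹₂/₅, p¹₁, pᵗ₂/₅)`,
  spine sweep angle, shoulder displacements Δxᵗ/Δyᵗ relative to the
  neck, and chest-length change |Δdᵗ(p₂, p₅)|, all smoothed with a
  5-frame moving average;
* **classifiers** — a transparent rule-based (RB) multilabel classifier
  (one threshold rule per compensation category: trunk forward `Y=0`,
  trunk rotation `Y=1`, shoulder elevation `Y=2`, other `Y=3`; no rule
  firing means Normal `Y=4`) and a two-stage neural approach (binary
  compensation gate C1, one-vs-rest multilabel identifier C2 — small
  MLPs trained with Adam, batch 5, ≤ 550 epochs);
* **evaluation** — micro-averaged precision/recall/F1 and Hamming loss
  over the 5-slot one-hot space, dataset statistics (P_min, per-label
  imbalance ratio IRLbl), and leave-one-subject-out (LOSO) /
  leave-one-exercise-out (LOEO) cross-validation;
* **virtual coach** — an 8-state reflex agent
  (out/in/exercise/normal/rotation/elevation/displacement/target) with
  11 transition rules emitting marker and speech events;
* **synthetic data** — a scripted stick-figure generator producing
  labeled multi-subject benchmarks with compensation episodes, pixel
  noise, confidence dropouts, ghost skeletons and bystanders. Episode
  magnitudes are expressed in multiples of the matched rule threshold,
  which makes the generator's ground truth an exact oracle for the
  rule-based path on noiseless data.

Clinical video of this population cannot be redistributed, so the
package is developed and validated entirely against this synthetic
benchmark; see `docs/methods.md` for what that does and does not
establish about real recordings.

## Worked example

`examples/01_rule_based_assessment.py` builds one noiseless frontal
trial with one scripted episode per category and runs the rule-based
pipeline:

```
frames assessed : 150
micro F1        : 1.000
Hamming loss    : 0.000
  frame  15: normal
  frame  30: trunk_forward
  frame  60: trunk_rotation
  frame  90: shoulder_elevation
  frame 120: other
```

Micro F1 of 1.000 against the generator's ground truth means every
episode was recovered on exactly the frames it was injected into —
with magnitude-2 episodes and the 5-frame smoothing window, detection
switches precisely at the episode boundaries. The other examples cover
the two-stage classifier under LOSO (`02`), the virtual-coach event
timeline (`03`) and artifact cleansing (`04`); each prints its numbers
with a closing line on how to read them.

A thin CLI mirrors the library:

```sh
compens2d simulate --subjects 6 --exercise E1 --trials 10 --seed 7 --out data/
compens2d assess --in data/P01_trial00.csv --out labels.csv
compens2d coach --in data/P01_trial00.csv --labels labels.csv --out events.jsonl
compens2d evaluate --method nn --exercise E1 --seed 7 --out result.json
```

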