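"""Scripted compensation episodes, recovered by the kinematic rules.

Builds one noiseless frontal-view trial of a synthetic seated subject
with one episode of each compensation category, runs the full
rule-based pipeline (cleansing -> body-frame normalization -> kinematic
variables -> threshold rules) and compares the per-frame labels with
the generator's ground truth.
"""

import compens2d as c2

template = c2.SubjectTemplate(scenario="S1", affected_side="right",
                              noise_sigma=0.0)
script = c2.CompensationScript(episodes=(
    c2.Episode(label=c2.TF, start=20, end=40),      # trunk forward
    c2.Episode(label=c2.TR, start=50, end=70),      # trunk rotation
    c2.Episode(label=c2.SE, start=80, end=100),     # shoulder elevation
    c2.Episode(label=c2.OTHER, start=110, end=130,  # trunk tilt
               mode="tilt"),
))
sequence, truth = c2.generate_sequence(template, script, n_frames=150,
                                       seed=11)

result = c2.assess_rb(sequence)
metrics = c2.mlc_metrics_labelsets(list(truth), result.labels)

print(f"frames assessed : {len(result.labels)}")
print(f"micro F1        : {metrics.f1:.3f}")
print(f"Hamming loss    : {metrics.hamming:.3f}")
for t in (15, 30, 60, 90, 120):
    ls = result.labels[t - 1]
    name = ("normal" if ls.normal
            else "+".join(c2.labels.LABEL_NAMES[l]
                          for l in sorted(ls.labels)))
    print(f"  frame {t:3d}: {name}")
print("An F1 of 1.000 means every scripted episode was recovered on "
      "exactly the frames it was injected into; noiseless magnitude-2 "
      "episodes are detected without edge error.")
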