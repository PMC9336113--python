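"""Replaying the virtual coach over a labeled trial.

Generates a trial with a shoulder-elevation episode, labels it with the
rule-based classifier, and feeds frames + labels through the 8-state
reflex agent. The printed timeline shows the coach positioning the
patient, starting the exercise, correcting the compensation and (if the
reach succeeds) praising the patient.
"""

import compens2d as c2

template = c2.SubjectTemplate(scenario="S1", affected_side="right",
                              noise_sigma=0.0)
script = c2.CompensationScript(episodes=(
    c2.Episode(label=c2.SE, start=30, end=55),))
sequence, _ = c2.generate_sequence(template, script, n_frames=90, seed=7)

labels = c2.assess_rb(sequence).labels
log = c2.run(sequence, labels, c2.CoachConfig(target_point=(0.0, 1.05),
                                              target_radius=0.1))

for entry in log:
    for event in entry.events:
        detail = f" [{event.color}]" if event.color else ""
        print(f"t={entry.frame:3d} ({entry.state.value:>2}) "
              f"rule {event.rule:2d}: {event.kind} {event.tag}{detail}")
print("Each line is one emitted coaching action: markers drive the "
      "on-screen overlay, speech tags index the subtitle/audio table.")
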