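"""Generate a small synthetic two-group EEG cohort and look inside it.

Builds a reduced version of the default cohort (64 channels, 500 Hz, 2 s
epochs; patients carry a delta-band disconnection), then prints the shapes
and a couple of cognitive scores.
"""

import eegraph as eg

spec = eg.CohortSpec(
    n_controls=3, n_patients=2,
    bands=(eg.BAND_MAP["delta"],),
    epochs_per_subject=6,
    seed=1,
)
subjects = eg.generate_cohort(spec)

for s in subjects:
    rec = s.recording
    print(
        f"{s.subject_id} ({s.group}): {rec.n_epochs} epochs x "
        f"{rec.n_channels} channels x {rec.n_samples} samples @ "
        f"{rec.sampling_rate:g} Hz"
    )
first = subjects[0]
print(
    "cognitive scores (subject %s): ONB=%.3f OCL=%.3f"
    % (first.subject_id, first.cognitive_scores["ONB"],
       first.cognitive_scores["OCL"])
)
print(
    "ONB/OCL are accuracy-type cognition subtests; controls are drawn with "
    "higher means than patients, mirroring the cohort the generator emulates."
)
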