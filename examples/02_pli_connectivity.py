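"""Phase-lag-index connectivity of one synthetic subject.

Band-pass filters the subject's epochs into the delta band, extracts
analytic phases, averages per-epoch PLI matrices, and summarises the
matrix globally and by region.
"""

import eegraph as eg

spec = eg.CohortSpec(
    n_controls=1, n_patients=0,
    bands=(eg.BAND_MAP["delta"],),
    epochs_per_subject=8,
    seed=2,
)
subject = eg.generate_cohort(spec)[0]

# artifact rejection (nothing exceeds 100 amplitude units here)
clean, dropped = eg.reject_artifacts(subject.recording, threshold=100.0)
print(f"artifact rejection dropped {dropped} of {subject.recording.n_epochs} epochs")

cm = eg.subject_connectivity(clean, eg.BAND_MAP["delta"])
roi = eg.DEFAULT_ROI_MAP

print(f"global average delta PLI: {eg.global_average_pli(cm):.4f}")
print(f"regional average PLI, right frontal (RF): "
      f"{eg.regional_pli(cm, roi, 'RF'):.4f}")
print(f"regional PLI, RF <-> right parietal (RP): "
      f"{eg.regional_pli(cm, roi, 'RF', 'RP'):.4f}")
print(f"regional PLI, RP <-> occipital (O):       "
      f"{eg.regional_pli(cm, roi, 'RP', 'O'):.4f}")
print(
    "PLI in [0, 1] measures consistently lagged synchrony; the RF row sits "
    "above the uncoupled baseline because the generator plants regional and "
    "fronto-parietal coupling there."
)
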