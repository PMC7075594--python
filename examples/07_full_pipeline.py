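"""The whole chain on a reduced synthetic cohort.

Cohort synthesis -> artifact rejection -> delta-band PLI -> graph and MST
topology -> gated permutation batteries -> three stepwise LDA models
(cognitive / EEG / combined) with LOOCV.  Runs in about a minute; the
study-scale run (90 epochs, five bands) uses the same call with the
default spec.
"""

import eegraph as eg

spec = eg.CohortSpec(
    n_controls=14, n_patients=8,
    bands=(eg.BAND_MAP["delta"],),
    epochs_per_subject=8,
    seed=6,
)
subjects = eg.generate_cohort(spec)
config = eg.PipelineConfig(
    bands=("delta",), n_perm=5000, n_null_graphs=20, seed=6
)
result = eg.analyze_cohort(subjects, config)

ctrl = result.labels == "control"
print("group means, global delta PLI: control %.4f, patient %.4f"
      % (result.global_pli.loc[ctrl.values, "delta"].mean(),
         result.global_pli.loc[(~ctrl).values, "delta"].mean()))
print("connectivity gate passed bands:", list(result.connectivity_report.passed_bands))
print("topology (dissimilarity) gate passed bands:",
      list(result.topology_report.passed_bands))
print("significant cognitive subtests:", result.cognitive_significant)
for name, (sel, rep) in result.models.items():
    print(f"model {name:9s}: features={sel.selected or '(null model)'} "
          f"accuracy={rep.accuracy:.3f} sensitivity={rep.sensitivity:.3f} "
          f"specificity={rep.specificity:.3f}")
print(
    "The patient arm was generated with weakened delta coupling, so its "
    "global PLI mean should sit below the controls'; cognitive subtests "
    "separate strongly by construction, and the combined model draws on "
    "both domains."
)
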