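"""Run the full synthetic modality-comparison study at desk scale.

For each synthetic patient: one phantom, three modality scans, three
reconstructions (DM / CM / MM for rotational-, CT- and MR-angiography-like
imaging), one shared WSS field mapped onto each model, then per-parameter
percent differences against the reference model DM with paired Wilcoxon
tests, and surface-distance statistics.
"""

from aneumorph import StudyConfig, run_study

config = StudyConfig(n_patients=3, master_seed=42)
result = run_study(config)
print(f"patients completed: {len(result.triplets)}, failures: {result.failures}")

summary = result.tables["summary"]
print("\nmean percent difference vs the reference model (mean ± SE, "
      "paired Wilcoxon p):")
for _, row in summary.iterrows():
    print(f"  {row.parameter:8} {row.comparison}: "
          f"{row.mean_delta_pct:5.1f} ± {row.se_delta_pct:4.1f} %   "
          f"p = {row.wilcoxon_p:.3f}")

print("\nsurface distance to the reference model (mm):")
print(result.tables["surface_distance"].to_string(index=False))
print("\nA larger percent difference means that modality's model deviates "
      "more from the\nrotational-angiography reference; hemodynamic "
      "parameters typically deviate more\nthan morphological ones.")
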