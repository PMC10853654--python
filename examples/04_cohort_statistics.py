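"""Regenerate the packaged 39-patient cohort and run the full analysis.

The packaged roster realizes the categorical structure of a posterior
cortex epilepsy surgical series (24 single / 9 multiple / 6 scattered
patients, 21 seizure-free).  Everything below — dipole tables, masks,
findings — is regenerated from the roster, pushed through the whole
pipeline, and summarized with exact contingency tests.

Takes about a minute (it fits ~250 dipoles).
"""

import epimeg

config = epimeg.study_cohort_config(noise_sd=0.0, seed=1)
patients, truth, parcellation = epimeg.generate_cohort(config)
scored = epimeg.score_cohort(patients, parcellation)
report = epimeg.run_study_analyses(scored)

s = report.summary
print(f"cohort: {s['n_patients']} patients, {s['n_seizure_free']} seizure-free")
print(f"patterns: {s['pattern_counts']}  ({s['pattern_percent']})")
print()
for name in ("single_vs_rest", "resection_within_single", "meg_mri",
             "seeg_sampling", "mri_resection_discordant_subgroup"):
    c = report[name]
    pcts = [f"{v:.1f}%" for v in 100 * c.table.row_proportions()]
    print(f"{name:35s} {c.table.counts.tolist()} seizure-free {pcts}"
          f"  p={c.p_reported:.3f} ({c.reported_convention})")
print()
print("Reading: complete resection of a single dipole cluster carries an")
print("83.3% seizure-free rate against 16.7% for incomplete resection")
print("(exact p ~ 0.007); MEG-MRI concordance and the MRI-discordant")
print("subgroup show the same direction of effect.")
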