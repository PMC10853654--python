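# epimeg

MEG dipole-cluster analysis for presurgical evaluation of posterior cortex
epilepsy, implemented end to end on synthetic data.

Posterior cortex epilepsy (seizures arising from occipital, parietal or
posterior temporal cortex) is hard to localize: scalp EEG is ambiguous over
the posterior quadrant and MRI is often negative. Magnetoencephalography
contributes by fitting an **equivalent current dipole (ECD)** to each
interictal spike and reading the spatial arrangement of the accepted
dipoles as a localization hypothesis. This package implements that whole
quantitative chain for researchers who want to study, stress-test or teach
the method without access to patient recordings:

1. **Forward model** — the magnetic field of a current dipole `Q` at `r0`
   in a spherically symmetric conductor (Sarvas closed form),

   `B(r) = μ0/(4πF²) · (F Q×r0 − (Q×r0 · r) ∇F)`,

   with `F = a(ra + r² − r0·r)`, `a = r − r0`, measured by a configurable
   helmet of radial magnetometers. Radial dipoles are externally silent —
   the property the tests verify to 1e-10.
2. **Inverse fit** — single-ECD fitting by coarse grid search plus local
   refinement, with the moment solved linearly at each position;
   `GOF = 1 − Σ(b−b̂)²/Σb²`, and only dipoles with GOF > 0.85 are kept.
3. **Pattern classification** — accepted dipoles are grouped by
   single-linkage at 10 mm (a cluster needs ≥ 5 dipoles) and judged against
   a gyral parcellation: one cluster within one gyrus or two adjacent gyri
   is a *single cluster*; clusters in non-adjacent gyri are *multiple
   clusters*; everything else is *scattered*.
4. **Surgical scoring** — *complete resection* means every cluster dipole
   lies within 1 cm of the resection volume (distance-transform based);
   concordance with MRI/PET/interictal EEG is scored at the lobar level and
   with SEEG at the gyral level (electrode sampling and seizure-onset-zone
   overlap).
5. **Exact statistics** — Fisher's exact test (one- and two-sided, by
   hypergeometric enumeration with exact integer weights) and the 2×K
   Freeman–Halton generalization, applied to every outcome table the study
   design defines.
6. **Synthetic cohorts** — a generator that plants dipole clouds,
   simulates noisy spike topographies, builds resection masks and modality
   findings from a declarative per-patient roster. The packaged roster
   realizes a 39-patient surgical series (24 single / 9 multiple /
   6 scattered; 21 seizure-free) whose every association table is
   reproduced by the pipeline.

## Worked example

```bash
python examples/04_cohort_statistics.py
```

prints (abridged):

```
cohort: 39 patients, 21 seizure-free
patterns: {'single_cluster': 24, 'multiple_clusters': 9, 'scattered': 6}  ({'single_cluster': 61.5, 'multiple_clusters': 23.1, 'scattered': 15.4})

single_vs_rest                      [[16, 8], [5, 10]] seizure-free ['66.7%', '33.3%']  p=0.044 (one_sided)
resection_within_single             [[15, 3], [1, 5]] seizure-free ['83.3%', '16.7%']  p=0.007 (two_sided)
meg_mri                             [[16, 8], [5, 10]] seizure-free ['66.7%', '33.3%']  p=0.044 (one_sided)
seeg_sampling                       [[4, 3], [0, 6]] seizure-free ['57.1%', '0.0%']  p=0.070 (two_sided)
mri_resection_discordant_subgroup   [[8, 2], [4, 10]] seizure-free ['80.0%', '28.6%']  p=0.018 (one_sided)
```

Reading the first two rows: patients whose MEG shows a single dipole
cluster are seizure-free in 16/24 cases against 5/15 otherwise (exact
p = 0.044), and within the single-cluster group complete resection of the
cluster carries an 83.3% seizure-free rate against 16.7% for incomplete
resection (exact p = 0.007). The other examples
(`01_forward_and_fit.py`, `02_classify_patterns.py`,
`03_resection_concordance.py`) each demonstrate one stage in isolation.

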