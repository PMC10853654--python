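"""Score resection completeness and multimodal concordance for one patient.

A single-cluster localization counts as completely resected when every
cluster dipole lies within 10 mm of the resection volume; multiple or
scattered localizations are noncomplete by definition.  Concordance with
MRI/PET/EEG is judged at the lobar level.
"""

import numpy as np

import epimeg

parcellation = epimeg.generate_parcellation()
sources, gyri = epimeg.plant_dipole_pattern("single", parcellation, seed=11)
result = epimeg.classify_pattern(list(sources), parcellation)

for status in ("complete", "noncomplete"):
    mask = epimeg.generate_resection(sources, status, parcellation, seed=1)
    scored = epimeg.resection_completeness(result, list(sources), mask)
    dmax = float(np.max(mask.distance_to([s.position for s in sources])))
    print(f"mask built as {status:11s}: scored {scored:11s} "
          f"(max dipole-to-mask distance {dmax:.1f} mm)")

meg_lobes = result.meg_lobes
mri = epimeg.ModalityFinding("MRI", frozenset(meg_lobes))
pet = epimeg.ModalityFinding("PET", frozenset({"non_posterior"}))
print()
print(f"MEG lobes {sorted(meg_lobes)}")
print(f"  vs MRI {sorted(mri.lobes)}: {epimeg.lobar_concordance(meg_lobes, mri)}")
print(f"  vs PET {sorted(pet.lobes)}: {epimeg.lobar_concordance(meg_lobes, pet)}")
print(f"  vs both jointly: {epimeg.combined_concordance(meg_lobes, [mri, pet])}")
print()
print("The 10-mm border tolerance is what turns 'all dipoles inside or near")
print("the cavity' into 'complete'; joint concordance requires agreement")
print("with every listed modality at once.")
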