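"""Plain-text serialization of cohort data.

Formats:

* dipoles.tsv — one fitted dipole per row: x_mm y_mm z_mm qx qy qz gof
  [spike_id]; also used for planted true sources.
* topographies.tsv — channel index and value_fT, one spike per file.
* findings.json — modality -> lobe list (MRI/PET/interictal_EEG; absent
  PET omitted) plus optional SEEG block (contacts + SOZ region ids).
* resection mask — either NIfTI (.nii) or a documented JSON voxel-list
  dialect: {"shape", "affine", "voxels"} with voxels the sorted [i,j,k]
  index triples of the mask.  The JSON form is bit-exact and diffable.
* patients.csv — one row of clinical metadata per patient.

``write_cohort``/``read_cohort`` lay a cohort out as one directory per
patient under a root, with patients.csv at the top.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .concordance import ModalityFinding, ResectionMask, SEEGData
from .dipoles import CurrentDipole, FieldTopography

__all__ = [
    "write_dipoles_tsv", "read_dipoles_tsv",
    "write_topography_tsv", "read_topography_tsv",
    "write_mask_json", "read_mask_json",
    "write_mask_nifti", "read_mask_nifti",
    "write_findings_json", "read_findings_json",
    "write_cohort", "read_cohort",
]

_DIPOLE_COLUMNS = ["x_mm", "y_mm", "z_mm", "qx", "qy", "qz", "gof", "spike_id"]


def write_dipoles_tsv(dipoles: Sequence[CurrentDipole], path) -> None:
    rows = [
        list(d.position) + list(d.moment) + [d.gof, d.spike_id] for d in dipoles
    ]
    pd.DataFrame(rows, columns=_DIPOLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dipoles_tsv(path) -> list[CurrentDipole]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            CurrentDipole(
                position=np.array([r["x_mm"], r["y_mm"], r["z_mm"]]),
                moment=np.array([r["qx"], r["qy"], r["qz"]]),
                gof=float(r["gof"]),
                spike_id="" if pd.isna(r.get("spike_id")) else str(r["spike_id"]),
            )
        )
    return out


def write_topography_tsv(topo: FieldTopography, path) -> None:
    pd.DataFrame(
        {"channel": np.arange(topo.n_channels), "value_fT": topo.values}
    ).to_csv(path, sep="\t", index=False)


def read_topography_tsv(path, spike_id: str = "") -> FieldTopography:
    df = pd.read_csv(path, sep="\t").sort_values("channel")
    return FieldTopography(values=df["value_fT"].to_numpy(), spike_id=spike_id)


def write_mask_json(mask: ResectionMask, path) -> None:
    voxels = np.argwhere(mask.mask)
    payload = {
        "shape": list(mask.mask.shape),
        "affine": mask.affine.tolist(),
        "voxels": voxels[np.lexsort(voxels.T[::-1])].tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_mask_json(path) -> ResectionMask:
    payload = json.loads(Path(path).read_text())
    m = np.zeros(tuple(payload["shape"]), dtype=bool)
    idx = np.asarray(payload["voxels"], dtype=int)
    if idx.size:
        m[tuple(idx.T)] = True
    return ResectionMask(mask=m, affine=np.asarray(payload["affine"]))


def write_mask_nifti(mask: ResectionMask, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_mask_nifti(path) -> ResectionMask:
    import nibabel as nib

    img = nib.load(str(path))
    return ResectionMask(
        mask=np.asarray(img.dataobj).astype(bool), affine=np.asarray(img.affine)
    )


def write_findings_json(
    findings: dict[str, ModalityFinding], seeg: SEEGData | None, path
) -> None:
    payload: dict = {
        name: sorted(f.lobes) for name, f in findings.items()
    }
    if seeg is not None:
        payload["SEEG"] = {
            "contacts": np.round(seeg.contact_positions, 4).tolist(),
            "soz_regions": sorted(seeg.soz_regions),
            "sampling_radius": seeg.sampling_radius,
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_findings_json(path) -> tuple[dict[str, ModalityFinding], SEEGData | None]:
    payload = json.loads(Path(path).read_text())
    seeg = None
    if "SEEG" in payload:
        block = payload.pop("SEEG")
        seeg = SEEGData(
            contact_positions=np.asarray(block["contacts"]),
            soz_regions=frozenset(block["soz_regions"]),
            sampling_radius=float(block.get("sampling_radius", 3.0)),
        )
    findings = {
        name: ModalityFinding(name, frozenset(lobes))
        for name, lobes in payload.items()
    }
    return findings, seeg


def write_cohort(patients: Sequence[PatientRecord], root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    meta = []
    for p in patients:
        pdir = root / p.id
        pdir.mkdir(exist_ok=True)
        write_dipoles_tsv(p.dipoles, pdir / "dipoles.tsv")
        write_dipoles_tsv(p.true_sources, pdir / "true_sources.tsv")
        write_mask_json(p.resection, pdir / "resection.json")
        write_findings_json(p.findings, p.seeg, pdir / "findings.json")
        meta.append(
            {
                "id": p.id, "age": p.age, "sex": p.sex,
                "duration_years": p.duration_years,
                "engel_class": p.engel_class,
                "follow_up_months": p.follow_up_months,
            }
        )
    pd.DataFrame(meta).to_csv(root / "patients.csv", index=False)


def read_cohort(root) -> list[PatientRecord]:
    root = Path(root)
    meta = pd.read_csv(root / "patients.csv")
    patients = []
    for _, r in meta.iterrows():
        pdir = root / str(r["id"])
        findings, seeg = read_findings_json(pdir / "findings.json")
        patients.append(
            PatientRecord(
                id=str(r["id"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                duration_years=float(r["duration_years"]),
                engel_class=str(r["engel_class"]),
                follow_up_months=int(r["follow_up_months"]),
                dipoles=tuple(read_dipoles_tsv(pdir / "dipoles.tsv")),
                true_sources=tuple(read_dipoles_tsv(pdir / "true_sources.tsv")),
                topographies=(),
                resection=read_mask_json(pdir / "resection.json"),
                findings=findings,
                seeg=seeg,
            )
        )
    return patients
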