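"""Synthetic cohort generation: planting, resections, determinism, IO."""

import numpy as np
import pandas as pd
import pytest

import epimeg
from epimeg import io
from epimeg.cohort import CohortConfig


def _mini_roster():
    """Three patients, one per pattern, with all modality flags set."""
    return (
        {"id": "A", "engel": "Ia", "pattern": "single", "resection": "complete",
         "mri": "concordant_exact", "pet": "concordant", "eeg": "concordant",
         "seeg": None, "straddle": False},
        {"id": "B", "engel": "III", "pattern": "multiple", "resection": "noncomplete",
         "mri": "discordant_positive", "pet": "discordant", "eeg": "concordant",
         "seeg": {"sampling": "partial", "soz": "partial"}, "straddle": False},
        {"id": "C", "engel": "II", "pattern": "scattered", "resection": "noncomplete",
         "mri": "negative", "pet": None, "eeg": "discordant",
         "seeg": None, "straddle": False},
    )


@pytest.fixture(scope="module")
def mini_cohort():
    cfg = CohortConfig(roster=_mini_roster(), seed=5, noise_sd=0.0)
    return epimeg.generate_cohort(cfg), cfg


class TestConfig:
    def test_complete_resection_of_multiple_rejected(self):
        bad = dict(_mini_roster()[1], resection="complete")
        with pytest.raises(ValueError, match="complete resection"):
            CohortConfig(roster=(bad,))

    def test_cell_counts_tabulate_roster(self):
        cfg = CohortConfig(roster=_mini_roster())
        cells = cfg.cell_counts()
        assert cells["count"].sum() == 3
        row = cells[(cells.pattern == "single_cluster")
                    & (cells.resection == "complete")]
        assert row["count"].tolist() == [1]

    def test_study_config_has_39_patients(self):
        cfg = epimeg.study_cohort_config()
        assert cfg.n_patients == 39
        cells = cfg.cell_counts()
        by_pattern = cells.groupby("pattern")["count"].sum()
        assert by_pattern["single_cluster"] == 24
        assert by_pattern["multiple_clusters"] == 9
        assert by_pattern["scattered"] == 6


class TestPlanting:
    def test_single_cluster_geometry(self, parcellation):
        sources, gyri = epimeg.plant_dipole_pattern(
            "single", parcellation, seed=1, n_per_cluster=6
        )
        pos = np.array([s.position for s in sources])
        assert len(sources) == 6 and len(gyri) == 1
        centroid = pos.mean(axis=0)
        assert np.linalg.norm(pos - centroid, axis=1).max() < 10.0
        assert {parcellation.assign_gyrus(p) for p in pos} == set(gyri)

    def test_scattered_distinct_gyri(self, parcellation):
        sources, gyri = epimeg.plant_dipole_pattern(
            "scattered", parcellation, seed=2, n_scatter=3
        )
        assert len(sources) == 3 and len(set(gyri)) == 3
        pos = np.array([s.position for s in sources])
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(pos[i] - pos[j]) > 20.0
                assert not parcellation.are_adjacent(gyri[i], gyri[j])

    def test_multiple_round_trip_through_classifier(self, parcellation):
        sources, gyri = epimeg.plant_dipole_pattern(
            "multiple", parcellation, seed=3, n_per_cluster=5
        )
        res = epimeg.classify_pattern(list(sources), parcellation)
        assert res.pattern == "multiple_clusters"

    def test_moments_tangential(self, parcellation):
        sources, _ = epimeg.plant_dipole_pattern("single", parcellation, seed=4)
        for s in sources:
            radial = s.position / np.linalg.norm(s.position)
            assert abs(s.moment @ radial) < 1e-9 * np.linalg.norm(s.moment) + 1e-6


class TestGenerateResection:
    def test_complete_covers_every_target(self, parcellation):
        sources, _ = epimeg.plant_dipole_pattern("single", parcellation, seed=5)
        mask = epimeg.generate_resection(sources, "complete", parcellation)
        pos = np.array([s.position for s in sources])
        assert np.all(mask.distance_to(pos) == 0.0)

    def test_noncomplete_leaves_target_beyond_tolerance(self, parcellation):
        sources, _ = epimeg.plant_dipole_pattern("single", parcellation, seed=6)
        mask = epimeg.generate_resection(sources, "noncomplete", parcellation)
        pos = np.array([s.position for s in sources])
        assert np.any(mask.distance_to(pos) > 10.0)

    def test_noncomplete_round_trip(self, parcellation):
        sources, _ = epimeg.plant_dipole_pattern(
            "single", parcellation, seed=7, n_per_cluster=5
        )
        mask = epimeg.generate_resection(sources, "noncomplete", parcellation)
        res = epimeg.classify_pattern(list(sources), parcellation)
        assert epimeg.resection_completeness(res, list(sources), mask) == "noncomplete"

    def test_empty_target_list_rejected(self, parcellation):
        with pytest.raises(ValueError):
            epimeg.generate_resection([], "complete", parcellation)


class TestGenerateCohort:
    def test_labels_recovered(self, mini_cohort):
        (patients, truth, parc), _ = mini_cohort
        scored = epimeg.score_cohort(patients, parc)
        merged = truth.merge(scored, on="id", suffixes=("_true", ""))
        for col in ("pattern", "resection_status", "conc_mri", "conc_pet",
                    "conc_eeg", "mri_resection_discordant"):
            assert (
                merged[col + "_true"].fillna("NA") == merged[col].fillna("NA")
            ).all(), col

    def test_truth_separate_from_records(self, mini_cohort):
        (patients, truth, _), _ = mini_cohort
        assert list(truth["id"]) == [p.id for p in patients]
        assert "pattern" in truth.columns
        assert not hasattr(patients[0], "pattern")

    def test_follow_up_meets_inclusion_minimum(self, mini_cohort):
        (patients, _, _), _ = mini_cohort
        assert all(p.follow_up_months >= 12 for p in patients)

    def test_deterministic_byte_identical(self, tmp_path):
        cfg = CohortConfig(roster=_mini_roster(), seed=11, noise_sd=20.0)
        for d in ("a", "b"):
            patients, _, _ = epimeg.generate_cohort(cfg)
            io.write_cohort(patients, tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            epimeg.generate_cohort(CohortConfig(roster=()))


class TestIO:
    def test_dipole_tsv_round_trip(self, tmp_path):
        dipoles = [
            epimeg.CurrentDipole(position=[1.5, -2.0, 30.0],
                                 moment=[10.0, 0.0, -5.0], gof=0.93,
                                 spike_id="s1"),
            epimeg.CurrentDipole(position=[0.0, 0.0, 40.0],
                                 moment=[0.0, 20.0, 0.0], gof=0.99,
                                 spike_id="s2"),
        ]
        path = tmp_path / "dipoles.tsv"
        io.write_dipoles_tsv(dipoles, path)
        back = io.read_dipoles_tsv(path)
        for a, b in zip(dipoles, back):
            assert np.allclose(a.position, b.position)
            assert np.allclose(a.moment, b.moment)
            assert a.gof == b.gof and a.spike_id == b.spike_id

    def test_topography_tsv_round_trip(self, tmp_path, array):
        topo = epimeg.FieldTopography(values=np.arange(array.n_channels, dtype=float))
        path = tmp_path / "topo.tsv"
        io.write_topography_tsv(topo, path)
        assert np.array_equal(io.read_topography_tsv(path).values, topo.values)

    def test_mask_json_round_trip(self, tmp_path):
        m = np.zeros((8, 8, 8), bool)
        m[2:4, 3, 3] = True
        mask = epimeg.ResectionMask(mask=m, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        path = tmp_path / "mask.json"
        io.write_mask_json(mask, path)
        back = io.read_mask_json(path)
        assert np.array_equal(back.mask, mask.mask)
        assert np.array_equal(back.affine, mask.affine)

    def test_mask_nifti_round_trip(self, tmp_path):
        m = np.zeros((8, 8, 8), bool)
        m[1:5, 2, 2] = True
        mask = epimeg.ResectionMask(mask=m, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        path = tmp_path / "mask.nii"
        io.write_mask_nifti(mask, path)
        back = io.read_mask_nifti(path)
        assert np.array_equal(back.mask, mask.mask)

    def test_findings_json_round_trip(self, tmp_path):
        findings = {
            "MRI": epimeg.ModalityFinding("MRI", frozenset({"parietal"})),
            "interictal_EEG": epimeg.ModalityFinding("interictal_EEG", frozenset()),
        }
        seeg = epimeg.SEEGData(
            contact_positions=np.array([[1.0, 2.0, 3.0]]),
            soz_regions=frozenset({4, 5}),
        )
        path = tmp_path / "findings.json"
        io.write_findings_json(findings, seeg, path)
        back_f, back_s = io.read_findings_json(path)
        assert back_f["MRI"].lobes == {"parietal"}
        assert back_f["interictal_EEG"].negative
        assert back_s.soz_regions == {4, 5}

    def test_cohort_directory_round_trip(self, tmp_path, mini_cohort):
        (patients, _, parc), _ = mini_cohort
        io.write_cohort(patients, tmp_path / "cohort")
        back = io.read_cohort(tmp_path / "cohort")
        assert [p.id for p in back] == [p.id for p in patients]
        scored_a = epimeg.score_cohort(patients, parc)
        scored_b = epimeg.score_cohort(back, parc)
        pd.testing.assert_frame_equal(scored_a, scored_b)
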