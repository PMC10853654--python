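"""Resection completeness, lobar concordance, SEEG scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epimeg
from epimeg.classification import ClassificationResult
from epimeg.concordance import (
    ModalityFinding,
    ResectionMask,
    SEEGData,
    combined_concordance,
    lobar_concordance,
    mri_resection_discordance,
    resection_completeness,
    seeg_sampling,
    seeg_soz_concordance,
)


def _mask_around(center, radius=10.0, shape=(40, 40, 40), vox=2.0):
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -vox * (np.array(shape) - 1) / 2
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack(grids, axis=-1) * vox + affine[:3, 3]
    mask = ((pts - np.asarray(center)) ** 2).sum(axis=-1) <= radius**2
    return ResectionMask(mask=mask, affine=affine)


def _single_result(indices, gyri=frozenset({1}), outliers=frozenset()):
    return ClassificationResult(
        pattern="single_cluster",
        clusters=(frozenset(indices),),
        outliers=outliers,
        cluster_gyri=(gyri,),
        meg_gyri=gyri,
        meg_lobes=frozenset({"parietal"}),
    )


def _dip(x, y, z):
    return epimeg.CurrentDipole(position=[x, y, z], moment=[50.0, 0, 0], gof=0.95)


class TestResectionCompleteness:
    def test_all_inside_mask_complete(self):
        mask = _mask_around([0, 0, 0], radius=12)
        dipoles = [_dip(2 * i - 4, 0, 0) for i in range(5)]
        res = _single_result(range(5))
        assert resection_completeness(res, dipoles, mask) == "complete"

    def test_member_8mm_outside_still_complete(self):
        """One member 8 mm beyond the border is inside the 1-cm tolerance."""
        mask = _mask_around([0, 0, 0], radius=10)
        dipoles = [_dip(0, 0, 0)] * 4 + [_dip(18, 0, 0)]
        res = _single_result(range(5))
        assert resection_completeness(res, dipoles, mask) == "complete"

    def test_member_beyond_tolerance_noncomplete(self):
        mask = _mask_around([0, 0, 0], radius=10)
        dipoles = [_dip(0, 0, 0)] * 4 + [_dip(24, 0, 0)]
        res = _single_result(range(5))
        assert resection_completeness(res, dipoles, mask) == "noncomplete"

    def test_outliers_ignored(self):
        """Spurious outlier localizations do not spoil completeness."""
        mask = _mask_around([0, 0, 0], radius=10)
        dipoles = [_dip(0, 0, 0)] * 5 + [_dip(35, 0, 0)]
        res = _single_result(range(5), outliers=frozenset({5}))
        assert resection_completeness(res, dipoles, mask) == "complete"

    @pytest.mark.parametrize("pattern", ["multiple_clusters", "scattered"])
    def test_nonsingle_patterns_always_noncomplete(self, pattern):
        """Multiple clusters and scattered dipoles extend beyond any
        resection: noncomplete even when fully covered by the mask."""
        mask = _mask_around([0, 0, 0], radius=30)
        dipoles = [_dip(0, 0, 0)] * 5
        res = ClassificationResult(
            pattern=pattern,
            clusters=(frozenset(range(5)),) if pattern != "scattered" else (),
            outliers=frozenset() if pattern != "scattered" else frozenset(range(5)),
            cluster_gyri=(frozenset({1}),) if pattern != "scattered" else (),
            meg_gyri=frozenset({1}),
            meg_lobes=frozenset({"parietal"}),
        )
        assert resection_completeness(res, dipoles, mask) == "noncomplete"

    def test_tolerance_monotonicity(self):
        """Raising the tolerance can only turn noncomplete into complete."""
        mask = _mask_around([0, 0, 0], radius=10)
        dipoles = [_dip(0, 0, 0)] * 4 + [_dip(22, 0, 0)]
        res = _single_result(range(5))
        states = [
            resection_completeness(res, dipoles, mask, tolerance=t)
            for t in (0.0, 5.0, 12.0, 20.0)
        ]
        # once complete, stays complete
        first_complete = next(
            (i for i, s in enumerate(states) if s == "complete"), len(states)
        )
        assert all(s == "complete" for s in states[first_complete:])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ResectionMask(mask=np.zeros((5, 5, 5), bool), affine=np.eye(4))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_distance_matches_brute_force_dilation(self, seed):
        """Distance-transform completeness equals brute-force voxel-center
        distance on small random masks."""
        rng = np.random.default_rng(seed)
        shape, vox = (14, 14, 14), 2.0
        m = np.zeros(shape, bool)
        idx = rng.integers(0, 14, size=(rng.integers(1, 8), 3))
        m[tuple(idx.T)] = True
        affine = np.diag([vox, vox, vox, 1.0])
        affine[:3, 3] = 0.0
        mask = ResectionMask(mask=m, affine=affine)
        centers = np.argwhere(m) * vox
        for _ in range(10):
            ijk = rng.integers(0, 14, size=3)
            p = ijk * vox
            brute = np.min(np.linalg.norm(centers - p, axis=1))
            assert np.isclose(mask.distance_to(p)[0], brute, atol=1e-9)


class TestLobarConcordance:
    def test_overlap_is_concordant(self):
        f = ModalityFinding("MRI", frozenset({"parietal", "occipital"}))
        assert lobar_concordance({"parietal"}, f) == "concordant"

    def test_disjoint_is_discordant(self):
        f = ModalityFinding("MRI", frozenset({"occipital"}))
        assert lobar_concordance({"parietal"}, f) == "discordant"

    def test_negative_study_is_discordant(self):
        assert lobar_concordance({"parietal"}, ModalityFinding("MRI")) == "discordant"

    def test_empty_meg_lobes_rejected(self):
        with pytest.raises(ValueError):
            lobar_concordance(set(), ModalityFinding("MRI", frozenset({"parietal"})))

    def test_symmetric_in_intersection(self):
        a, b = {"parietal", "occipital"}, {"occipital", "posterior_temporal"}
        assert lobar_concordance(a, ModalityFinding("x", frozenset(b))) == \
            lobar_concordance(b, ModalityFinding("x", frozenset(a)))


class TestCombinedConcordance:
    def test_requires_all_modalities(self):
        mri = ModalityFinding("MRI", frozenset({"parietal"}))
        pet = ModalityFinding("PET", frozenset({"occipital"}))
        assert combined_concordance({"parietal"}, [mri, pet]) == "discordant"
        pet2 = ModalityFinding("PET", frozenset({"parietal"}))
        assert combined_concordance({"parietal"}, [mri, pet2]) == "concordant"

    def test_single_modality_reduces_to_lobar(self):
        f = ModalityFinding("PET", frozenset({"occipital"}))
        assert combined_concordance({"occipital"}, [f]) == \
            lobar_concordance({"occipital"}, f)

    def test_no_findings_rejected(self):
        with pytest.raises(ValueError):
            combined_concordance({"parietal"}, [])


class TestMriResectionDiscordance:
    def test_contained_is_concordant(self):
        mri = ModalityFinding("MRI", frozenset({"parietal"}))
        assert mri_resection_discordance(mri, {"parietal"}) is False

    def test_extra_lobe_is_discordant(self):
        mri = ModalityFinding("MRI", frozenset({"parietal", "occipital"}))
        assert mri_resection_discordance(mri, {"parietal"}) is True

    def test_negative_mri_is_discordant(self):
        assert mri_resection_discordance(ModalityFinding("MRI"), {"parietal"}) is True


class TestSEEG:
    def _seeg(self, parc, gyri, soz):
        contacts = np.array([parc.interior_point(g) for g in gyri])
        return SEEGData(contact_positions=contacts, soz_regions=frozenset(soz))

    def test_complete_sampling(self, parcellation):
        res = _single_result([0], gyri=frozenset({1, 2}))
        seeg = self._seeg(parcellation, [1, 2], {1})
        assert seeg_sampling(res, seeg, parcellation) == ("complete_sample", False)

    def test_partial_sampling(self, parcellation):
        res = _single_result([0], gyri=frozenset({1, 2}))
        seeg = self._seeg(parcellation, [1], {1})
        assert seeg_sampling(res, seeg, parcellation) == ("partial_sample", False)

    def test_no_sampling_warns(self, parcellation):
        res = _single_result([0], gyri=frozenset({1}))
        seeg = self._seeg(parcellation, [5], {5})
        cat, warn = seeg_sampling(res, seeg, parcellation)
        assert cat == "partial_sample" and warn

    def test_soz_complete_includes_equality(self, parcellation):
        res = _single_result([0], gyri=frozenset({1}))
        assert seeg_soz_concordance(res, self._seeg(parcellation, [1], {1})) == \
            ("complete_concordance", False)
        assert seeg_soz_concordance(res, self._seeg(parcellation, [1], {1, 2})) == \
            ("complete_concordance", False)

    def test_soz_partial_overlap(self, parcellation):
        res = _single_result([0], gyri=frozenset({1, 5}))
        assert seeg_soz_concordance(res, self._seeg(parcellation, [1], {1})) == \
            ("partial_concordance", False)

    def test_soz_disjoint_warns(self, parcellation):
        res = _single_result([0], gyri=frozenset({1}))
        cat, warn = seeg_soz_concordance(res, self._seeg(parcellation, [5], {5}))
        assert cat == "partial_concordance" and warn
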