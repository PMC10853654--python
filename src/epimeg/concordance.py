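"""Resection completeness and cross-modality concordance scoring.

Completeness of the MEG localization's resection is judged with a 1-cm
tolerance around the resection border: a single-cluster localization is
completely resected when every cluster-member dipole (outliers excluded)
lies within the mask or within ``tolerance`` mm of it.  Multiple-cluster
and scattered localizations are noncomplete by definition — they extend
beyond any single resection.

Concordance with MRI / PET / interictal EEG is scored at the lobar level:
concordant when the MEG lobes overlap at least one lobe of the other
modality's finding.  A negative (empty) finding counts as discordant.
SEEG is scored at the gyral ("sublobar") level, first for electrode
sampling of the MEG regions, then for overlap with the seizure onset zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .classification import ClassificationResult
from .dipoles import CurrentDipole
from .parcellation import Parcellation, UnassignedDipoleError

__all__ = [
    "ResectionMask",
    "ModalityFinding",
    "SEEGData",
    "SEEGResult",
    "resection_completeness",
    "lobar_concordance",
    "combined_concordance",
    "mri_resection_discordance",
    "resection_lobes",
    "seeg_sampling",
    "seeg_soz_concordance",
]

MODALITIES = ("MRI", "PET", "interictal_EEG")


@dataclass(frozen=True)
class ResectionMask:
    """Binary resection volume on a voxel grid with an affine to mm.

    The derived distance field gives, for every voxel, the Euclidean
    distance (mm) to the nearest mask voxel center — zero on the mask
    itself.  Distances at arbitrary mm points are looked up at the nearest
    voxel; with voxel sizes <= 2.5 mm the discretization error is far
    below the 10-mm clinical tolerance.
    """

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask must be a 3-d voxel grid")
        if not m.any():
            raise ValueError("resection mask must be nonempty")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def voxel_size(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    def distance_field(self) -> np.ndarray:
        """mm to the nearest mask voxel, zero inside the mask (cached)."""
        cached = getattr(self, "_df_cache", None)
        if cached is None:
            cached = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.voxel_size
            )
            object.__setattr__(self, "_df_cache", cached)
        return cached

    def distance_to(self, points_mm: np.ndarray) -> np.ndarray:
        """Distance (mm) from each point to the mask, via the distance field."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = np.rint((np.column_stack([p, np.ones(len(p))]) @ inv.T)[:, :3]).astype(int)
        shape = np.array(self.mask.shape)
        clipped = np.clip(ijk, 0, shape - 1)
        df = self.distance_field()
        d = df[tuple(clipped.T)]
        # points off the grid: add the out-of-grid offset so distance is
        # never understated
        off = np.linalg.norm((ijk - clipped) * self.voxel_size, axis=1)
        return d + off


@dataclass(frozen=True)
class ModalityFinding:
    """Lobar finding of one noninvasive modality; empty = negative study."""

    modality: str
    lobes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lobes", frozenset(self.lobes))

    @property
    def negative(self) -> bool:
        return len(self.lobes) == 0


@dataclass(frozen=True)
class SEEGData:
    """SEEG electrode contacts and the seizure onset zone they identified."""

    contact_positions: np.ndarray
    soz_regions: frozenset[int]
    sampling_radius: float = 3.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.contact_positions, dtype=float))
        if pos.shape[1] != 3:
            raise ValueError("contact positions must be (n, 3)")
        object.__setattr__(self, "contact_positions", pos)
        object.__setattr__(self, "soz_regions", frozenset(self.soz_regions))


class SEEGResult(NamedTuple):
    """Category plus a warning flag for configurations the two-level
    scheme does not anticipate (e.g. zero MEG gyri sampled)."""

    category: str
    warning: bool = False


def resection_completeness(
    result: ClassificationResult,
    dipoles: Sequence[CurrentDipole],
    mask: ResectionMask,
    tolerance: float = 10.0,
) -> str:
    """'complete' or 'noncomplete' resection of the MEG localization.

    Multiple-cluster and scattered patterns are noncomplete
    unconditionally.  For a single cluster, every cluster-member dipole
    must lie within ``tolerance`` mm of the resection; spurious outlier
    localizations are not considered.
    """
    if result.pattern in ("multiple_clusters", "scattered"):
        return "noncomplete"
    members = sorted(i for c in result.clusters for i in c)
    pos = np.array([dipoles[i].position for i in members])
    return "complete" if np.all(mask.distance_to(pos) <= tolerance) else "noncomplete"


def lobar_concordance(meg_lobes: Iterable[str], finding: ModalityFinding) -> str:
    """'concordant' when MEG lobes overlap at least one lobe of the
    finding; a negative study is discordant."""
    meg = frozenset(meg_lobes)
    if not meg:
        raise ValueError("MEG lobe set must be nonempty")
    return "concordant" if meg & finding.lobes else "discordant"


def combined_concordance(
    meg_lobes: Iterable[str], findings: Sequence[ModalityFinding]
) -> str:
    """Concordant only when concordant with *every* listed modality."""
    if len(findings) == 0:
        raise ValueError("at least one finding is required")
    meg = frozenset(meg_lobes)
    ok = all(lobar_concordance(meg, f) == "concordant" for f in findings)
    return "concordant" if ok else "discordant"


def mri_resection_discordance(
    mri: ModalityFinding, resection_lobes: Iterable[str]
) -> bool:
    """True when the MRI abnormality is not fully inside the resection at
    the lobar level, or the MRI is negative."""
    res = frozenset(resection_lobes)
    if not res:
        raise ValueError("resection lobe set must be nonempty")
    return mri.negative or not (mri.lobes <= res)


def resection_lobes(
    mask: ResectionMask, parcellation: Parcellation, min_fraction: float = 0.05
) -> frozenset[str]:
    """Lobes substantially covered by the resection: lobes of gyri holding
    at least ``min_fraction`` of the mask's voxels.

    The threshold ignores incidental spill of a few voxels into a
    neighboring gyrus.  Assumes mask and parcellation share grid and
    affine (one coordinate frame, the pipeline's standing assumption).
    """
    if mask.mask.shape != parcellation.label_volume.shape:
        raise ValueError("mask and parcellation grids differ")
    labels = parcellation.label_volume[mask.mask]
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("resection does not intersect the parcellation")
    ids, counts = np.unique(labels, return_counts=True)
    keep = ids[counts / labels.size >= min_fraction]
    return frozenset(parcellation.lobes_of([int(g) for g in keep]))


def _sampled_gyri(
    seeg: SEEGData, parcellation: Parcellation
) -> frozenset[int]:
    sampled: set[int] = set()
    for p in seeg.contact_positions:
        try:
            sampled.add(parcellation.assign_gyrus(p, seeg.sampling_radius))
        except UnassignedDipoleError:
            continue  # contact in white matter / outside cortex
    return frozenset(sampled)


def seeg_sampling(
    result: ClassificationResult, seeg: SEEGData, parcellation: Parcellation
) -> SEEGResult:
    """'complete_sample' when every MEG-implicated gyrus holds at least one
    contact; otherwise 'partial_sample' (with a warning when none do)."""
    sampled = _sampled_gyri(seeg, parcellation)
    meg = result.meg_gyri
    if not meg:
        raise ValueError("classification implicates no gyri")
    if meg <= sampled:
        return SEEGResult("complete_sample")
    if meg & sampled:
        return SEEGResult("partial_sample")
    return SEEGResult("partial_sample", warning=True)


def seeg_soz_concordance(
    result: ClassificationResult, seeg: SEEGData
) -> SEEGResult:
    """'complete_concordance' when the MEG gyri are included in the SOZ;
    'partial_concordance' when they merely overlap it (warning when they
    do not overlap at all — a case the two-level scheme leaves undefined)."""
    if not seeg.soz_regions:
        raise ValueError("SOZ region set must be nonempty")
    meg = result.meg_gyri
    if meg <= seeg.soz_regions:
        return SEEGResult("complete_concordance")
    if meg & seeg.soz_regions:
        return SEEGResult("partial_concordance")
    return SEEGResult("partial_concordance", warning=True)
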