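"""Synthetic cohort generation.

The generator builds everything the analysis consumes — sensor array,
parcellation, planted dipole sources, simulated spike topographies, fitted
dipole tables, resection masks, modality findings, SEEG data and outcomes —
from a declarative per-patient roster, so every downstream stage is
testable without any external data.

A packaged roster (``study_cohort_config``) realizes the categorical
structure of a 39-patient posterior-cortex-epilepsy surgical series:
24 single-cluster / 9 multiple-cluster / 6 scattered patients, the
complete/noncomplete resection split, per-modality concordance flags and
SEEG sampling/SOZ categories, with 21 seizure-free outcomes.  Geometry is
chosen so that the scoring pipeline recovers each patient's intended
labels: clusters are planted deep inside gyri, noncomplete resections are
displaced well beyond the 10-mm tolerance, and findings are constructed
relative to the lobes the planted sources implicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    ModalityFinding,
    ResectionMask,
    SEEGData,
    resection_lobes as _resection_lobes,
)
from .dipoles import CurrentDipole, FieldTopography, filter_significant
from .fitting import LeadFieldGrid, fit_dipole
from .forward import simulate_topography
from .parcellation import (
    POSTERIOR_LOBES,
    Parcellation,
    ParcellationSpec,
    default_parcellation_spec,
    generate_parcellation,
)
from .sensors import SphereModel, generate_sensor_array

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "plant_dipole_pattern",
    "generate_resection",
    "generate_cohort",
    "study_cohort_config",
]

PATTERN_NAMES = {"single": "single_cluster", "multiple": "multiple_clusters",
                 "scattered": "scattered"}

#: default source strength of an averaged interictal spike, nA*m
DEFAULT_AMPLITUDE = 250.0
#: default sensor noise on a spike-peak topography, fT
DEFAULT_NOISE_SD = 40.0


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort deterministically.

    ``roster`` is a list of per-patient dicts with keys: id, engel,
    pattern (single/multiple/scattered), resection (complete/noncomplete),
    mri (concordant_exact / concordant_extra / discordant_positive /
    negative), pet (concordant / discordant / None), eeg (concordant /
    discordant), seeg (None or {"sampling":..., "soz":...}), straddle.
    A patient with multiple/scattered pattern marked 'complete' is a
    configuration error: those localizations extend beyond any resection.
    """

    roster: tuple[dict[str, Any], ...]
    seed: int = 0
    noise_sd: float = DEFAULT_NOISE_SD
    amplitude: float = DEFAULT_AMPLITUDE
    cluster_sd: float = 3.0
    scatter_min_sep: float = 20.0
    dipoles_per_cluster: tuple[int, int] = (6, 8)
    n_scatter: tuple[int, int] = (2, 3)
    resection_margin: float = 8.0
    gof_threshold: float = 0.85
    n_channels: int = 102
    helmet_radius: float = 110.0
    sphere_radius: float = 90.0
    parcellation_spec: ParcellationSpec = field(
        default_factory=default_parcellation_spec
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "roster", tuple(dict(e) for e in self.roster))
        for e in self.roster:
            if e["pattern"] not in PATTERN_NAMES:
                raise ValueError(f"unknown pattern {e['pattern']!r}")
            if e["resection"] not in ("complete", "noncomplete"):
                raise ValueError(f"unknown resection status {e['resection']!r}")
            if e["pattern"] in ("multiple", "scattered") and e["resection"] == "complete":
                raise ValueError(
                    f"patient {e.get('id')}: complete resection is undefined for "
                    f"{e['pattern']} patterns (they extend beyond the resection)"
                )

    @property
    def n_patients(self) -> int:
        return len(self.roster)

    def cell_counts(self) -> pd.DataFrame:
        """Configured (pattern, resection, outcome) cell counts."""
        rows = [
            {
                "pattern": PATTERN_NAMES[e["pattern"]],
                "resection": e["resection"],
                "outcome": "seizure_free"
                if e["engel"].rstrip("abcd") == "I"
                else "not_seizure_free",
            }
            for e in self.roster
        ]
        return (
            pd.DataFrame(rows)
            .value_counts(["pattern", "resection", "outcome"])
            .rename("count")
            .reset_index()
            .sort_values(["pattern", "resection", "outcome"])
            .reset_index(drop=True)
        )


def study_cohort_config(noise_sd: float = 0.0, seed: int = 0) -> CohortConfig:
    """The packaged 39-patient reproduction roster.

    Defaults to noiseless topographies so the realized cohort equals the
    configured one exactly; pass a nonzero ``noise_sd`` to stress the
    pipeline under measurement noise.
    """
    text = resources.files("epimeg.data").joinpath("study_roster.json").read_text()
    return CohortConfig(roster=tuple(json.loads(text)), noise_sd=noise_sd, seed=seed)


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: measurements plus clinical metadata."""

    id: str
    age: float
    sex: str
    duration_years: float
    engel_class: str
    follow_up_months: int
    dipoles: tuple[CurrentDipole, ...]          # fitted, GOF-filtered
    true_sources: tuple[CurrentDipole, ...]
    topographies: tuple[FieldTopography, ...]
    resection: ResectionMask
    findings: dict[str, ModalityFinding]
    seeg: SEEGData | None = None

    def __post_init__(self) -> None:
        if self.follow_up_months < 12:
            raise ValueError("follow-up below the 12-month inclusion minimum")


# -- source planting --------------------------------------------------------

def _tangential_moment(position: np.ndarray, amplitude: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Random moment of given amplitude perpendicular to the radial
    direction (radial components are externally silent and unfittable)."""
    radial = position / np.linalg.norm(position)
    v = rng.normal(size=3)
    v -= (v @ radial) * radial
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        v -= (v @ radial) * radial
        n = np.linalg.norm(v)
    return amplitude * v / n


def _single_linkage_connected(points: np.ndarray, radius: float = 10.0) -> bool:
    if len(points) <= 1:
        return True
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1) <= radius
    reach = {0}
    frontier = [0]
    while frontier:
        v = frontier.pop()
        for w in np.flatnonzero(d[v]):
            if w not in reach:
                reach.add(int(w))
                frontier.append(int(w))
    return len(reach) == len(points)


def _sample_in_gyri(
    center: np.ndarray,
    sd: float,
    n: int,
    parcellation: Parcellation,
    allowed: set[int],
    rng: np.random.Generator,
    max_tries: int = 4000,
    require_connected: bool = False,
) -> np.ndarray:
    """Gaussian cloud around ``center`` rejected into the allowed gyri.

    With ``require_connected`` the cloud is resampled until it forms one
    single-linkage component at the 10-mm clinical cluster radius — a
    planted "cluster" must actually be one cluster.
    """
    vol = parcellation.label_volume
    shape = np.array(vol.shape)
    for _ in range(40):
        out: list[np.ndarray] = []
        tries = 0
        while len(out) < n:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place sources inside the target gyri")
            p = center + rng.normal(0.0, sd, size=3)
            ijk = np.rint(parcellation.mm_to_voxel(p)[0]).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= shape):
                continue
            if int(vol[tuple(ijk)]) in allowed:
                out.append(p)
        pts = np.array(out)
        if not require_connected or _single_linkage_connected(pts):
            return pts
    raise RuntimeError("could not sample a connected cluster")


def _pick_nonadjacent(
    gyri: list[int], parcellation: Parcellation, k: int,
    min_sep: float, rng: np.random.Generator,
) -> list[int]:
    """A uniformly chosen set of k mutually non-adjacent gyri whose
    interior points are pairwise more than ``min_sep`` apart."""
    from itertools import combinations

    pts = {g: parcellation.interior_point(g) for g in gyri}
    valid = [
        list(combo)
        for combo in combinations(sorted(gyri), k)
        if all(
            not parcellation.are_adjacent(a, b)
            and np.linalg.norm(pts[a] - pts[b]) > min_sep
            for a, b in combinations(combo, 2)
        )
    ]
    if not valid:
        raise RuntimeError(
            f"parcellation offers no {k} mutually non-adjacent gyri "
            f"separated by > {min_sep} mm"
        )
    return valid[int(rng.integers(len(valid)))]


def plant_dipole_pattern(
    pattern: str,
    parcellation: Parcellation,
    seed: int | np.random.Generator = 0,
    *,
    cluster_sd: float = 3.0,
    n_per_cluster: int = 6,
    n_clusters: int = 2,
    n_scatter: int = 3,
    scatter_min_sep: float = 20.0,
    amplitude: float = DEFAULT_AMPLITUDE,
    allowed_lobes: Sequence[str] = POSTERIOR_LOBES,
    gyri: Sequence[int] | None = None,
    straddle: bool = False,
) -> tuple[list[CurrentDipole], list[int]]:
    """Plant ground-truth sources realizing one spatial pattern.

    single    : >= 5 sources, Gaussian spread ``cluster_sd`` around a deep
                point of one gyrus (or the border of two adjacent gyri when
                ``straddle``);
    multiple  : ``n_clusters`` such groups in mutually non-adjacent gyri;
    scattered : ``n_scatter`` (<= 4 by default) lone sources in mutually
                non-adjacent gyri more than ``scatter_min_sep`` mm apart.

    Returns (sources, gyri used).  Moments are tangential with the given
    amplitude.  Classification of the result is the classifier's business;
    the generator only guarantees the geometry above.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    posterior = [
        g for g in parcellation.gyrus_ids()
        if parcellation.lobe_of(g) in set(allowed_lobes)
    ]
    if not posterior:
        raise RuntimeError("no gyri in the allowed lobes")

    sources: list[CurrentDipole] = []
    used: list[int] = []

    def add(positions: np.ndarray) -> None:
        for p in positions:
            sources.append(
                CurrentDipole(
                    position=p,
                    moment=_tangential_moment(p, amplitude, rng),
                    gof=1.0,
                    spike_id=f"spike{len(sources):03d}",
                )
            )

    if pattern == "single":
        if straddle:
            if gyri is not None:
                g, h = int(gyri[0]), int(gyri[1])
            else:
                pair = None
                order = rng.permutation(len(posterior))
                for i in order:
                    cand = posterior[i]
                    partners = [
                        p for p in posterior
                        if p != cand and parcellation.are_adjacent(cand, p)
                    ]
                    if partners:
                        pair = (cand, partners[int(rng.integers(len(partners)))])
                        break
                if pair is None:
                    raise RuntimeError("no adjacent posterior gyrus pair to straddle")
                g, h = pair
            center = _border_point(parcellation, g, h)
            pts = _sample_in_gyri(center, max(cluster_sd, 2.0), n_per_cluster,
                                  parcellation, {g, h}, rng,
                                  require_connected=True)
            # make sure both gyri are really represented
            labels = {
                int(parcellation.label_volume[tuple(np.rint(
                    parcellation.mm_to_voxel(p)[0]).astype(int))])
                for p in pts
            }
            tries = 0
            while labels != {g, h}:
                tries += 1
                if tries > 50:
                    break
                pts = _sample_in_gyri(center, max(cluster_sd, 2.0), n_per_cluster,
                                      parcellation, {g, h}, rng,
                                      require_connected=True)
                labels = {
                    int(parcellation.label_volume[tuple(np.rint(
                        parcellation.mm_to_voxel(p)[0]).astype(int))])
                    for p in pts
                }
            add(pts)
            used = [g, h]
        else:
            g = int(rng.choice(posterior)) if gyri is None else int(gyri[0])
            center = parcellation.interior_point(g)
            add(_sample_in_gyri(center, cluster_sd, n_per_cluster,
                                parcellation, {g}, rng,
                                require_connected=True))
            used = [g]
    elif pattern == "multiple":
        chosen = (
            list(gyri)
            if gyri is not None
            else _pick_nonadjacent(posterior, parcellation, n_clusters,
                                   scatter_min_sep, rng)
        )
        for g in chosen:
            center = parcellation.interior_point(g)
            add(_sample_in_gyri(center, cluster_sd, n_per_cluster,
                                parcellation, {g}, rng,
                                require_connected=True))
        used = chosen
    elif pattern == "scattered":
        chosen = (
            list(gyri)
            if gyri is not None
            else _pick_nonadjacent(posterior, parcellation, n_scatter,
                                   scatter_min_sep, rng)
        )
        for g in chosen:
            center = parcellation.interior_point(g)
            add(_sample_in_gyri(center, 1.5, 1, parcellation, {g}, rng))
        used = chosen
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return sources, used


def _border_point(parcellation: Parcellation, g: int, h: int) -> np.ndarray:
    """Centroid of the shared voxel interface of two adjacent gyri."""
    vol = parcellation.label_volume
    midpoints = []
    for axis in range(3):
        a = np.moveaxis(vol, axis, 0)[:-1]
        b = np.moveaxis(vol, axis, 0)[1:]
        for first, second in ((g, h), (h, g)):
            where = np.argwhere((a == first) & (b == second))
            if where.size == 0:
                continue
            ijk = np.moveaxis(
                np.stack(
                    [where[:, 0], where[:, 1], where[:, 2]], axis=1
                ), 0, 0
            ).astype(float)
            # convert back to the original axis order and take face midpoints
            ijk_full = np.empty_like(ijk)
            order = [axis] + [x for x in range(3) if x != axis]
            for out_axis, in_col in zip(order, range(3)):
                ijk_full[:, out_axis] = ijk[:, in_col]
            ijk_full[:, axis] += 0.5
            midpoints.append(parcellation.voxel_to_mm(ijk_full))
    if not midpoints:
        raise RuntimeError(f"gyri {g} and {h} share no voxel interface")
    return np.concatenate(midpoints).mean(axis=0)


# -- resection --------------------------------------------------------------

def _ball_mask(
    shape: tuple[int, ...], affine: np.ndarray, centers_mm: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Union of balls on the voxel grid (marks voxel centers within radius)."""
    mask = np.zeros(shape, dtype=bool)
    vox = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    for c in np.atleast_2d(centers_mm):
        lo = np.floor((c - radius - origin) / vox).astype(int)
        hi = np.ceil((c + radius - origin) / vox).astype(int) + 1
        lo = np.clip(lo, 0, shape)
        hi = np.clip(hi, 0, shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        grids = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
        )
        pts = np.stack(grids, axis=-1) * vox + origin
        d2 = ((pts - c) ** 2).sum(axis=-1)
        mask[sl] |= d2 <= radius**2
    return mask


def generate_resection(
    targets: Sequence[CurrentDipole],
    status: str,
    parcellation: Parcellation,
    margin: float = 8.0,
    seed: int | np.random.Generator = 0,
    tolerance: float = 10.0,
) -> ResectionMask:
    """Build a resection mask realizing the requested completeness.

    complete    : union of ``margin``-mm balls around every target — each
                  target's distance to the mask is exactly 0.
    noncomplete : if the targets occupy several gyri, resect only the
                  first gyrus's group (the rest lie far outside); for a
                  single tight group, resect a different gyrus of the same
                  lobe so every target is well beyond ``tolerance`` of the
                  border.  The construction is verified before returning.
    """
    if len(targets) == 0:
        raise ValueError("cannot build a resection for an empty target list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = parcellation.label_volume.shape
    affine = parcellation.affine
    pos = np.array([t.position for t in targets])

    if status == "complete":
        mask = _ball_mask(shape, affine, pos, margin)
        return ResectionMask(mask=mask, affine=affine)
    if status != "noncomplete":
        raise ValueError(f"unknown resection status {status!r}")

    gyri = [parcellation.assign_gyrus(p) for p in pos]
    first = gyri[0]
    in_first = pos[[g == first for g in gyri]]
    out_first = pos[[g != first for g in gyri]]
    if len(out_first) > 0:
        mask = _ball_mask(shape, affine, in_first, margin)
        rm = ResectionMask(mask=mask, affine=affine)
        if np.any(rm.distance_to(out_first) > tolerance):
            return rm
    # single tight group: resect elsewhere in the same lobe
    lobe = parcellation.lobe_of(first)
    candidates = [
        g for g in parcellation.gyrus_ids()
        if g not in set(gyri) and parcellation.lobe_of(g) == lobe
    ]
    candidates += [
        g for g in parcellation.gyrus_ids()
        if g not in set(gyri) | set(candidates)
    ]
    for g in candidates:
        center = parcellation.interior_point(g)
        mask = _ball_mask(shape, affine, center[None, :], 1.5 * margin)
        if not mask.any():
            continue
        rm = ResectionMask(mask=mask, affine=affine)
        if np.any(rm.distance_to(pos) > tolerance):
            return rm
    raise RuntimeError("could not realize a noncomplete resection")


# -- findings / SEEG --------------------------------------------------------

def _build_findings(
    entry: dict[str, Any],
    meg_lobes: set[str],
    res_lobes: set[str],
    all_lobes: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, ModalityFinding]:
    """Modality lobe sets realizing the roster's concordance flags,
    constructed relative to the lobes the planted sources implicate."""
    meg_sorted = sorted(meg_lobes)
    anchor = meg_sorted[0]
    off_meg = [l for l in all_lobes if l not in meg_lobes]
    off_both = [l for l in off_meg if l not in res_lobes]
    if not off_both:
        raise RuntimeError("lobe vocabulary too small to realize discordance")

    def modality(kind: str | None, name: str) -> ModalityFinding | None:
        if kind is None:
            return None
        if kind == "concordant":
            return ModalityFinding(name, frozenset({anchor}))
        if kind == "discordant":
            return ModalityFinding(name, frozenset({off_both[0]}))
        raise ValueError(kind)

    findings: dict[str, ModalityFinding] = {}
    mri_kind = entry["mri"]
    if mri_kind == "concordant_exact":
        findings["MRI"] = ModalityFinding("MRI", frozenset(res_lobes))
    elif mri_kind == "concordant_extra":
        findings["MRI"] = ModalityFinding(
            "MRI", frozenset({anchor, off_both[0]})
        )
    elif mri_kind == "discordant_positive":
        findings["MRI"] = ModalityFinding("MRI", frozenset({off_both[0]}))
    elif mri_kind == "negative":
        findings["MRI"] = ModalityFinding("MRI", frozenset())
    else:
        raise ValueError(f"unknown MRI category {mri_kind!r}")

    pet = modality(entry["pet"], "PET")
    if pet is not None:
        findings["PET"] = pet
    findings["interictal_EEG"] = modality(entry["eeg"], "interictal_EEG")
    return findings


def _build_seeg(
    entry: dict[str, Any],
    meg_gyri: list[int],
    parcellation: Parcellation,
    rng: np.random.Generator,
) -> SEEGData | None:
    spec = entry.get("seeg")
    if not spec:
        return None
    if spec["sampling"] == "complete":
        sampled = list(meg_gyri)
    else:
        if len(meg_gyri) < 2:
            raise RuntimeError(
                "partial sampling needs a multi-gyrus MEG localization"
            )
        sampled = [meg_gyri[0]]
    contacts = []
    for g in sampled:
        center = parcellation.interior_point(g)
        for _ in range(3):
            contacts.append(center + rng.normal(0.0, 0.8, size=3))

    if spec["soz"] == "complete":
        soz = set(meg_gyri)
    else:
        if len(meg_gyri) < 2:
            raise RuntimeError(
                "partial SOZ concordance needs a multi-gyrus MEG localization"
            )
        others = [
            g for g in parcellation.gyrus_ids()
            if g not in meg_gyri
            and parcellation.lobe_of(g) != "non_posterior"
        ]
        soz = {meg_gyri[0], others[int(rng.integers(len(others)))]}
    return SEEGData(
        contact_positions=np.array(contacts), soz_regions=frozenset(soz)
    )


# -- cohort -----------------------------------------------------------------

def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], pd.DataFrame, Parcellation]:
    """Generate the full cohort plus its ground-truth label table.

    Returns (patients, truth, parcellation).  ``truth`` holds one row per
    patient with the *intended* labels from the roster; the records hold
    only data (dipole tables, masks, findings), so the analysis pipeline
    can be scored against the truth.  Identical config and seed give an
    identical cohort.
    """
    if config.n_patients == 0:
        raise ValueError("empty roster")
    parcellation = generate_parcellation(config.parcellation_spec, seed=config.seed)
    sphere = SphereModel(radius=config.sphere_radius)
    array = generate_sensor_array(
        config.n_channels, config.helmet_radius, seed=config.seed
    )
    grid = LeadFieldGrid.build(array, sphere)
    all_lobes = sorted({l for l in parcellation.gyrus_lobes.values()})

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 1)
    demo_rng = np.random.default_rng(children[-1])
    n = config.n_patients
    n_male = int(round(n * 26 / 39))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    demo_rng.shuffle(sexes)

    patients: list[PatientRecord] = []
    truth_rows: list[dict[str, Any]] = []
    for idx, entry in enumerate(config.roster):
        rng = np.random.default_rng(children[idx])
        n_per = int(rng.integers(config.dipoles_per_cluster[0],
                                 config.dipoles_per_cluster[1] + 1))
        n_sc = int(rng.integers(config.n_scatter[0], config.n_scatter[1] + 1))
        sources, gyri = plant_dipole_pattern(
            entry["pattern"], parcellation, rng,
            cluster_sd=config.cluster_sd,
            n_per_cluster=n_per,
            n_scatter=n_sc,
            scatter_min_sep=config.scatter_min_sep,
            amplitude=config.amplitude,
            straddle=bool(entry.get("straddle")),
        )

        topos = [
            simulate_topography(s, array, sphere, config.noise_sd, rng)
            for s in sources
        ]
        fitted = [fit_dipole(t, array, sphere, grid=grid) for t in topos]
        kept = filter_significant(fitted, config.gof_threshold)

        resection = generate_resection(
            sources, entry["resection"], parcellation,
            margin=config.resection_margin, seed=rng,
        )
        res_lobes = set(_resection_lobes(resection, parcellation))
        meg_lobes = set(parcellation.lobes_of(gyri))
        findings = _build_findings(entry, meg_lobes, res_lobes, all_lobes, rng)
        seeg = _build_seeg(entry, gyri, parcellation, rng)

        age = float(np.clip(demo_rng.normal(18.4, 9.0), 5.0, 44.0))
        duration = float(np.clip(demo_rng.normal(9.1, 8.8), 0.6, min(41.0, age)))
        follow_up = int(demo_rng.integers(12, 49))

        patients.append(
            PatientRecord(
                id=entry["id"],
                age=round(age, 1),
                sex=str(sexes[idx]),
                duration_years=round(duration, 1),
                engel_class=entry["engel"],
                follow_up_months=follow_up,
                dipoles=tuple(kept),
                true_sources=tuple(sources),
                topographies=tuple(topos),
                resection=resection,
                findings=findings,
                seeg=seeg,
            )
        )
        truth_rows.append(
            {
                "id": entry["id"],
                "pattern": PATTERN_NAMES[entry["pattern"]],
                "resection_status": entry["resection"],
                "outcome": "seizure_free"
                if entry["engel"].rstrip("abcd") == "I"
                else "not_seizure_free",
                "mri_category": entry["mri"],
                "conc_mri": entry["mri"] in ("concordant_exact", "concordant_extra"),
                "conc_pet": None if entry["pet"] is None
                else entry["pet"] == "concordant",
                "conc_eeg": entry["eeg"] == "concordant",
                "mri_resection_discordant": entry["mri"] != "concordant_exact",
                "seeg_sampling": None if not entry.get("seeg")
                else entry["seeg"]["sampling"] + "_sample",
                "seeg_soz": None if not entry.get("seeg")
                else entry["seeg"]["soz"] + "_concordance",
                "gyri": tuple(gyri),
            }
        )
    return patients, pd.DataFrame(truth_rows), parcellation
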