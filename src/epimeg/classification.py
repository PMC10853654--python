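"""Dipole-pattern classification: single cluster / multiple clusters / scattered.

A cluster is at least ``min_size`` dipoles forming a single-linkage
component at the linkage radius (default 10 mm, the operational reading of
"within about 1 cm^3").  Clusters are then judged against the gyral
parcellation:

* clusters whose gyrus sets share a gyrus or contain adjacent gyri are
  merged (clusters in adjacent gyri are one focus, not "multiple");
* a merged cluster is *valid* when its gyrus set is one gyrus or two
  adjacent gyri;
* exactly one valid cluster  -> single_cluster
* two or more valid clusters -> multiple_clusters (necessarily in
  non-adjacent gyri after merging)
* anything else              -> scattered (including few-dipole sets that
  form no cluster at all).

The precedence rule closes the gap between "a cluster needs >= 5 dipoles"
and "scattered means < 4 dipoles in different gyri": whatever yields no
valid cluster is scattered.  Dipoles in no valid cluster are outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .dipoles import CurrentDipole
from .parcellation import Parcellation, UnassignedDipoleError

__all__ = ["ClassificationResult", "detect_clusters", "classify_pattern"]

PATTERNS = ("single_cluster", "multiple_clusters", "scattered")


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of pattern classification for one patient.

    clusters/outliers partition the dipole indices; ``cluster_gyri`` holds
    the gyrus set of each valid cluster; ``meg_gyri``/``meg_lobes`` are the
    regions the MEG localization implicates (cluster gyri for clustered
    patterns, all assigned dipole gyri for scattered).
    """

    pattern: str
    clusters: tuple[frozenset[int], ...]
    outliers: frozenset[int]
    cluster_gyri: tuple[frozenset[int], ...]
    meg_gyri: frozenset[int]
    meg_lobes: frozenset[str]
    dipole_gyri: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        seen: set[int] = set(self.outliers)
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters/outliers must be disjoint")
            seen |= c


def detect_clusters(
    dipoles: Sequence[CurrentDipole],
    linkage_radius: float = 10.0,
    min_size: int = 5,
) -> tuple[list[set[int]], set[int]]:
    """Single-linkage components at ``linkage_radius``; components of at
    least ``min_size`` dipoles are clusters, the rest are outliers.

    Returns (clusters, outliers) as index sets into ``dipoles``; clusters
    are ordered by smallest member index for determinism.
    """
    n = len(dipoles)
    if n == 0:
        return [], set()
    pos = np.array([d.position for d in dipoles])
    if n == 1:
        comp_labels = np.zeros(1, dtype=int)
    else:
        close = squareform(pdist(pos) <= linkage_radius)
        graph = csr_matrix(close)
        _, comp_labels = connected_components(graph, directed=False)
    clusters: list[set[int]] = []
    outliers: set[int] = set()
    for label in np.unique(comp_labels):
        members = set(np.flatnonzero(comp_labels == label).tolist())
        if len(members) >= min_size:
            clusters.append(members)
        else:
            outliers |= members
    clusters.sort(key=min)
    return clusters, outliers


def _gyrus_sets_touch(s1: frozenset[int], s2: frozenset[int], parc: Parcellation) -> bool:
    if s1 & s2:
        return True
    return any(parc.are_adjacent(a, b) for a in s1 for b in s2)


def _is_valid(gyri: frozenset[int], parc: Parcellation) -> bool:
    if len(gyri) == 1:
        return True
    if len(gyri) == 2:
        a, b = sorted(gyri)
        return parc.are_adjacent(a, b)
    return False


def classify_pattern(
    dipoles: Sequence[CurrentDipole],
    parcellation: Parcellation,
    linkage_radius: float = 10.0,
    min_size: int = 5,
    snap_radius: float = 5.0,
) -> ClassificationResult:
    """Classify a patient's filtered dipole set.

    Dipoles that cannot be assigned a gyrus (beyond ``snap_radius`` from
    any label) are treated as outliers; a geometric cluster that drops
    below ``min_size`` assignable members is demoted entirely.
    """
    if len(dipoles) == 0:
        raise ValueError("cannot classify an empty dipole list")

    gyrus_of: dict[int, int] = {}
    unassigned: set[int] = set()
    for i, d in enumerate(dipoles):
        try:
            gyrus_of[i] = parcellation.assign_gyrus(d.position, snap_radius)
        except UnassignedDipoleError:
            unassigned.add(i)

    assignable = [i for i in range(len(dipoles)) if i not in unassigned]
    sub_dipoles = [dipoles[i] for i in assignable]
    raw_clusters, raw_outliers = detect_clusters(sub_dipoles, linkage_radius, min_size)
    # map back to original indices
    clusters = [{assignable[i] for i in c} for c in raw_clusters]
    outliers = {assignable[i] for i in raw_outliers} | unassigned

    # merge clusters whose gyrus sets share a gyrus or touch via adjacency
    gyri_of_cluster = [frozenset(gyrus_of[i] for i in c) for c in clusters]
    merged = True
    while merged:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if _gyrus_sets_touch(gyri_of_cluster[a], gyri_of_cluster[b], parcellation):
                    clusters[a] |= clusters[b]
                    gyri_of_cluster[a] |= gyri_of_cluster[b]
                    del clusters[b], gyri_of_cluster[b]
                    merged = True
                    break
            if merged:
                break

    valid = [
        (frozenset(c), g)
        for c, g in zip(clusters, gyri_of_cluster)
        if _is_valid(g, parcellation)
    ]
    for c, _ in zip(clusters, gyri_of_cluster):
        if not any(c <= vc for vc, _ in valid):
            outliers |= c

    if len(valid) == 1:
        pattern = "single_cluster"
    elif len(valid) >= 2:
        pattern = "multiple_clusters"
    else:
        pattern = "scattered"

    valid.sort(key=lambda cg: min(cg[0]))
    valid_clusters = tuple(c for c, _ in valid)
    valid_gyri = tuple(g for _, g in valid)
    if pattern == "scattered":
        meg_gyri = frozenset(gyrus_of.values())
    else:
        meg_gyri = frozenset().union(*valid_gyri)
    meg_lobes = frozenset(parcellation.lobes_of(sorted(meg_gyri)))

    return ClassificationResult(
        pattern=pattern,
        clusters=valid_clusters,
        outliers=frozenset(outliers),
        cluster_gyri=valid_gyri,
        meg_gyri=meg_gyri,
        meg_lobes=meg_lobes,
        dipole_gyri=gyrus_of,
    )
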