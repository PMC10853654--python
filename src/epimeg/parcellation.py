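"""Toy gyral parcellation of a spherical brain volume.

A parcellation is a labeled voxel grid (0 = outside the brain) with an
affine mapping voxel indices to mm, a gyrus -> lobe map and a symmetric
gyral adjacency graph.  It stands in for a cortical atlas parcellation:
what downstream rules need is only "which gyrus is this point in", "which
lobe is this gyrus in" and "are these gyri adjacent", all of which this
object provides.  Regions are grown as Voronoi cells of seed points inside
the brain sphere, so every region is connected and regions partition the
brain mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ParcellationSpec",
    "Parcellation",
    "generate_parcellation",
    "default_parcellation_spec",
    "UnassignedDipoleError",
]

LOBES = ("parietal", "occipital", "posterior_temporal", "non_posterior")
POSTERIOR_LOBES = ("parietal", "occipital", "posterior_temporal")


class UnassignedDipoleError(ValueError):
    """A point has no gyrus label within the snap radius."""


@dataclass(frozen=True)
class ParcellationSpec:
    """Layout from which a parcellation is grown.

    region_layout maps gyrus_id -> (lobe_label, seed point mm).  Adjacency
    may be given explicitly as id pairs or left None to be derived from
    voxel face-contacts of the grown regions (the geometric truth).
    """

    grid_shape: tuple[int, int, int] = (76, 76, 76)
    voxel_size: float = 2.5
    brain_radius: float = 85.0
    region_layout: Mapping[int, tuple[str, Sequence[float]]] = field(default_factory=dict)
    adjacency: frozenset[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        ids = list(self.region_layout)
        if len(ids) != len(set(ids)) or 0 in ids:
            raise ValueError("gyrus ids must be unique and nonzero")
        for gid, (lobe, seed) in self.region_layout.items():
            if lobe not in LOBES:
                raise ValueError(f"unknown lobe label {lobe!r} for gyrus {gid}")
        if self.adjacency is not None:
            pairs = frozenset(tuple(sorted(p)) for p in self.adjacency)
            for a, b in pairs:
                if a == b:
                    raise ValueError("adjacency must be irreflexive")
                if a not in self.region_layout or b not in self.region_layout:
                    raise ValueError("adjacency references unknown gyrus ids")
            object.__setattr__(self, "adjacency", pairs)


@dataclass(frozen=True)
class Parcellation:
    """Labeled voxel volume with lobe map and gyral adjacency."""

    label_volume: np.ndarray          # int array, 0 outside brain
    affine: np.ndarray                # (4, 4), voxel index -> mm
    gyrus_lobes: dict[int, str]
    adjacency: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_volume)) - {0}
        if not labels <= set(self.gyrus_lobes):
            raise ValueError("every nonzero label needs a lobe entry")
        for a, b in self.adjacency:
            if a not in self.gyrus_lobes or b not in self.gyrus_lobes:
                raise ValueError("adjacency references unknown gyrus ids")

    # -- coordinate helpers -------------------------------------------------
    @property
    def voxel_size(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.column_stack([p, np.ones(len(p))])
        return (homog @ inv.T)[:, :3]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.column_stack([v, np.ones(len(v))])
        return (homog @ self.affine.T)[:, :3]

    # -- queries ------------------------------------------------------------
    def gyrus_ids(self) -> list[int]:
        return sorted(self.gyrus_lobes)

    def are_adjacent(self, g1: int, g2: int) -> bool:
        return tuple(sorted((g1, g2))) in self.adjacency

    def lobe_of(self, gyrus_id: int) -> str:
        return self.gyrus_lobes[gyrus_id]

    def lobes_of(self, gyri: Sequence[int]) -> set[str]:
        return {self.gyrus_lobes[g] for g in gyri}

    def assign_gyrus(self, point_mm: np.ndarray, snap_radius: float = 5.0) -> int:
        """Gyrus label at a point; snap to the nearest label within
        ``snap_radius`` mm when the containing voxel is unlabeled.

        Raises :class:`UnassignedDipoleError` when no label is that close
        (the caller treats such a dipole as an outlier).
        """
        ijk = np.rint(self.mm_to_voxel(point_mm)[0]).astype(int)
        shape = self.label_volume.shape
        if np.all((ijk >= 0) & (ijk < shape)):
            label = int(self.label_volume[tuple(ijk)])
            if label != 0:
                return label
        # snap: nearest labeled voxel within the radius
        dist_vox, nearest = self._nearest_label_fields()
        ijk_c = np.clip(ijk, 0, np.array(shape) - 1)
        d_mm = dist_vox[tuple(ijk_c)]
        # add the clipping offset so out-of-grid points are not understated
        d_mm += np.linalg.norm((ijk - ijk_c) * self.voxel_size)
        if d_mm > snap_radius:
            raise UnassignedDipoleError(
                f"no gyrus label within {snap_radius} mm of point {point_mm}"
            )
        idx = tuple(n[tuple(ijk_c)] for n in nearest)
        return int(self.label_volume[idx])

    def interior_point(self, gyrus_id: int) -> np.ndarray:
        """mm coordinates of the deepest voxel of a gyrus (max distance to
        anything outside the gyrus); a stable "safe" planting site."""
        cache = getattr(self, "_ip_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_ip_cache", cache)
        if gyrus_id not in cache:
            region = self.label_volume == gyrus_id
            if not region.any():
                raise ValueError(f"gyrus {gyrus_id} has no voxels")
            depth = ndimage.distance_transform_edt(region, sampling=self.voxel_size)
            ijk = np.unravel_index(int(np.argmax(depth)), depth.shape)
            cache[gyrus_id] = self.voxel_to_mm(np.array(ijk))[0]
        return cache[gyrus_id]

    def _nearest_label_fields(self):
        cached = getattr(self, "_nlf_cache", None)
        if cached is None:
            dist, nearest = ndimage.distance_transform_edt(
                self.label_volume == 0,
                sampling=self.voxel_size,
                return_indices=True,
            )
            cached = (dist, tuple(nearest))
            object.__setattr__(self, "_nlf_cache", cached)
        return cached


def default_parcellation_spec() -> ParcellationSpec:
    """Twelve gyri over four lobes on an 85-mm brain sphere.

    Posterior lobes (parietal, occipital, posterior temporal) occupy the
    superior-posterior, inferior-posterior and lateral-posterior cortex;
    everything anterior is lumped into non_posterior.  Seeds are placed so
    each lobe holds several gyri and non-adjacent gyrus pairs exist both
    within and across lobes.
    """
    layout = {
        1: ("parietal", (0.0, -30.0, 70.0)),
        2: ("parietal", (42.0, -32.0, 52.0)),
        3: ("parietal", (-42.0, -32.0, 52.0)),
        4: ("parietal", (0.0, -65.0, 45.0)),
        5: ("occipital", (0.0, -78.0, -8.0)),
        6: ("occipital", (36.0, -64.0, -12.0)),
        7: ("occipital", (-36.0, -64.0, -12.0)),
        8: ("posterior_temporal", (58.0, -38.0, -2.0)),
        9: ("posterior_temporal", (-58.0, -38.0, -2.0)),
        10: ("non_posterior", (0.0, 42.0, 55.0)),
        11: ("non_posterior", (48.0, 32.0, -2.0)),
        12: ("non_posterior", (-48.0, 32.0, -2.0)),
    }
    return ParcellationSpec(region_layout=layout)


def generate_parcellation(spec: ParcellationSpec | None = None, seed: int = 0) -> Parcellation:
    """Grow a parcellation from a spec: Voronoi cells of the seed points
    restricted to the brain sphere.

    Voronoi cells of distinct seeds are convex, so each region is
    connected, and together they tile the brain mask exactly.  The seed
    argument is accepted for interface symmetry; the construction itself
    is deterministic.  Coincident seed points are a generation error.
    """
    if spec is None:
        spec = default_parcellation_spec()
    if not spec.region_layout:
        raise ValueError("region_layout must define at least one gyrus")

    ids = sorted(spec.region_layout)
    seeds = np.array([spec.region_layout[g][1] for g in ids], dtype=float)
    if len(np.unique(seeds, axis=0)) != len(seeds):
        raise ValueError("overlapping (coincident) region seeds")

    shape = np.array(spec.grid_shape, dtype=int)
    vox = float(spec.voxel_size)
    # affine centered on the grid: voxel (i,j,k) -> mm
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -vox * (shape - 1) / 2.0

    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack(grids, axis=-1).reshape(-1, 3) * vox + affine[:3, 3]
    inside = np.linalg.norm(coords, axis=1) <= spec.brain_radius

    labels = np.zeros(int(np.prod(shape)), dtype=np.int16)
    d2 = ((coords[inside, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels[inside] = np.asarray(ids, dtype=np.int16)[np.argmin(d2, axis=1)]
    volume = labels.reshape(tuple(shape))

    if spec.adjacency is not None:
        adjacency = spec.adjacency
    else:
        adjacency = _derive_adjacency(volume)

    lobes = {g: spec.region_layout[g][0] for g in ids}
    return Parcellation(
        label_volume=volume, affine=affine, gyrus_lobes=lobes, adjacency=adjacency
    )


def _derive_adjacency(volume: np.ndarray) -> frozenset[tuple[int, int]]:
    """Gyrus pairs whose regions share a voxel face."""
    pairs: set[tuple[int, int]] = set()
    for axis in range(3):
        a = np.moveaxis(volume, axis, 0)[:-1]
        b = np.moveaxis(volume, axis, 0)[1:]
        touching = (a != b) & (a != 0) & (b != 0)
        stacked = np.sort(
            np.column_stack([a[touching].ravel(), b[touching].ravel()]), axis=1
        )
        for x, y in np.unique(stacked, axis=0):
            pairs.add((int(x), int(y)))
    return frozenset(pairs)
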