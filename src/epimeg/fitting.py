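"""Single-equivalent-current-dipole inverse fit.

For a candidate position the moment is the linear least-squares solution
against the (channels x 3) lead field, so the nonlinear search runs over
position only.  The search is a coarse grid over the sphere interior
(default 10 mm spacing) followed by derivative-free local refinement
(Nelder-Mead on the normalized residual).  Goodness of fit is

    gof = 1 - sum (b_meas - b_fit)^2 / sum b_meas^2,

clipped to [0, 1].  Everything is deterministic: ties in the grid stage
break toward larger gof, then lexicographically smallest position.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dipoles import CurrentDipole, FieldTopography
from .forward import sarvas_field
from .sensors import SensorArray, SphereModel

__all__ = ["LeadFieldGrid", "fit_dipole"]


def _lead_field(
    positions_mm: np.ndarray, array: SensorArray, sphere: SphereModel
) -> np.ndarray:
    """Lead fields for unit moments along x, y, z: shape (n_pos, n_chan, 3)."""
    pos = np.atleast_2d(positions_mm)
    out = np.empty((pos.shape[0], array.n_channels, 3))
    eye = np.eye(3)
    for g, p in enumerate(pos):
        for j in range(3):
            B = sarvas_field(eye[j], p, array.channel_positions, center_mm=sphere.center)
            out[g, :, j] = np.einsum("ij,ij->i", B, array.channel_orientations)
    return out


@dataclass
class LeadFieldGrid:
    """Precomputed coarse-search grid, reusable across fits on one array."""

    positions: np.ndarray       # (g, 3) mm
    G: np.ndarray               # (g, n_chan, 3)
    GtG: np.ndarray             # (g, 3, 3)

    @classmethod
    def build(
        cls,
        array: SensorArray,
        sphere: SphereModel,
        spacing: float = 10.0,
        margin: float = 5.0,
    ) -> "LeadFieldGrid":
        """Cubic grid of candidate positions strictly inside the sphere.

        ``margin`` keeps candidates away from the surface where the lead
        field becomes ill-conditioned.
        """
        r = sphere.radius - margin
        axis = np.arange(-sphere.radius, sphere.radius + spacing / 2, spacing)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts = pts[np.linalg.norm(pts, axis=1) <= r] + sphere.center
        # deterministic ordering: lexicographic by (x, y, z)
        order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
        pts = pts[order]
        G = _lead_field(pts, array, sphere)
        GtG = np.einsum("gci,gcj->gij", G, G)
        return cls(positions=pts, G=G, GtG=GtG)


_GRID_CACHE: dict[bytes, LeadFieldGrid] = {}


def _cached_grid(array: SensorArray, sphere: SphereModel, spacing: float) -> LeadFieldGrid:
    key = hashlib.sha256(
        array.fingerprint()
        + sphere.center.tobytes()
        + np.float64([sphere.radius, spacing]).tobytes()
    ).digest()
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = LeadFieldGrid.build(array, sphere, spacing=spacing)
    return _GRID_CACHE[key]


def _residual_at(
    pos: np.ndarray,
    b: np.ndarray,
    array: SensorArray,
    sphere: SphereModel,
    ridge: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Normalized residual power and best moment at one position."""
    G = _lead_field(pos[None, :], array, sphere)[0]
    GtG = G.T @ G
    Gtb = G.T @ b
    m = np.linalg.solve(GtG + ridge * (np.trace(GtG) + 1.0) * np.eye(3), Gtb)
    resid = b - G @ m
    return float(resid @ resid / (b @ b)), m


def fit_dipole(
    topography: FieldTopography,
    array: SensorArray,
    sphere: SphereModel,
    *,
    grid_spacing: float = 10.0,
    grid: LeadFieldGrid | None = None,
    refine: bool = True,
    xatol: float = 1e-3,
    fatol: float = 1e-6,
) -> CurrentDipole:
    """Fit one equivalent current dipole to a spike-peak topography.

    Parameters
    ----------
    topography : measured per-channel field, fT
    grid : optionally a prebuilt :class:`LeadFieldGrid`; otherwise one is
        built for ``grid_spacing`` and cached per (array, sphere).
    refine : run Nelder-Mead refinement from the best grid node.

    Raises
    ------
    ValueError : all-zero topography (nothing to fit).
    """
    b = topography.values
    if b.shape[0] != array.n_channels:
        raise ValueError("topography length does not match the sensor array")
    ss_b = float(b @ b)
    if ss_b == 0.0:
        raise ValueError("cannot fit a dipole to an all-zero topography")

    if grid is None:
        grid = _cached_grid(array, sphere, grid_spacing)

    Gtb = np.einsum("gci,c->gi", grid.G, b)
    traces = np.einsum("gii->g", grid.GtG)
    # absolute floor keeps degenerate nodes (e.g. the sphere center, where
    # every moment is externally silent) solvable with a zero moment
    ridge = 1e-12 * traces + 1e-12 * (traces.max() + 1.0)
    A = grid.GtG + ridge[:, None, None] * np.eye(3)[None, :, :]
    moments = np.linalg.solve(A, Gtb[..., None])[..., 0]
    ss_res = ss_b - np.einsum("gi,gi->g", moments, Gtb)
    gof = 1.0 - ss_res / ss_b
    # best gof; ties -> lexicographically smallest position (grid is sorted)
    best = int(np.argmax(gof > np.max(gof) - 1e-15))

    pos = grid.positions[best].copy()
    if refine:
        r_max = sphere.radius - 2.0

        def objective(p: np.ndarray) -> float:
            depth = np.linalg.norm(p - sphere.center)
            if depth >= r_max:
                return 1.0 + (depth - r_max)  # push back inside
            return _residual_at(p, b, array, sphere)[0]

        # Nelder-Mead with restarts (a fresh simplex escapes premature
        # collapse), then a Powell polish
        x, fx = pos, 1.0 - gof[best]
        for _ in range(3):
            res = optimize.minimize(
                objective, x, method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": 400},
            )
            improved = res.fun < fx - fatol * 0.1
            if res.fun < fx:
                x, fx = res.x, res.fun
            if not improved:
                break
        res = optimize.minimize(
            objective, x, method="Powell",
            options={"xtol": xatol, "ftol": fatol, "maxiter": 200},
        )
        if res.fun < fx:
            x, fx = res.x, res.fun
        if fx <= 1.0 - gof[best]:
            pos = x

    nres, moment = _residual_at(pos, b, array, sphere)
    return CurrentDipole(
        position=pos,
        moment=moment,
        gof=float(np.clip(1.0 - nres, 0.0, 1.0)),
        spike_id=topography.spike_id,
    )
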