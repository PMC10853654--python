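"""Sensor-array and conductor geometry.

The measurement model is a whole-head helmet of radial magnetometers above a
spherically symmetric volume conductor.  Real MEG systems mix magnetometers
and planar gradiometers; radial magnetometers on a hemisphere keep the
forward physics simple while exercising every downstream stage, and the
channel count and helmet radius are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SphereModel", "SensorArray", "generate_sensor_array"]


@dataclass(frozen=True)
class SphereModel:
    """Homogeneous spherical volume conductor.

    Parameters
    ----------
    center : (3,) array-like, mm
    radius : float, mm
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 90.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Strict interior test for one or many points (mm)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.linalg.norm(p - self.center, axis=-1) < self.radius


@dataclass(frozen=True)
class SensorArray:
    """Set of point magnetometers with sensing orientations.

    positions are in mm in the head frame; orientations are unit vectors
    giving the sensed field component (radial for the default helmet).
    """

    channel_positions: np.ndarray
    channel_orientations: np.ndarray
    helmet_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.channel_positions, dtype=float)
        ori = np.asarray(self.channel_orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise ValueError("positions/orientations must be matching (n, 3) arrays")
        if pos.shape[0] < 8:
            raise ValueError("at least 8 channels are required")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("channel orientations must have unit norm")
        object.__setattr__(self, "channel_positions", pos)
        object.__setattr__(self, "channel_orientations", ori)

    @property
    def n_channels(self) -> int:
        return self.channel_positions.shape[0]

    def fingerprint(self) -> bytes:
        """Stable identity for lead-field caching."""
        return (
            self.channel_positions.tobytes()
            + self.channel_orientations.tobytes()
            + np.float64(self.helmet_radius).tobytes()
        )


def generate_sensor_array(
    n_channels: int = 102,
    helmet_radius: float = 110.0,
    seed: int = 0,
    *,
    min_elevation: float = 0.0,
) -> SensorArray:
    """Quasi-uniform radial magnetometers on the upper hemisphere.

    Channels are placed on a Fibonacci lattice over ``z >= min_elevation *
    radius`` and sense the radial field component (orientation pointing away
    from the origin).  The seed rotates the lattice about z, so distinct
    seeds give distinct but equally uniform arrays and a fixed seed is
    fully deterministic.
    """
    if n_channels < 8:
        raise ValueError("n_channels must be >= 8")
    if helmet_radius <= 0:
        raise ValueError("helmet_radius must be positive")

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_channels)
    # z from just above the rim to the pole, open at the ends
    z = min_elevation + (1.0 - min_elevation) * (k + 0.5) / n_channels
    theta = golden * k + phase
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    directions = np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return SensorArray(
        channel_positions=helmet_radius * directions,
        channel_orientations=directions,
        helmet_radius=float(helmet_radius),
    )
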