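"""Current-dipole and field-topography containers plus the significance filter."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["CurrentDipole", "FieldTopography", "filter_significant"]


@dataclass(frozen=True)
class CurrentDipole:
    """A fitted (or planted) equivalent current dipole.

    position : (3,) mm, head frame
    moment   : (3,) nA*m
    gof      : goodness of fit, fraction in [0, 1]; 1 - residual/total power
    spike_id : identifier of the spike the dipole was fitted to
    """

    position: np.ndarray
    moment: np.ndarray
    gof: float = 1.0
    spike_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        mom = np.asarray(self.moment, dtype=float)
        if pos.shape != (3,) or mom.shape != (3,):
            raise ValueError("position and moment must be 3-vectors")
        if not (0.0 <= self.gof <= 1.0):
            raise ValueError(f"gof must lie in [0, 1], got {self.gof}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", mom)


@dataclass(frozen=True)
class FieldTopography:
    """Per-channel measurements (femtotesla) of one spike-peak field map."""

    values: np.ndarray
    spike_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("topography values must be a 1-d vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("topography values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def filter_significant(
    dipoles: Iterable[CurrentDipole], threshold: float = 0.85
) -> list[CurrentDipole]:
    """Keep dipoles whose goodness of fit strictly exceeds ``threshold``.

    The acceptance rule is strict (> 85% by default): a dipole at exactly
    the threshold is rejected.  Input order is preserved.
    """
    return [d for d in dipoles if d.gof > threshold]
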