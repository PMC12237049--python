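"""Depth-ordered flux profiles.

A :class:`FluxProfile` holds the flux of one taxon (or a taxon aggregate) for
one trap deployment as a function of depth. It is the common currency between
the flux arithmetic (depth averaging) and the sinking-speed inversion
(depth integration, rigid-translation solve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UserInputError

__all__ = ["FluxProfile"]


@dataclass(frozen=True)
class FluxProfile:
    """Fluxes of one taxon at strictly increasing depths.

    Parameters
    ----------
    depths_m
        Trap depths in meters, strictly increasing, all positive.
    values
        Fluxes at those depths (cells m-2 d-1 by default), non-negative.
    sigmas
        Optional symmetric 1-sigma uncertainties, same length as ``values``.
    taxon, deployment
        Identity of the profile; ``deployment`` counts from 1.
    interval_midpoint_d
        Time coordinate (days) of the collection-interval midpoint, used when
        profiles from successive deployments are differenced.
    units
        Unit string carried through to derived records.
    """

    depths_m: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray | None = None
    taxon: str = ""
    deployment: int = 0
    interval_midpoint_d: float = 0.0
    units: str = "cells m-2 d-1"

    def __post_init__(self) -> None:
        z = np.asarray(self.depths_m, dtype=float)
        f = np.asarray(self.values, dtype=float)
        if z.ndim != 1 or f.ndim != 1 or z.size != f.size:
            raise UserInputError("depths and fluxes must be 1-D and equal length")
        if z.size == 0:
            raise UserInputError("empty profile")
        if np.any(z <= 0):
            raise UserInputError("depths must be positive")
        if np.any(np.diff(z) <= 0):
            raise UserInputError("depths must be strictly increasing")
        if np.any(f < 0):
            raise UserInputError("fluxes must be non-negative")
        s = self.sigmas
        if s is not None:
            s = np.asarray(s, dtype=float)
            if s.shape != f.shape:
                raise UserInputError("sigmas must match fluxes in length")
            if np.any(s < 0):
                raise UserInputError("sigmas must be non-negative")
        object.__setattr__(self, "depths_m", z)
        object.__setattr__(self, "values", f)
        object.__setattr__(self, "sigmas", s)

    def __len__(self) -> int:
        return int(self.depths_m.size)

    @property
    def z_min(self) -> float:
        return float(self.depths_m[0])

    @property
    def z_max(self) -> float:
        return float(self.depths_m[-1])

    def interp(self, z: np.ndarray, extrapolation: str = "constant") -> np.ndarray:
        """Linear interpolation of the flux at depths ``z``.

        ``extrapolation='constant'`` holds the endpoint fluxes outside the
        sampled range; ``'none'`` raises for out-of-range queries.
        """
        z = np.asarray(z, dtype=float)
        if extrapolation == "none":
            if np.any(z < self.z_min) or np.any(z > self.z_max):
                raise UserInputError("depth outside profile support")
        elif extrapolation != "constant":
            raise UserInputError(f"unknown extrapolation {extrapolation!r}")
        return np.interp(z, self.depths_m, self.values)
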