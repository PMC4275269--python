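"""Vertical regridding of casts onto a 1 m depth grid, and layer means.

The analysis works on the 0–50 m band split into three layers, 0–10 m,
11–30 m and 31–50 m (integer grid depths; the three ranges partition 0..50).
Each QC-passed cast is linearly interpolated onto integer depths between its
shallowest and deepest level — never extrapolated — and layer averages are
taken over the defined grid values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .profiles import TemperatureProfile

__all__ = [
    "DepthLayer", "L0_10", "L11_30", "L31_50", "BAND_0_50", "LAYERS",
    "InterpolatedProfile", "interpolate_1m", "layer_mean",
]

MAX_DEPTH = 50


@dataclass(frozen=True)
class DepthLayer:
    """A closed integer interval of grid depths, e.g. [11, 30]."""

    label: str
    lo: int
    hi: int

    @property
    def depths(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1

    def __contains__(self, depth: int) -> bool:
        return self.lo <= depth <= self.hi

    def overlaps(self, dmin: float, dmax: float) -> bool:
        """Does the (possibly fractional) depth range intersect this layer?"""
        return dmin <= self.hi and dmax >= self.lo


L0_10 = DepthLayer("L0_10", 0, 10)
L11_30 = DepthLayer("L11_30", 11, 30)
L31_50 = DepthLayer("L31_50", 31, 50)
#: Merged band used for the headline 0–50 m association analysis.
BAND_0_50 = DepthLayer("BAND_0_50", 0, 50)
LAYERS = (L0_10, L11_30, L31_50)


@dataclass
class InterpolatedProfile:
    """Source metadata plus temperatures on the integer 0..50 m grid.

    ``grid_temps[z]`` is NaN wherever the source levels do not bracket depth
    ``z`` (no extrapolation).  Index ``z`` runs 0..50 inclusive.
    """

    source: TemperatureProfile
    grid_temps: np.ndarray  # shape (51,), NaN where undefined

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.grid_temps)

    def value_at(self, depth: int) -> float:
        return float(self.grid_temps[depth])


def interpolate_1m(profile: TemperatureProfile,
                   surface_fill: bool = False) -> InterpolatedProfile:
    """Piecewise-linear regrid of one cast onto integer depths 0..50 m.

    Grid depths outside [shallowest, deepest] source level are left
    undefined.  With ``surface_fill=True`` the shallowest measured value is
    carried up to 0 m as a constant (only meaningful for casts whose
    shallowest level already passed the shallow-sampling QC rule).

    A cast with fewer than 2 levels intersecting 0–50 m yields an empty
    grid; callers decide what to do with it.
    """
    z, t = profile.depths, profile.temps
    grid = np.full(MAX_DEPTH + 1, np.nan)
    if z.size >= 2:
        zg = np.arange(MAX_DEPTH + 1, dtype=float)
        inside = (zg >= z[0]) & (zg <= z[-1])
        if inside.sum() >= 1 and (z[0] <= MAX_DEPTH):
            grid[inside] = np.interp(zg[inside], z, t)
        if surface_fill and z[0] > 0 and z[0] <= MAX_DEPTH:
            grid[: int(np.ceil(z[0]))] = t[0]
        # an empty or single-point overlap with 0-50 m counts as no data
        if np.count_nonzero(~np.isnan(grid)) < 2:
            grid[:] = np.nan
    return InterpolatedProfile(source=profile, grid_temps=grid)


def layer_mean(ip: InterpolatedProfile, layer: DepthLayer,
               min_coverage: float = 0.5) -> float:
    """Unweighted mean of defined grid values inside ``layer``.

    Returns NaN when fewer than ``min_coverage`` of the layer's integer
    depths carry a value — a partially sampled layer is treated as missing
    rather than biased toward whichever part was sampled.
    """
    vals = ip.grid_temps[layer.lo: layer.hi + 1]
    ok = ~np.isnan(vals)
    if ok.sum() < min_coverage * layer.size:
        return float("nan")
    return float(vals[ok].mean())
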