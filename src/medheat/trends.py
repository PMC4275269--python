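"""Gridded linear temperature trends with significance masking.

For every 1°×1° cell and depth layer, profiles from the selected months are
reduced to yearly mean layer temperatures, and that yearly series is
regressed on calendar year by ordinary least squares.  The slope's two-sided
t-test (n−2 degrees of freedom) provides the significance mask: a cell is
*significant* at the default 90% confidence when p ≤ 0.10.  Cells with fewer
than ``min_years`` distinct years are reported as insufficient rather than
merely non-significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interp import BAND_0_50, LAYERS, DepthLayer, interpolate_1m, layer_mean
from .profiles import ProfileSet

__all__ = [
    "GridSpec", "CellLayerSeries", "TrendCellResult",
    "assign_cell", "build_yearly_series", "fit_trend", "trend_map",
    "trend_table",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid with integer-degree origin.

    Cell assignment is half-open: a point belongs to the cell whose lower
    edge it sits on, so every finite coordinate maps to exactly one cell.
    The cell index is ``(i, j) = (floor(lon/size), floor(lat/size))``.
    """

    cell_size: float = 1.0

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValueError("coordinates must be finite")
        return (math.floor(lon / self.cell_size),
                math.floor(lat / self.cell_size))

    def bounds(self, cell: tuple[int, int]) -> tuple[float, float, float, float]:
        """(lon_lo, lon_hi, lat_lo, lat_hi) of a cell, half-open on top."""
        i, j = cell
        s = self.cell_size
        return (i * s, (i + 1) * s, j * s, (j + 1) * s)


def assign_cell(lat: float, lon: float,
                grid: GridSpec | None = None) -> tuple[int, int]:
    """Map a point to its grid cell (module-level convenience)."""
    return (grid or GridSpec()).cell_of(lat, lon)


@dataclass
class CellLayerSeries:
    """Yearly mean layer temperature for one cell, with sample counts."""

    cell: tuple[int, int]
    layer: DepthLayer
    values: dict[int, float] = field(default_factory=dict)   # year -> °C
    n_profiles: dict[int, int] = field(default_factory=dict)  # year -> count

    @property
    def n_years(self) -> int:
        return len(self.values)


@dataclass
class TrendCellResult:
    """OLS trend of one cell × layer yearly series."""

    cell: tuple[int, int]
    layer: DepthLayer
    slope: float       # °C/yr
    intercept: float   # °C at year 0
    p_value: float
    n_years: int
    significant: bool
    stderr: float = float("nan")  # standard error of the slope


def build_yearly_series(pset: ProfileSet,
                        grid: GridSpec,
                        layer: DepthLayer,
                        months: Iterable[int] = (7, 8, 9, 10, 11),
                        min_coverage: float = 0.5,
                        _interp_cache: dict | None = None,
                        ) -> dict[tuple[int, int], CellLayerSeries]:
    """Aggregate QC-passed profiles into per-cell yearly mean series.

    The yearly value is the plain mean of the layer means of all in-cell,
    in-month profiles of that year; profiles whose layer mean is undefined
    (insufficient vertical coverage) are excluded, and years with no usable
    profile are simply absent.
    """
    months = set(months)
    acc: dict[tuple[int, int], CellLayerSeries] = {}
    for p in pset:
        if p.month not in months:
            continue
        if _interp_cache is not None and p.profile_id in _interp_cache:
            ip = _interp_cache[p.profile_id]
        else:
            ip = interpolate_1m(p)
            if _interp_cache is not None:
                _interp_cache[p.profile_id] = ip
        lm = layer_mean(ip, layer, min_coverage)
        if math.isnan(lm):
            continue
        cell = grid.cell_of(p.latitude, p.longitude)
        s = acc.setdefault(cell, CellLayerSeries(cell=cell, layer=layer))
        # accumulate running sums; finalized below
        s.values[p.year] = s.values.get(p.year, 0.0) + lm
        s.n_profiles[p.year] = s.n_profiles.get(p.year, 0) + 1
    for s in acc.values():
        for yr in s.values:
            s.values[yr] /= s.n_profiles[yr]
    return acc


def fit_trend(series: CellLayerSeries,
              confidence: float = 0.90,
              min_years: int = 10) -> TrendCellResult | None:
    """OLS of yearly temperature on calendar year.

    Returns ``None`` when the series has fewer than ``min_years`` distinct
    years (or a degenerate single year).  ``p_value`` is the two-sided
    t-test on the slope with n−2 degrees of freedom.
    """
    if series.n_years < max(min_years, 2):
        return None
    years = np.array(sorted(series.values))
    temps = np.array([series.values[y] for y in years])
    res = stats.linregress(years, temps)
    p = float(res.pvalue)
    return TrendCellResult(
        cell=series.cell,
        layer=series.layer,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=p,
        n_years=int(len(years)),
        significant=bool(p <= 1.0 - confidence),
        stderr=float(res.stderr),
    )


def trend_map(pset: ProfileSet,
              grid: GridSpec | None = None,
              layers: Sequence[DepthLayer] = (*LAYERS, BAND_0_50),
              months: Iterable[int] = (7, 8, 9, 10, 11),
              confidence: float = 0.90,
              min_years: int = 10,
              min_coverage: float = 0.5) -> list[TrendCellResult]:
    """Fit one trend per (cell, layer) with sufficient data.

    The merged 0–50 m band is fitted from its own 0–50 m layer means, not
    from an average of the three per-layer slopes.
    """
    grid = grid or GridSpec()
    cache: dict = {}
    out: list[TrendCellResult] = []
    for layer in layers:
        series = build_yearly_series(pset, grid, layer, months,
                                     min_coverage, _interp_cache=cache)
        for s in series.values():
            r = fit_trend(s, confidence=confidence, min_years=min_years)
            if r is not None:
                out.append(r)
    return out


def trend_table(results: Sequence[TrendCellResult],
                grid: GridSpec | None = None) -> pd.DataFrame:
    """Flat export of a trend map (one row per cell × layer)."""
    grid = grid or GridSpec()
    rows = []
    for r in results:
        lon_lo, _, lat_lo, _ = grid.bounds(r.cell)
        rows.append({
            "cell_lon_edge": lon_lo,
            "cell_lat_edge": lat_lo,
            "layer": r.layer.label,
            "slope": r.slope,
            "intercept": r.intercept,
            "p_value": r.p_value,
            "stderr": r.stderr,
            "n_years": r.n_years,
            "significant": r.significant,
        })
    return pd.DataFrame(rows, columns=[
        "cell_lon_edge", "cell_lat_edge", "layer", "slope", "intercept",
        "p_value", "stderr", "n_years", "significant"])
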