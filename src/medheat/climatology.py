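"""Local-scale climatology, event-month anomalies, and warm-extreme counts.

Within ~2°×2° region boxes the profile record is split into two reference
periods — 1945–1982 (before the first documented mass mortality) and
1983–2011 — and condensed into monthly mean temperature profiles with
standard-deviation envelopes on the 1 m grid.  The temperature state of an
event month is then expressed as an anomaly profile against each period's
climatology, and the month-by-month frequency of *positive temperature
extremes* (layer means exceeding the full-period mean, or the mean plus one
SD) is tabulated per period.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .interp import LAYERS, MAX_DEPTH, DepthLayer, interpolate_1m, layer_mean
from .profiles import ProfileSet, TemperatureProfile

__all__ = [
    "RegionBox", "Period", "P1945_1982", "P1983_2011", "FULL_1945_2011",
    "ClimatologyProfile", "AnomalyProfile",
    "monthly_climatology", "event_anomaly", "extreme_frequency",
    "DEFAULT_BOXES",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionBox:
    """Named lat/lon rectangle, optionally limited to shallow stations.

    ``max_seafloor_depth_m`` is honoured only when profiles carry a
    seafloor-depth attribute; profile records here do not, so the box is
    used as-is and a warning is logged when the limit is set.
    """

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    max_seafloor_depth_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError("degenerate region box")

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat_min <= lat <= self.lat_max
                and self.lon_min <= lon <= self.lon_max)


@dataclass(frozen=True)
class Period:
    label: str
    start: int
    end: int  # inclusive

    def __contains__(self, year: int) -> bool:
        return self.start <= year <= self.end


P1945_1982 = Period("P1945_1982", 1945, 1982)
P1983_2011 = Period("P1983_2011", 1983, 2011)
FULL_1945_2011 = Period("FULL_1945_2011", 1945, 2011)

#: Editable default bounds for the five repeatedly affected areas; box
#: extents are ~2°×2° rectangles centred on the coasts in question.
DEFAULT_BOXES = (
    RegionBox("Ligurian Sea", 43.0, 44.5, 7.5, 10.0),
    RegionBox("Provence Coast", 42.0, 43.5, 4.5, 7.5),
    RegionBox("Eastern Tyrrhenian", 39.5, 41.5, 13.0, 15.5),
    RegionBox("Western Tyrrhenian", 40.5, 42.5, 9.5, 12.0),
    RegionBox("Balearic-Columbretes", 38.5, 40.5, 0.0, 4.0),
)


@dataclass
class ClimatologyProfile:
    """Per-depth mean/SD of all qualifying casts (box × month × period).

    Arrays are indexed by integer depth 0..50; depths sampled by fewer than
    ``n_min`` casts are NaN (counts still reported).  SD is the sample
    (n−1) standard deviation.
    """

    box: RegionBox
    month: int
    period: Period
    mean_t: np.ndarray
    sd_t: np.ndarray
    n: np.ndarray

    @property
    def empty(self) -> bool:
        return bool(np.all(np.isnan(self.mean_t)))


@dataclass
class AnomalyProfile:
    """Event-month mean profile minus the reference climatology.

    One delta per reference period; ``max_anomaly[label]`` is the largest
    *positive* delta and its depth (first occurrence from the surface when
    tied), or ``None`` when no positive anomaly exists.  ``no_data`` marks
    the explicit absence of event-month profiles — never rendered as a zero
    anomaly.
    """

    box: RegionBox
    year: int
    month: int
    n_event_profiles: int
    delta_t: dict[str, np.ndarray] = field(default_factory=dict)
    max_anomaly: dict[str, tuple[float, int] | None] = field(default_factory=dict)

    @property
    def no_data(self) -> bool:
        return self.n_event_profiles == 0


def _box_month_grids(pset: ProfileSet, box: RegionBox, month: int,
                     years: Iterable[int] | Period) -> np.ndarray:
    """Stack the 1 m grids of qualifying casts → array (n_profiles, 51)."""
    if box.max_seafloor_depth_m is not None:
        log.warning("box %s requests seafloor limit %.0f m but profiles "
                    "carry no seafloor depth; using the full box",
                    box.name, box.max_seafloor_depth_m)
    rows = []
    for p in pset:
        if p.month != month or p.year not in years:
            continue
        if not box.contains(p.latitude, p.longitude):
            continue
        rows.append(interpolate_1m(p).grid_temps)
    if not rows:
        return np.empty((0, MAX_DEPTH + 1))
    return np.vstack(rows)


def monthly_climatology(pset: ProfileSet, box: RegionBox, month: int,
                        period: Period, n_min: int = 3) -> ClimatologyProfile:
    """Mean/SD temperature at each 1 m depth over one box, month and period.

    Statistics at a given depth use every cast whose interpolated grid is
    defined there; depths with fewer than ``n_min`` casts are masked.  An
    empty selection yields an all-NaN climatology (callers render nothing).
    """
    grids = _box_month_grids(pset, box, month, period)
    nz = MAX_DEPTH + 1
    mean_t = np.full(nz, np.nan)
    sd_t = np.full(nz, np.nan)
    n = np.zeros(nz, dtype=int)
    if len(grids):
        defined = ~np.isnan(grids)
        n = defined.sum(axis=0)
        ok = n >= max(n_min, 1)
        with np.errstate(invalid="ignore"):
            mean_t[ok] = np.nanmean(grids[:, ok], axis=0)
            sd = np.full(nz, np.nan)
            two = ok & (n >= 2)
            sd[two] = np.nanstd(grids[:, two], axis=0, ddof=1)
            sd_t = sd
    return ClimatologyProfile(box=box, month=month, period=period,
                              mean_t=mean_t, sd_t=sd_t, n=n)


def event_anomaly(pset: ProfileSet, box: RegionBox, year: int, month: int,
                  reference_periods: Sequence[Period] = (P1945_1982, P1983_2011),
                  n_min: int = 3) -> AnomalyProfile:
    """Anomaly of the event month's mean profile against period climatologies.

    The event-month mean uses *all* in-box casts of that calendar month and
    year, not only casts at the mortality site.  Returns an explicit
    ``no_data`` result when no such cast exists.
    """
    grids = _box_month_grids(pset, box, month, [year])
    out = AnomalyProfile(box=box, year=year, month=month,
                         n_event_profiles=len(grids))
    if not len(grids):
        return out
    defined = ~np.isnan(grids)
    counts = defined.sum(axis=0)
    sums = np.where(defined, grids, 0.0).sum(axis=0)
    event_mean = np.divide(sums, counts, out=np.full(grids.shape[1], np.nan),
                           where=counts > 0)
    for period in reference_periods:
        clim = monthly_climatology(pset, box, month, period, n_min=n_min)
        delta = event_mean - clim.mean_t
        out.delta_t[period.label] = delta
        pos = np.where(np.nan_to_num(delta, nan=-np.inf) > 0)[0]
        if pos.size:
            zmax = int(pos[np.argmax(delta[pos])])
            out.max_anomaly[period.label] = (float(delta[zmax]), zmax)
        else:
            out.max_anomaly[period.label] = None
    return out


def extreme_frequency(pset: ProfileSet,
                      boxes: Sequence[RegionBox],
                      layers: Sequence[DepthLayer] = LAYERS,
                      months: Iterable[int] = (7, 8, 9, 10, 11),
                      periods: Sequence[Period] = (P1945_1982, P1983_2011),
                      reference: Period = FULL_1945_2011,
                      min_coverage: float = 0.5) -> pd.DataFrame:
    """Count warm extremes per (box, layer, month, period).

    A cast is a *positive temperature extreme* when its layer-mean
    temperature exceeds the full-reference-period mean (column
    ``n_gt_mean``) or the mean plus one sample SD (``n_gt_mean_plus_sd``).
    Counts are also emitted as proportions of the period's cast count.
    """
    months = sorted(set(months))
    rows = []
    # precompute layer means of every cast once
    lm_cache: list[tuple[TemperatureProfile, dict[str, float]]] = []
    for p in pset:
        ip = interpolate_1m(p)
        lm_cache.append((p, {ly.label: layer_mean(ip, ly, min_coverage)
                             for ly in layers}))
    for box in boxes:
        for layer in layers:
            for month in months:
                ref_vals = [v[layer.label] for p, v in lm_cache
                            if p.month == month and p.year in reference
                            and box.contains(p.latitude, p.longitude)
                            and not math.isnan(v[layer.label])]
                if len(ref_vals) < 2:
                    continue
                ref_mean = float(np.mean(ref_vals))
                ref_sd = float(np.std(ref_vals, ddof=1))
                for period in periods:
                    vals = [v[layer.label] for p, v in lm_cache
                            if p.month == month and p.year in period
                            and box.contains(p.latitude, p.longitude)
                            and not math.isnan(v[layer.label])]
                    n = len(vals)
                    n_gt_mean = int(sum(v > ref_mean for v in vals))
                    n_gt_sd = int(sum(v > ref_mean + ref_sd for v in vals))
                    rows.append({
                        "box": box.name, "layer": layer.label,
                        "month": month, "period": period.label,
                        "n": n,
                        "n_gt_mean": n_gt_mean,
                        "n_gt_mean_plus_sd": n_gt_sd,
                        "p_gt_mean": n_gt_mean / n if n else np.nan,
                        "p_gt_mean_plus_sd": n_gt_sd / n if n else np.nan,
                        "ref_mean": ref_mean, "ref_sd": ref_sd,
                    })
    return pd.DataFrame(rows, columns=[
        "box", "layer", "month", "period", "n", "n_gt_mean",
        "n_gt_mean_plus_sd", "p_gt_mean", "p_gt_mean_plus_sd",
        "ref_mean", "ref_sd"])
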