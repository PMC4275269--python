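"""Synthetic profile sets, trend fields and mortality catalogs.

The generator emulates the statistical structure the analysis assumes, so
every stage is exercisable end to end without any archive download:

* a seasonally stratified water column — a warm mixed layer over a tanh
  thermocline relaxing to a constant deep temperature;
* a spatially varying linear trend field β (°C/yr) confined to the warm
  upper layer (the deep water does not trend);
* instrument-style Gaussian level noise, an instrument mix with different
  level spacings, and spatio-temporally inhomogeneous Poisson sampling that
  peaks mid-record;
* optional QC defects injected at configured per-rule rates, recorded in a
  truth sidecar;
* mortality events placed over cells with probability ∝ exp(γ·β), so γ = 0
  is the uniform null and larger γ couples events to warming.

The deterministic column model is

    T(cell, year, month, z) = T_deep
        + (ΔT_month + β_cell · (year − year₀)) · (1 − tanh((z − z_th)/w)) / 2

with year₀ the first year of the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import MortalityEvent
from .profiles import ProfileSet, TemperatureProfile
from .trends import GridSpec

__all__ = [
    "TrendField", "ProfileShape", "SyntheticConfig",
    "true_temperature", "sample_profiles", "generate_events",
]


@dataclass(frozen=True)
class TrendField:
    """Per-cell linear trend β (°C/yr) on a regular grid."""

    grid: GridSpec
    betas: dict[tuple[int, int], float]

    @property
    def cells(self) -> list[tuple[int, int]]:
        return sorted(self.betas)

    def beta(self, cell: tuple[int, int]) -> float:
        return self.betas[cell]

    @staticmethod
    def _domain_cells(domain: tuple[float, float, float, float],
                      grid: GridSpec) -> list[tuple[int, int]]:
        lat0, lat1, lon0, lon1 = domain
        s = grid.cell_size
        ii = range(math.floor(lon0 / s), math.ceil(lon1 / s))
        jj = range(math.floor(lat0 / s), math.ceil(lat1 / s))
        return [(i, j) for i in ii for j in jj]

    @classmethod
    def constant(cls, domain, value: float,
                 grid: GridSpec | None = None) -> "TrendField":
        grid = grid or GridSpec()
        return cls(grid, {c: value for c in cls._domain_cells(domain, grid)})

    @classmethod
    def two_region(cls, domain, beta_west: float, beta_east: float,
                   split_lon: float, grid: GridSpec | None = None) -> "TrendField":
        """Warming/cooling split at a longitude (cell-centre test)."""
        grid = grid or GridSpec()
        betas = {}
        for c in cls._domain_cells(domain, grid):
            lon_lo, lon_hi, _, _ = grid.bounds(c)
            centre = 0.5 * (lon_lo + lon_hi)
            betas[c] = beta_west if centre < split_lon else beta_east
        return cls(grid, betas)

    @classmethod
    def gradient(cls, domain, beta_min: float, beta_max: float,
                 grid: GridSpec | None = None) -> "TrendField":
        """β linear in longitude across the domain (uniformly distributed
        cell betas when cells are equally spaced in longitude)."""
        grid = grid or GridSpec()
        lat0, lat1, lon0, lon1 = domain
        betas = {}
        for c in cls._domain_cells(domain, grid):
            lon_lo, lon_hi, _, _ = grid.bounds(c)
            centre = 0.5 * (lon_lo + lon_hi)
            f = (centre - lon0) / max(lon1 - lon0, 1e-12)
            betas[c] = beta_min + f * (beta_max - beta_min)
        return cls(grid, betas)


@dataclass(frozen=True)
class ProfileShape:
    """Stratified-column parameters.

    T_deep: deep-water temperature, °C (Mediterranean intermediate water
    sits near 13.5 °C year-round).  surface_excess: ΔT of the mixed layer
    over T_deep per month, °C.  z_th / width: thermocline centre and width
    in metres.
    """

    T_deep: float = 13.5
    surface_excess: dict[int, float] = field(default_factory=lambda: {
        7: 10.5, 8: 12.5, 9: 11.0, 10: 7.5, 11: 4.5})
    z_th: float = 20.0
    width: float = 10.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("thermocline width must be positive")


#: Instrument sampling styles: (probability, level spacing m, max depth m).
DEFAULT_INSTRUMENT_MIX = {
    "bottle": (0.15, 10.0, 100.0),
    "MBT": (0.30, 5.0, 60.0),
    "XBT": (0.40, 2.0, 80.0),
    "CTD": (0.15, 1.0, 100.0),
}

#: Late-summer-weighted start months for mortality events (Jul–Nov).
EVENT_MONTH_WEIGHTS = {7: 0.10, 8: 0.20, 9: 0.40, 10: 0.20, 11: 0.10}


def _default_field() -> TrendField:
    # paper-scale basin: trends between mild cooling and +0.07 °C/yr warming
    return TrendField.gradient((30.0, 46.0, -6.0, 36.5), -0.05, 0.07)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``profiles_per_cell_year`` is the Poisson mean of casts per cell and
    year pooled over the five stratified-season months; the default 2.0
    reproduces the order of magnitude of the real archive (≈10⁵ casts over
    ≈680 one-degree marine cells and 67 years).  ``noise_sd`` lumps
    instrument error and submesoscale variability at a given depth.
    ``defect_rates`` are mutually exclusive per-profile probabilities of
    injecting one defect of each QC rule; the default mix discards ≈15% of
    casts, matching the discard fraction a real-archive QC produces.
    """

    seed: int = 0
    trend_field: TrendField = field(default_factory=_default_field)
    years: tuple[int, int] = (1945, 2011)
    months: tuple[int, ...] = (7, 8, 9, 10, 11)
    shape: ProfileShape = field(default_factory=ProfileShape)
    noise_sd: float = 0.5
    profiles_per_cell_year: float = 2.0
    year_weight: Callable[[int], float] | None = None
    instrument_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENT_MIX))
    defect_rates: dict[str, float] = field(default_factory=dict)
    n_events: int = 33
    gamma: float = 10.0
    event_years: tuple[int, int] = (1983, 2009)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if sum(self.defect_rates.values()) > 1.0:
            raise ValueError("defect rates must sum to <= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


#: Default discard mix used when a caller asks for "realistic" defects.
DEFAULT_DEFECT_RATES = {
    "out_of_region": 0.015,
    "out_of_window": 0.015,
    "bad_month": 0.02,
    "gross_range": 0.025,
    "spike": 0.025,
    "non_monotonic_depth": 0.01,
    "constant_value": 0.01,
    "too_few_levels": 0.005,
    "no_shallow_data": 0.005,
    "duplicate": 0.02,
}


def _mid_record_weight(year: int, years: tuple[int, int]) -> float:
    """Sampling inhomogeneity: densest coverage near 1980 in the default
    record, mimicking the real archives' 1965–1995 peak."""
    y0, y1 = years
    centre = y0 + 0.52 * (y1 - y0)
    return 0.4 + 0.9 * math.exp(-((year - centre) / 15.0) ** 2)


def true_temperature(cell: tuple[int, int], year: int, month: int,
                     depth: float | np.ndarray,
                     config: SyntheticConfig) -> float | np.ndarray:
    """Deterministic noise-free column temperature (°C)."""
    if cell not in config.trend_field.betas:
        raise ValueError(f"cell {cell} outside the configured trend field")
    if not (config.years[0] <= year <= config.years[1]):
        raise ValueError(f"year {year} outside configured record")
    if month not in config.shape.surface_excess:
        raise ValueError(f"no surface excess configured for month {month}")
    sh = config.shape
    beta = config.trend_field.beta(cell)
    amp = sh.surface_excess[month] + beta * (year - config.years[0])
    z = np.asarray(depth, dtype=float)
    t = sh.T_deep + amp * (1.0 - np.tanh((z - sh.z_th) / sh.width)) / 2.0
    return float(t) if np.isscalar(depth) else t


def _make_levels(rng: np.random.Generator, spacing: float,
                 max_depth: float) -> np.ndarray:
    z0 = rng.uniform(0.0, min(3.0, spacing))
    return np.arange(z0, max_depth + 1e-9, spacing)


def _inject_defect(rng: np.random.Generator, rule: str,
                   p: TemperatureProfile) -> TemperatureProfile:
    """Return a modified copy of ``p`` that fails exactly ``rule``."""
    z, t = p.depths.copy(), p.temps.copy()
    if rule == "out_of_region":
        return replace(p, latitude=float(rng.uniform(20.0, 28.0)))
    if rule == "out_of_window":
        return replace(p, year=int(rng.integers(1900, 1940)))
    if rule == "bad_month":
        return replace(p, month=int(rng.integers(1, 7)))
    if rule == "gross_range":
        # whole-profile warm bias: out of range at every level, but no
        # spike (level-to-level differences are preserved)
        t = t + float(rng.uniform(25.0, 32.0))
        return replace(p, depths=z, temps=t)
    if rule == "spike":
        i = int(rng.integers(1, max(z.size - 1, 2)))
        idx = np.arange(z.size)
        near = (np.abs(z - z[i]) <= 5.0) & (idx != i)
        if not ((near & (z < z[i])).any() and (near & (z > z[i])).any()):
            # ensure neighbours exist so the spike is detectable
            zi = z[i]
            zn = np.sort(np.concatenate([z, [zi + 2.0, zi - 2.0]]))
            tn = np.interp(zn, z, t)
            z, t = zn, tn
            i = int(np.searchsorted(z, zi))
        t[i] += float(rng.choice([-1.0, 1.0])) * float(rng.uniform(5.0, 7.0))
        t[i] = min(t[i], 34.5)  # stay inside the gross range
        return replace(p, depths=z, temps=t)
    if rule == "non_monotonic_depth":
        if z.size >= 2:
            # collapse the deepest pair: repeated depth, no thermal signal
            z[-1] = z[-2]
            t[-1] = t[-2]
        return replace(p, depths=z, temps=t)
    if rule == "constant_value":
        t[:] = float(t.mean())
        return replace(p, depths=z, temps=t)
    if rule == "too_few_levels":
        return replace(p, depths=z[:1], temps=t[:1])
    if rule == "no_shallow_data":
        keep = z > 12.0
        if keep.sum() >= 2:
            return replace(p, depths=z[keep], temps=t[keep])
        return replace(p, depths=z + 13.0, temps=t)
    raise ValueError(f"unknown defect rule {rule!r}")


def sample_profiles(config: SyntheticConfig
                    ) -> tuple[ProfileSet, pd.DataFrame]:
    """Draw a profile set from the configured column model.

    Returns the set plus a truth sidecar with one row per profile
    (``profile_id, cell_i, cell_j, beta, defect``; defect is "" for clean
    profiles and the rule name for injected ones — the injected duplicate
    copy carries "duplicate").  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    yw = config.year_weight or (lambda y: _mid_record_weight(y, config.years))
    instruments = list(config.instrument_mix)
    probs = np.array([config.instrument_mix[k][0] for k in instruments])
    probs = probs / probs.sum()
    rules = list(config.defect_rates)
    rates = np.array([config.defect_rates[r] for r in rules], dtype=float)

    profiles: list[TemperatureProfile] = []
    truth_rows = []
    counter = 0
    y0, y1 = config.years
    n_months = len(config.months)
    for cell in config.trend_field.cells:
        lon_lo, lon_hi, lat_lo, lat_hi = config.trend_field.grid.bounds(cell)
        beta = config.trend_field.beta(cell)
        for year in range(y0, y1 + 1):
            lam = config.profiles_per_cell_year * yw(year) / n_months
            for month in config.months:
                for _ in range(rng.poisson(lam)):
                    instr = instruments[int(rng.choice(len(instruments), p=probs))]
                    _, spacing, max_depth = config.instrument_mix[instr]
                    z = _make_levels(rng, spacing, max_depth)
                    t = true_temperature(cell, year, month, z, config)
                    if config.noise_sd > 0:
                        t = t + rng.normal(0.0, config.noise_sd, size=z.size)
                    counter += 1
                    p = TemperatureProfile(
                        profile_id=f"p{counter:06d}",
                        latitude=float(rng.uniform(lat_lo, lat_hi)),
                        longitude=float(rng.uniform(lon_lo, lon_hi)),
                        year=year, month=month,
                        day=int(rng.integers(1, 29)),
                        instrument=instr,
                        depths=z, temps=np.asarray(t, dtype=float),
                    )
                    defect = ""
                    if rules:
                        u = rng.uniform()
                        cum = np.cumsum(rates)
                        k = int(np.searchsorted(cum, u))
                        if k < len(rules):
                            defect = rules[k]
                            if defect == "duplicate":
                                # keep the original, add a near-identical copy
                                profiles.append(p)
                                truth_rows.append(_truth_row(p, cell, beta, ""))
                                counter += 1
                                p = replace(
                                    p,
                                    profile_id=f"p{counter:06d}",
                                    depths=p.depths[:-1] if p.n_levels > 2
                                    else p.depths,
                                    temps=p.temps[:-1] if p.n_levels > 2
                                    else p.temps,
                                )
                            else:
                                p = _inject_defect(rng, defect, p)
                    profiles.append(p)
                    truth_rows.append(_truth_row(p, cell, beta, defect))
    sidecar = pd.DataFrame(
        truth_rows,
        columns=["profile_id", "cell_i", "cell_j", "beta", "defect"])
    return ProfileSet(profiles, provenance="synthetic"), sidecar


def _truth_row(p: TemperatureProfile, cell, beta, defect):
    return {"profile_id": p.profile_id, "cell_i": cell[0], "cell_j": cell[1],
            "beta": beta, "defect": defect}


def generate_events(config: SyntheticConfig,
                    trend_field: TrendField | None = None,
                    ) -> tuple[list[MortalityEvent], pd.DataFrame]:
    """Place mortality events over cells with probability ∝ exp(γ·β).

    γ = 0 gives the uniform null over cells; larger γ concentrates events
    in warming cells.  Start months are drawn from the late-summer-weighted
    Jul–Nov distribution.  The truth sidecar records each event's
    generating cell and β.
    """
    tf = trend_field or config.trend_field
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7919]))
    cells = tf.cells
    betas = np.array([tf.beta(c) for c in cells])
    logw = config.gamma * betas
    w = np.exp(logw - logw.max())
    w /= w.sum()
    months = list(EVENT_MONTH_WEIGHTS)
    mprobs = np.array([EVENT_MONTH_WEIGHTS[m] for m in months])
    mprobs /= mprobs.sum()
    species_pool = _species_pool()
    group_probs = {"cnidarians": 0.45, "sponges": 0.30, "bryozoans": 0.10,
                   "ascidians": 0.05, "bivalves": 0.05, "other": 0.05}

    events: list[MortalityEvent] = []
    rows = []
    for k in range(config.n_events):
        ci = int(rng.choice(len(cells), p=w))
        cell = cells[ci]
        lon_lo, lon_hi, lat_lo, lat_hi = tf.grid.bounds(cell)
        year = int(rng.integers(config.event_years[0],
                                config.event_years[1] + 1))
        month = months[int(rng.choice(len(months), p=mprobs))]
        dmin = float(rng.choice([0.0, 0.0, 5.0, 10.0]))
        dmax = float(rng.choice([20.0, 30.0, 40.0, 50.0]))
        n_taxa = int(rng.integers(1, 4))
        taxa = []
        for _ in range(n_taxa):
            g = list(group_probs)[int(rng.choice(
                len(group_probs), p=np.array(list(group_probs.values()))))]
            taxa.append((species_pool[g][int(rng.integers(
                0, len(species_pool[g])))], g))
        eid = f"ev{k + 1:03d}"
        events.append(MortalityEvent(
            event_id=eid, group_id=eid,
            latitude=float(rng.uniform(lat_lo, lat_hi)),
            longitude=float(rng.uniform(lon_lo, lon_hi)),
            year=year, month=month,
            depth_min_m=dmin, depth_max_m=max(dmin, dmax),
            taxa=sorted(set(taxa)),
            metric="% affected colonies",
            intensity=str(rng.choice(["low", "medium", "high"])),
            co_threats=None,
            sources=[f"synth{int(rng.integers(1, 36)):02d}"],
        ))
        rows.append({"event_id": eid, "cell_i": cell[0], "cell_j": cell[1],
                     "beta": float(betas[ci])})
    sidecar = pd.DataFrame(rows, columns=["event_id", "cell_i", "cell_j",
                                          "beta"])
    return events, sidecar


def _species_pool() -> dict[str, list[str]]:
    return {
        "cnidarians": ["Paramuricea clavata", "Eunicella singularis",
                       "Eunicella cavolinii", "Cladocora caespitosa",
                       "Corallium rubrum"],
        "sponges": ["Spongia officinalis", "Ircinia variabilis",
                    "Petrosia ficiformis", "Cacospongia scalaris"],
        "bryozoans": ["Pentapora fascialis", "Myriapora truncata"],
        "ascidians": ["Halocynthia papillosa"],
        "bivalves": ["Pinna nobilis", "Arca noae"],
        "other": ["Ophidiaster ophidianus"],
    }
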