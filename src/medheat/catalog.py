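"""Mass-mortality event catalog: schema, I/O, validation, summary.

One catalog row is one (event, location) record.  A multi-site event — for
example a mortality outbreak spanning hundreds of kilometres of coastline —
appears as several rows sharing a ``group_id``, because the association
stage matches each location to its own grid cell.  The marker ``n.r.``
("not reported") denotes an absent value and survives a write/read
round-trip.

Catalog file: CSV with header ``event_id, group_id, latitude, longitude,
year, month, depth_min_m, depth_max_m, species, higher_group, metric,
intensity, co_threats, sources``.  ``species``/``higher_group``/``sources``
hold ``;``-separated lists (a single higher group broadcasts over all
species of the row).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HIGHER_GROUPS", "MortalityEvent", "CatalogSummary",
    "read_catalog", "write_catalog", "summarize_catalog",
    "parse_depth_range", "CATALOG_COLUMNS", "example_catalog_path",
]


def example_catalog_path() -> Path:
    """Path of the bundled synthetic event catalog.

    A synthetic stand-in for a published Mediterranean mass-mortality
    review table (the original supplement is not redistributable): 28
    (event, location) rows covering 19 distinct events, 59 distinct species
    and 35 distinct publication keys, 1983–2009, with the documented
    multi-site outbreaks of 1999 and 2003 spanning several regions.
    """
    return Path(__file__).parent / "data" / "s1_events_synthetic.csv"

HIGHER_GROUPS = ("sponges", "cnidarians", "bryozoans", "ascidians",
                 "bivalves", "other")

CATALOG_COLUMNS = [
    "event_id", "group_id", "latitude", "longitude", "year", "month",
    "depth_min_m", "depth_max_m", "species", "higher_group", "metric",
    "intensity", "co_threats", "sources",
]

NR = "n.r."


class CatalogFormatError(ValueError):
    """Catalog file violates the documented header."""


def _is_nr(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or \
        (isinstance(v, str) and v.strip().lower() in {"n.r.", "nr", "n.r", ""})


def parse_depth_range(text) -> tuple[float | None, float | None]:
    """Parse a combined depth-range string like ``"0–40"`` (en dash or
    hyphen), a single number, or ``"n.r."`` → (min, max), None for absent."""
    if _is_nr(text):
        return None, None
    s = str(text).strip()
    parts = re.split(r"\s*[–—-]\s*", s)
    nums = [float(p) for p in parts if p != ""]
    if len(nums) == 1:
        return nums[0], nums[0]
    return min(nums), max(nums)


@dataclass
class MortalityEvent:
    """One catalogued (event, location) record."""

    event_id: str
    latitude: float
    longitude: float
    year: int
    month: int | None = None
    group_id: str | None = None
    depth_min_m: float | None = None
    depth_max_m: float | None = None
    taxa: list[tuple[str, str]] = field(default_factory=list)  # (species, group)
    metric: str | None = None
    intensity: str | float | None = None  # low/medium/high or percent affected
    co_threats: str | None = None
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.depth_min_m is not None and self.depth_max_m is not None
                and self.depth_min_m > self.depth_max_m):
            raise ValueError("depth_min_m must be <= depth_max_m")

    @property
    def species(self) -> list[str]:
        return [s for s, _ in self.taxa]

    @property
    def depth_range(self) -> tuple[float | None, float | None]:
        return (self.depth_min_m, self.depth_max_m)


@dataclass
class CatalogSummary:
    n_publications: int
    n_events: int
    n_species: int
    events_per_year: dict[int, int]
    taxa_histogram: dict[str, int]

    @property
    def first_year(self) -> int | None:
        return min(self.events_per_year) if self.events_per_year else None


def _parse_intensity(v):
    if _is_nr(v):
        return None
    s = str(v).strip()
    if s.lower() in {"low", "medium", "high"}:
        return s.lower()
    m = re.match(r"([0-9.]+)\s*%?$", s)
    if m:
        return float(m.group(1))
    return s


def read_catalog(path: str | Path) -> tuple[list[MortalityEvent], pd.DataFrame]:
    """Read the catalog CSV.

    Returns (events, rejects).  Rows with unparseable coordinates or year go
    to the rejects frame with a reason; ``n.r.`` anywhere parses as absent;
    percent intensities parse numerically.
    """
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"missing required column(s): {', '.join(missing)}")
    events: list[MortalityEvent] = []
    rejects = []
    for idx, row in df.iterrows():
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
            year = int(float(row["year"]))
        except ValueError:
            rejects.append({"row": idx + 2,
                            "reason": "unparseable coordinates or year"})
            continue
        month = None if _is_nr(row["month"]) else int(float(row["month"]))
        dmin, _x = parse_depth_range(row["depth_min_m"])
        _y, dmax = parse_depth_range(row["depth_max_m"])
        if dmin is not None and dmax is None and _x != dmin:
            dmax = _x  # combined "lo–hi" form in a single column
        species = [] if _is_nr(row["species"]) \
            else [s.strip() for s in str(row["species"]).split(";") if s.strip()]
        groups = [] if _is_nr(row["higher_group"]) \
            else [g.strip() for g in str(row["higher_group"]).split(";") if g.strip()]
        if len(groups) == 1 and len(species) > 1:
            groups = groups * len(species)
        taxa = [(s, g if g in HIGHER_GROUPS else "other")
                for s, g in zip(species, groups)]
        sources = [] if _is_nr(row["sources"]) \
            else [s.strip() for s in str(row["sources"]).split(";") if s.strip()]
        events.append(MortalityEvent(
            event_id=str(row["event_id"]),
            group_id=None if _is_nr(row["group_id"]) else str(row["group_id"]),
            latitude=lat, longitude=lon, year=year, month=month,
            depth_min_m=dmin, depth_max_m=dmax,
            taxa=taxa,
            metric=None if _is_nr(row["metric"]) else str(row["metric"]),
            intensity=_parse_intensity(row["intensity"]),
            co_threats=None if _is_nr(row["co_threats"]) else str(row["co_threats"]),
            sources=sources,
        ))
    return events, pd.DataFrame(rejects, columns=["row", "reason"])


def write_catalog(events: Sequence[MortalityEvent], path: str | Path) -> None:
    """Write events back to the catalog schema; absent values become n.r."""
    def nr(v):
        return NR if v is None else v

    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id,
            "group_id": nr(e.group_id),
            "latitude": f"{e.latitude:.4f}",
            "longitude": f"{e.longitude:.4f}",
            "year": e.year,
            "month": nr(e.month),
            "depth_min_m": NR if e.depth_min_m is None else f"{e.depth_min_m:g}",
            "depth_max_m": NR if e.depth_max_m is None else f"{e.depth_max_m:g}",
            "species": ";".join(s for s, _ in e.taxa) or NR,
            "higher_group": ";".join(g for _, g in e.taxa) or NR,
            "metric": nr(e.metric),
            "intensity": nr(e.intensity),
            "co_threats": nr(e.co_threats),
            "sources": ";".join(e.sources) or NR,
        })
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, index=False)


def summarize_catalog(events: Sequence[MortalityEvent]) -> CatalogSummary:
    """Distinct-event, species and publication counts plus yearly series."""
    event_ids = {e.event_id for e in events}
    species = {s for e in events for s in e.species}
    pubs = {s for e in events for s in e.sources}
    per_year: dict[int, int] = {}
    seen: set[str] = set()
    for e in sorted(events, key=lambda e: (e.year, e.event_id)):
        if e.event_id in seen:
            continue
        seen.add(e.event_id)
        per_year[e.year] = per_year.get(e.year, 0) + 1
    taxa_hist: dict[str, int] = {}
    for e in events:
        for _, g in e.taxa:
            taxa_hist[g] = taxa_hist.get(g, 0) + 1
    return CatalogSummary(
        n_publications=len(pubs),
        n_events=len(event_ids),
        n_species=len(species),
        events_per_year=dict(sorted(per_year.items())),
        taxa_histogram=taxa_hist,
    )
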