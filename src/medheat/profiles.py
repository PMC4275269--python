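"""Temperature-profile containers and I/O.

A *profile* (or cast) is one vertical series of (depth, temperature)
measurements taken at a station and time with one instrument.  Profiles are
exchanged in two formats:

* **columnar text** — long-format CSV, one row per measured level, header
  ``profile_id, latitude, longitude, year, month, day, instrument, depth_m,
  temperature_c``;
* **gridded binary** — a CF-style netCDF file using the contiguous ragged
  array layout for discrete sampling geometries (one record dimension over
  levels plus a per-profile row-size coordinate).

Native archive dialects (MEDATLAS, WOD, ...) are deliberately not parsed;
converting them to the columnar schema is left as an extension point.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INSTRUMENTS",
    "TemperatureProfile",
    "ProfileSet",
    "read_profiles",
    "write_profiles",
    "COLUMNS",
]

#: Recognised profiling instruments, in roughly increasing accuracy.
INSTRUMENTS = ("bottle", "MBT", "XBT", "CTD", "unknown")

#: Header of the columnar text interchange format.
COLUMNS = [
    "profile_id",
    "latitude",
    "longitude",
    "year",
    "month",
    "day",
    "instrument",
    "depth_m",
    "temperature_c",
]

_REQUIRED = ["profile_id", "latitude", "longitude", "year", "month",
             "depth_m", "temperature_c"]


class ProfileFormatError(ValueError):
    """A profile file violates the declared schema (e.g. missing column)."""


def _normalize_lon(lon: float) -> float:
    """Map a longitude onto [-180, 180)."""
    return ((lon + 180.0) % 360.0) - 180.0


@dataclass
class TemperatureProfile:
    """One station cast: metadata plus sorted (depth, temperature) levels.

    Depths are metres, positive downward; temperatures are in-situ °C.
    ``day`` may be ``None`` — monthly analyses never need it and archive
    records frequently omit it.
    """

    profile_id: str
    latitude: float
    longitude: float
    year: int
    month: int
    day: int | None = None
    instrument: str = "unknown"
    depths: np.ndarray = field(default_factory=lambda: np.empty(0))
    temps: np.ndarray = field(default_factory=lambda: np.empty(0))
    qc_status: str = "unchecked"  # unchecked | passed | failed
    qc_reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.depths.shape != self.temps.shape:
            raise ValueError("depths and temps must have equal length")
        if self.depths.size == 0:
            raise ValueError("profile must have at least one level")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        self.longitude = _normalize_lon(self.longitude)
        if self.instrument not in INSTRUMENTS:
            self.instrument = "unknown"
        order = np.argsort(self.depths, kind="stable")
        self.depths = self.depths[order]
        self.temps = self.temps[order]
        if (self.qc_status == "failed") != bool(self.qc_reasons):
            raise ValueError("qc_reasons must be nonempty iff status is failed")

    @property
    def n_levels(self) -> int:
        return int(self.depths.size)

    def with_qc(self, status: str, reasons: Iterable[str] = ()) -> "TemperatureProfile":
        return replace(self, qc_status=status, qc_reasons=frozenset(reasons))


@dataclass
class ProfileSet:
    """A collection of profiles with unique ids plus a provenance label.

    ``rejects`` carries the row-level reject report produced by
    :func:`read_profiles` (empty frame when nothing was rejected).
    """

    profiles: list[TemperatureProfile]
    provenance: str = ""
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    def __post_init__(self) -> None:
        ids = [p.profile_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ValueError("profile_id values must be unique within a set")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[TemperatureProfile]:
        return iter(self.profiles)

    def __getitem__(self, key: int | str) -> TemperatureProfile:
        if isinstance(key, str):
            for p in self.profiles:
                if p.profile_id == key:
                    return p
            raise KeyError(key)
        return self.profiles[key]

    @property
    def n_levels(self) -> int:
        return sum(p.n_levels for p in self.profiles)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (one row per level) in the interchange schema."""
        parts = []
        for p in self.profiles:
            parts.append(pd.DataFrame({
                "profile_id": p.profile_id,
                "latitude": p.latitude,
                "longitude": p.longitude,
                "year": p.year,
                "month": p.month,
                "day": np.nan if p.day is None else p.day,
                "instrument": p.instrument,
                "depth_m": p.depths,
                "temperature_c": p.temps,
            }))
        if not parts:
            return pd.DataFrame(columns=COLUMNS)
        return pd.concat(parts, ignore_index=True)[COLUMNS]


def _profiles_from_frame(df: pd.DataFrame, provenance: str,
                         rejects: pd.DataFrame) -> ProfileSet:
    profiles = []
    if len(df):
        for pid, grp in df.groupby("profile_id", sort=False):
            first = grp.iloc[0]
            day = first["day"]
            day = None if pd.isna(day) else int(day)
            profiles.append(TemperatureProfile(
                profile_id=str(pid),
                latitude=float(first["latitude"]),
                longitude=float(first["longitude"]),
                year=int(first["year"]),
                month=int(first["month"]),
                day=day,
                instrument=str(first["instrument"]),
                depths=grp["depth_m"].to_numpy(float),
                temps=grp["temperature_c"].to_numpy(float),
            ))
    return ProfileSet(profiles, provenance=provenance, rejects=rejects)


def _read_columnar(path: Path) -> ProfileSet:
    df = pd.read_csv(path, dtype={"profile_id": str, "instrument": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ProfileFormatError(
            f"missing required column(s): {', '.join(missing)}")
    if "day" not in df.columns:
        df["day"] = np.nan
    if "instrument" not in df.columns:
        df["instrument"] = "unknown"

    numeric = ["latitude", "longitude", "year", "month", "day",
               "depth_m", "temperature_c"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    must_parse = ["latitude", "longitude", "year", "month", "depth_m",
                  "temperature_c"]
    # rows where a required numeric failed to parse (or was missing)
    bad = coerced[must_parse].isna().any(axis=1)
    rej_rows = df.index[bad]
    rejects = pd.DataFrame({
        "row": rej_rows + 2,  # 1-based file line, after the header
        "reason": [
            "unparseable or missing value in "
            + ",".join(c for c in must_parse
                       if pd.isna(coerced.at[i, c]))
            for i in rej_rows
        ],
    })
    good = df.loc[~bad].copy()
    good[numeric] = coerced.loc[~bad, numeric]
    return _profiles_from_frame(good, provenance=str(path), rejects=rejects)


def _write_columnar(pset: ProfileSet, path: Path) -> None:
    df = pset.to_frame()
    df["latitude"] = df["latitude"].map(lambda v: f"{v:.3f}")
    df["longitude"] = df["longitude"].map(lambda v: f"{v:.3f}")
    df["temperature_c"] = df["temperature_c"].map(lambda v: f"{v:.3f}")
    df["depth_m"] = df["depth_m"].map(lambda v: f"{v:.1f}")
    df["day"] = df["day"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)


def _read_netcdf(path: Path) -> ProfileSet:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    row_size = ds["row_size"].values.astype(int)
    depths = ds["depth"].values.astype(float)
    temps = ds["temperature"].values.astype(float)
    ids = [str(v) for v in _decode_str(ds["profile_id"].values)]
    instr = [str(v) for v in _decode_str(ds["instrument"].values)]
    lat = ds["latitude"].values
    lon = ds["longitude"].values
    year = ds["year"].values.astype(int)
    month = ds["month"].values.astype(int)
    day = ds["day"].values.astype(int)
    profiles = []
    start = 0
    for k in range(len(row_size)):
        n = row_size[k]
        profiles.append(TemperatureProfile(
            profile_id=ids[k],
            latitude=float(lat[k]),
            longitude=float(lon[k]),
            year=int(year[k]),
            month=int(month[k]),
            day=None if day[k] < 0 else int(day[k]),
            instrument=instr[k],
            depths=depths[start:start + n],
            temps=temps[start:start + n],
        ))
        start += n
    return ProfileSet(profiles, provenance=str(path))


def _decode_str(arr: np.ndarray) -> list[str]:
    out = []
    for v in np.asarray(arr):
        if isinstance(v, bytes):
            out.append(v.decode("utf-8"))
        else:
            out.append(str(v))
    return out


def _write_netcdf(pset: ProfileSet, path: Path) -> None:
    import xarray as xr

    row_size = np.array([p.n_levels for p in pset.profiles], dtype="i4")
    ds = xr.Dataset(
        {
            "latitude": ("profile", np.array([p.latitude for p in pset.profiles])),
            "longitude": ("profile", np.array([p.longitude for p in pset.profiles])),
            "year": ("profile", np.array([p.year for p in pset.profiles], dtype="i4")),
            "month": ("profile", np.array([p.month for p in pset.profiles], dtype="i4")),
            "day": ("profile", np.array(
                [-1 if p.day is None else p.day for p in pset.profiles], dtype="i4")),
            "profile_id": ("profile", np.array(
                [p.profile_id for p in pset.profiles], dtype="S64")),
            "instrument": ("profile", np.array(
                [p.instrument for p in pset.profiles], dtype="S16")),
            "row_size": ("profile", row_size),
            "depth": ("obs", np.concatenate(
                [p.depths for p in pset.profiles]) if pset.profiles else np.empty(0)),
            "temperature": ("obs", np.concatenate(
                [p.temps for p in pset.profiles]) if pset.profiles else np.empty(0)),
        },
        attrs={
            "featureType": "profile",
            "Conventions": "CF-1.8",
            "provenance": pset.provenance,
        },
    )
    ds["row_size"].attrs["sample_dimension"] = "obs"
    ds["depth"].attrs.update(units="m", positive="down")
    ds["temperature"].attrs.update(units="degree_Celsius")
    ds.to_netcdf(path, engine="scipy")


def read_profiles(path: str | Path,
                  format: str = "columnar_text") -> ProfileSet:
    """Read a profile dataset.

    Malformed rows of the columnar format are collected into the returned
    set's ``rejects`` frame (line number and reason) rather than silently
    dropped; a missing required column raises :class:`ProfileFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "columnar_text":
        return _read_columnar(path)
    if format == "gridded_binary":
        return _read_netcdf(path)
    raise ValueError(f"unknown format {format!r}")


def write_profiles(pset: ProfileSet, path: str | Path,
                   format: str = "columnar_text") -> None:
    """Write a profile dataset, round-trippable by :func:`read_profiles`.

    Declared precision of the text format: 0.001 for temperature and
    coordinates, 0.1 m for depth.  The netCDF variant stores full doubles.
    """
    path = Path(path)
    if format == "columnar_text":
        _write_columnar(pset, path)
    elif format == "gridded_binary":
        _write_netcdf(pset, path)
    else:
        raise ValueError(f"unknown format {format!r}")
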