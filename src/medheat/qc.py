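"""Quality control of temperature profiles.

A standard hydrographic QC battery applied before any analysis: position and
date window, month selection, gross temperature range, spike test, depth
monotonicity, stuck-value detection, minimum sampling of the 0–50 m layer,
and near-duplicate removal.  A profile failing any rule is discarded
wholesale — single-level editing is deliberately not done, which keeps the
contract simple (a profile either enters the analysis or it does not).

Every threshold is exposed in :class:`QCConfig`; the defaults bracket
Mediterranean upper-layer conditions for the stratified season
(July–November, 1945–2011).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .profiles import ProfileSet, TemperatureProfile

__all__ = ["QCConfig", "QCReport", "qc_profile", "apply_qc", "RULES"]

#: Identifiers of all content rules, in evaluation order.  ``duplicate`` is a
#: set-level rule applied only by :func:`apply_qc`.
RULES = (
    "out_of_region",
    "out_of_window",
    "bad_month",
    "gross_range",
    "spike",
    "non_monotonic_depth",
    "constant_value",
    "too_few_levels",
    "no_shallow_data",
    "duplicate",
)


@dataclass
class QCConfig:
    """Thresholds for the QC battery.

    region_bounds : (lat_min, lat_max, lon_min, lon_max) in degrees.
    temp_range : plausible in-situ temperature bounds, °C.
    spike_threshold : max |T − median of neighbours within spike_window_m|.
    duplicate_tolerance : (km, hours) within which two casts of the same
        instrument are considered the same station occupation.
    """

    region_bounds: tuple[float, float, float, float] = (30.0, 46.0, -6.0, 36.5)
    temp_range: tuple[float, float] = (3.0, 35.0)
    spike_threshold: float = 3.0
    spike_window_m: float = 5.0
    min_levels_0_50: int = 2
    shallowest_required: float = 10.0
    duplicate_tolerance: tuple[float, float] = (1.0, 24.0)
    date_window: tuple[int, int] = (1945, 2011)
    months: frozenset[int] = frozenset({7, 8, 9, 10, 11})

    def __post_init__(self) -> None:
        if self.temp_range[0] >= self.temp_range[1]:
            raise ValueError("temp_range.min must be < temp_range.max")
        for v in (self.spike_threshold, self.spike_window_m,
                  self.shallowest_required, *self.duplicate_tolerance):
            if v <= 0:
                raise ValueError("all thresholds must be positive")
        self.months = frozenset(self.months)

    def to_file(self, path: str | Path) -> None:
        """Serialize as flat key: value lines."""
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, (tuple, frozenset, set)):
                v = ",".join(str(x) for x in sorted(v) if True) \
                    if isinstance(v, (frozenset, set)) \
                    else ",".join(str(x) for x in v)
            lines.append(f"{k}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class QCReport:
    """Bookkeeping of one :func:`apply_qc` run.

    ``n_input = n_passed + n_failed`` always holds; the per-rule counts can
    sum to more than ``n_failed`` because one profile may fail several rules.
    """

    n_input: int = 0
    n_passed: int = 0
    n_failed: int = 0
    failures_by_rule: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_input == self.n_passed + self.n_failed
        assert sum(self.failures_by_rule.values()) >= self.n_failed

    def to_table(self):
        import pandas as pd
        return pd.DataFrame(
            sorted(self.failures_by_rule.items()),
            columns=["rule", "count"],
        )

    def log_lines(self) -> list[str]:
        lines = [f"QC: {self.n_input} profiles in, {self.n_passed} passed, "
                 f"{self.n_failed} failed"]
        for rule, n in sorted(self.failures_by_rule.items()):
            lines.append(f"  {rule}: {n}")
        return lines


def qc_profile(profile: TemperatureProfile,
               config: QCConfig | None = None) -> tuple[str, frozenset[str]]:
    """Run all content rules on one profile.

    Returns ``("passed", {})`` or ``("failed", reasons)`` with every fired
    rule listed.  QC never raises on content — structural validity is the
    reader's job.
    """
    config = config or QCConfig()
    reasons: set[str] = set()
    lat0, lat1, lon0, lon1 = config.region_bounds
    if not (lat0 <= profile.latitude <= lat1 and lon0 <= profile.longitude <= lon1):
        reasons.add("out_of_region")
    if not (config.date_window[0] <= profile.year <= config.date_window[1]):
        reasons.add("out_of_window")
    if profile.month not in config.months:
        reasons.add("bad_month")

    z, t = profile.depths, profile.temps
    if np.any(t < config.temp_range[0]) or np.any(t > config.temp_range[1]):
        reasons.add("gross_range")
    if np.any(np.diff(z) <= 0):
        reasons.add("non_monotonic_depth")
    if z.size >= 3 and np.ptp(t) == 0.0:
        reasons.add("constant_value")
    in_band = (z >= 0) & (z <= 50)
    if int(in_band.sum()) < config.min_levels_0_50:
        reasons.add("too_few_levels")
    if z.min() > config.shallowest_required:
        reasons.add("no_shallow_data")
    if _has_spike(z, t, config.spike_window_m, config.spike_threshold):
        reasons.add("spike")

    if reasons:
        return "failed", frozenset(reasons)
    return "passed", frozenset()


def _has_spike(z: np.ndarray, t: np.ndarray, window_m: float,
               threshold: float) -> bool:
    """Interior spike test: |T(z) − median of neighbours within window_m|.

    Only levels with at least one neighbour on *each* side inside the
    window are testable — endpoint deviations reflect real vertical
    gradient, not instrument glitches, and are not flagged.
    """
    n = z.size
    for i in range(n):
        near = (np.abs(z - z[i]) <= window_m)
        near[i] = False
        if (near & (z < z[i])).any() and (near & (z > z[i])).any():
            if abs(t[i] - float(np.median(t[near]))) > threshold:
                return True
    return False


def _km_between(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in km."""
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(min(1.0, math.sqrt(a)))


def _hours_between(p: TemperatureProfile, q: TemperatureProfile) -> float:
    """Coarse time gap in hours; a missing day counts as mid-month noon."""
    def t(x):
        day = 15 if x.day is None else x.day
        return (x.year * 8760.0) + (x.month - 1) * 730.0 + (day - 1) * 24.0
    return abs(t(p) - t(q))


def _dedup_reps(profiles: list[TemperatureProfile],
                config: QCConfig) -> set[str]:
    """Return ids of the duplicates to discard (non-representatives).

    Duplicate group: same instrument, positions within the distance
    tolerance, times within the hour tolerance (transitively).  The kept
    representative has the most levels; ties go to the deepest cast, then to
    the lexicographically smallest id.
    """
    km_tol, h_tol = config.duplicate_tolerance
    n = len(profiles)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # group candidates share instrument and calendar month (cheap pre-key)
    from collections import defaultdict
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, p in enumerate(profiles):
        buckets[(p.instrument, p.year, p.month)].append(i)
    for idxs in buckets.values():
        for a in range(len(idxs)):
            i = idxs[a]
            for b in range(a + 1, len(idxs)):
                j = idxs[b]
                p, q = profiles[i], profiles[j]
                if (_hours_between(p, q) <= h_tol and
                        _km_between(p.latitude, p.longitude,
                                    q.latitude, q.longitude) <= km_tol):
                    parent[find(i)] = find(j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)

    discard: set[str] = set()
    for members in groups.values():
        if len(members) == 1:
            continue
        def rank(i):
            p = profiles[i]
            return (-p.n_levels, -float(p.depths.max()), p.profile_id)
        keep = min(members, key=rank)
        discard.update(profiles[i].profile_id for i in members if i != keep)
    return discard


def apply_qc(pset: ProfileSet,
             config: QCConfig | None = None) -> tuple[ProfileSet, QCReport]:
    """Run content rules plus duplicate removal over a whole set.

    Returns the passed subset (statuses stamped) and a :class:`QCReport`.
    Idempotent: re-applying to its own output removes nothing further.
    """
    config = config or QCConfig()
    report = QCReport(n_input=len(pset))
    statuses: list[tuple[TemperatureProfile, frozenset[str]]] = []
    for p in pset:
        _, reasons = qc_profile(p, config)
        statuses.append((p, reasons))

    survivors = [p for p, r in statuses if not r]
    dup_ids = _dedup_reps(survivors, config)

    passed: list[TemperatureProfile] = []
    for p, reasons in statuses:
        if not reasons and p.profile_id in dup_ids:
            reasons = frozenset({"duplicate"})
        if reasons:
            report.n_failed += 1
            for rule in reasons:
                report.failures_by_rule[rule] = \
                    report.failures_by_rule.get(rule, 0) + 1
        else:
            passed.append(p.with_qc("passed"))
    report.n_passed = len(passed)
    report.validate()
    return ProfileSet(passed, provenance=pset.provenance), report
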