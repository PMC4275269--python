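"""Event-to-trend association: sign ratios, binned distribution, KS test.

Each mortality occurrence is matched to the trend cell containing its
coordinates.  The association is then quantified three ways:

1. **sign counts** — occurrences in negative- vs positive-trend cells,
   reported as a 1:k ratio and compared with the corresponding ratio of
   available cell areas;
2. **binned distribution** — occurrence counts over five equal-width trend
   intervals spanning the significant map's slope range;
3. **Kolmogorov–Smirnov** — one-sample KS of the occurrences' cell slopes
   against a uniform distribution over that range (primary), with a
   two-sample KS of event slopes vs all cell slopes reported alongside.

By default only cells whose trend is significant at the 90% level
participate; ``restrict_to_significant=False`` reruns everything over all
assessed cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .catalog import MortalityEvent
from .interp import BAND_0_50, LAYERS, DepthLayer
from .trends import GridSpec, TrendCellResult

__all__ = [
    "EventTrendAssignment", "SignCounts", "KSResult", "AssociationResult",
    "match_events", "sign_counts", "bin_distribution", "ks_uniform",
    "associate",
]

log = logging.getLogger(__name__)


@dataclass
class EventTrendAssignment:
    """One (event, cell, layer) match carrying the matched trend.

    ``weight`` down-weights multi-layer matches so an event spanning three
    layers is not triple-counted (weights of one event sum to 1); an
    unweighted mode reproduces plain row counting.
    """

    event_id: str
    cell: tuple[int, int]
    layer: DepthLayer
    slope: float
    p_value: float
    significant: bool
    weight: float = 1.0


@dataclass
class SignCounts:
    n_neg: float
    n_pos: float
    cells_neg: int
    cells_pos: int

    @property
    def event_ratio(self) -> tuple[float, float]:
        """(1, k) with k = larger/smaller; (0, n) when one side is empty."""
        return _one_to_k(self.n_neg, self.n_pos)

    @property
    def area_ratio(self) -> tuple[float, float]:
        return _one_to_k(self.cells_neg, self.cells_pos)


def _one_to_k(a: float, b: float) -> tuple[float, float]:
    lo, hi = min(a, b), max(a, b)
    if lo == 0:
        return (0.0, hi)
    return (1.0, hi / lo)


@dataclass
class KSResult:
    D: float | None
    p: float | None
    n: int
    underpowered: bool = False
    two_sample_D: float | None = None
    two_sample_p: float | None = None


@dataclass
class AssociationResult:
    """Everything the association stage reports, in one block."""

    assignments: list[EventTrendAssignment]
    unmatched: list[tuple[str, str]]  # (event_id, reason)
    sign: SignCounts
    bin_edges: np.ndarray
    histogram: np.ndarray
    ks: KSResult
    restricted_to_significant: bool


def match_events(events: Sequence[MortalityEvent],
                 results: Sequence[TrendCellResult],
                 grid: GridSpec | None = None,
                 layer_policy: str = "band_0_50",
                 ) -> tuple[list[EventTrendAssignment], list[tuple[str, str]]]:
    """Match each occurrence to the trend of the cell containing it.

    ``layer_policy="band_0_50"`` makes one assignment per event against the
    merged 0–50 m trend; ``"per_layer"`` makes one per depth layer
    overlapped by the event's depth range (absent depths span the full
    band), each carrying weight 1/k.  Events whose cell has no trend result
    for the required layer are returned in the unmatched list with reasons.
    """
    if layer_policy not in {"band_0_50", "per_layer"}:
        raise ValueError(f"unknown layer_policy {layer_policy!r}")
    grid = grid or GridSpec()
    by_key: dict[tuple, TrendCellResult] = {
        (r.cell, r.layer.label): r for r in results}
    assignments: list[EventTrendAssignment] = []
    unmatched: list[tuple[str, str]] = []
    for e in events:
        cell = grid.cell_of(e.latitude, e.longitude)
        if layer_policy == "band_0_50":
            wanted: list[DepthLayer] = [BAND_0_50]
        else:
            dmin = 0.0 if e.depth_min_m is None else e.depth_min_m
            dmax = 50.0 if e.depth_max_m is None else e.depth_max_m
            wanted = [ly for ly in LAYERS if ly.overlaps(dmin, dmax)]
            if not wanted:
                unmatched.append((e.event_id, "depth range outside 0-50 m"))
                continue
        hits = [by_key[(cell, ly.label)] for ly in wanted
                if (cell, ly.label) in by_key]
        if not hits:
            unmatched.append((e.event_id, "no trend result at event cell"))
            continue
        w = 1.0 / len(hits)
        for r in hits:
            assignments.append(EventTrendAssignment(
                event_id=e.event_id, cell=cell, layer=r.layer,
                slope=r.slope, p_value=r.p_value,
                significant=r.significant, weight=w))
    return assignments, unmatched


def _select(assignments: Iterable[EventTrendAssignment],
            restrict_to_significant: bool) -> list[EventTrendAssignment]:
    if restrict_to_significant:
        return [a for a in assignments if a.significant]
    return list(assignments)


def sign_counts(assignments: Sequence[EventTrendAssignment],
                results: Sequence[TrendCellResult] = (),
                restrict_to_significant: bool = True,
                weighted: bool = True) -> SignCounts:
    """Occurrence and cell counts by trend sign.

    An exactly zero slope (a measure-zero event in floating point) counts
    as positive and is logged, keeping the partition deterministic.
    """
    sel = _select(assignments, restrict_to_significant)
    n_neg = n_pos = 0.0
    for a in sel:
        w = a.weight if weighted else 1.0
        if a.slope == 0.0:
            log.warning("exactly zero slope in cell %s: counted as positive",
                        a.cell)
        if a.slope < 0:
            n_neg += w
        else:
            n_pos += w
    cells = [r for r in results
             if (r.significant or not restrict_to_significant)]
    cells_neg = sum(1 for r in cells if r.slope < 0)
    cells_pos = sum(1 for r in cells if r.slope >= 0)
    return SignCounts(n_neg=n_neg, n_pos=n_pos,
                      cells_neg=cells_neg, cells_pos=cells_pos)


def _slope_range(results: Sequence[TrendCellResult],
                 restrict_to_significant: bool) -> tuple[float, float]:
    slopes = [r.slope for r in results
              if r.significant or not restrict_to_significant]
    if not slopes:
        raise ValueError("no cells available to define the trend range")
    return min(slopes), max(slopes)


def bin_distribution(assignments: Sequence[EventTrendAssignment],
                     results: Sequence[TrendCellResult],
                     n_bins: int = 5,
                     restrict_to_significant: bool = True,
                     weighted: bool = True,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of occurrences over equal-width trend intervals.

    Edges partition the slope range of the (significant) trend map, not of
    the event slopes; intervals are right-open except the last, which is
    closed so the maximum joins the final bin.  Returns (edges, counts).
    """
    sel = _select(assignments, restrict_to_significant)
    lo, hi = _slope_range(results, restrict_to_significant)
    if lo == hi:
        edges = np.array([lo, hi])
        counts = np.array([sum((a.weight if weighted else 1.0) for a in sel)])
        return edges, counts
    edges = np.linspace(lo, hi, n_bins + 1)
    slopes = np.array([a.slope for a in sel])
    weights = np.array([a.weight if weighted else 1.0 for a in sel])
    counts, _ = np.histogram(slopes, bins=edges, weights=weights)
    return edges, counts


def ks_uniform(assignments: Sequence[EventTrendAssignment],
               results: Sequence[TrendCellResult],
               restrict_to_significant: bool = True,
               min_n: int = 3) -> KSResult:
    """KS test of occurrence slopes against uniformity over the trend range.

    Primary: one-sample KS of the matched cell slopes against the uniform
    distribution on [min, max] of the (significant) map's slopes, with the
    asymptotic Kolmogorov p-value.  Secondary: two-sample KS of event
    slopes vs all participating cell slopes.  Fewer than ``min_n``
    assignments yields an underpowered result with no p-value.
    """
    sel = _select(assignments, restrict_to_significant)
    n = len(sel)
    if n < min_n:
        return KSResult(D=None, p=None, n=n, underpowered=True)
    lo, hi = _slope_range(results, restrict_to_significant)
    slopes = np.array([a.slope for a in sel])
    if hi == lo:
        return KSResult(D=None, p=None, n=n, underpowered=True)
    res = stats.kstest(slopes, stats.uniform(loc=lo, scale=hi - lo).cdf,
                       method="asymp")
    cell_slopes = np.array([r.slope for r in results
                            if r.significant or not restrict_to_significant])
    res2 = stats.ks_2samp(slopes, cell_slopes, method="asymp")
    return KSResult(D=float(res.statistic), p=float(res.pvalue), n=n,
                    two_sample_D=float(res2.statistic),
                    two_sample_p=float(res2.pvalue))


def associate(events: Sequence[MortalityEvent],
              results: Sequence[TrendCellResult],
              grid: GridSpec | None = None,
              layer_policy: str = "band_0_50",
              restrict_to_significant: bool = True,
              n_bins: int = 5,
              weighted: bool = True) -> AssociationResult:
    """Full association stage in one call."""
    assignments, unmatched = match_events(events, results, grid, layer_policy)
    sc = sign_counts(assignments, results, restrict_to_significant, weighted)
    sel = _select(assignments, restrict_to_significant)
    if sel:
        edges, hist = bin_distribution(assignments, results, n_bins,
                                       restrict_to_significant, weighted)
    else:
        edges, hist = np.array([]), np.array([])
    ks = ks_uniform(assignments, results, restrict_to_significant)
    return AssociationResult(
        assignments=assignments, unmatched=unmatched, sign=sc,
        bin_edges=edges, histogram=hist, ks=ks,
        restricted_to_significant=restrict_to_significant)
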