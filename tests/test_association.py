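"""Event-trend matching, sign ratios, binning, and KS statistics."""

import numpy as np
import pytest

from medheat import (GridSpec, MortalityEvent, TrendCellResult, associate,
                     bin_distribution, ks_uniform, match_events, sign_counts)
from medheat.association import EventTrendAssignment
from medheat.interp import BAND_0_50, L0_10, L11_30, L31_50, LAYERS


def cell_result(cell, slope, layer=BAND_0_50, significant=True, p=0.01):
    return TrendCellResult(cell=cell, layer=layer, slope=slope,
                           intercept=15.0, p_value=p, n_years=30,
                           significant=significant)


def event(i, lat, lon, dmin=None, dmax=None):
    return MortalityEvent(event_id=f"e{i}", latitude=lat, longitude=lon,
                          year=1999, month=9, depth_min_m=dmin,
                          depth_max_m=dmax)


def assignment(slope, eid="e", weight=1.0, significant=True):
    return EventTrendAssignment(event_id=eid, cell=(0, 0), layer=BAND_0_50,
                                slope=slope, p_value=0.01,
                                significant=significant, weight=weight)


class TestMatchEvents:
    def test_per_layer_interval_overlap(self):
        results = [cell_result((3, 42), 0.03, ly) for ly in LAYERS]
        a, unmatched = match_events([event(1, 42.5, 3.5, 5, 25)], results,
                                    layer_policy="per_layer")
        assert not unmatched
        assert {x.layer.label for x in a} == {"L0_10", "L11_30"}
        assert all(x.cell == (3, 42) for x in a)
        assert sum(x.weight for x in a) == pytest.approx(1.0)

    def test_absent_depth_band_policy(self):
        results = [cell_result((3, 42), 0.03)]
        a, unmatched = match_events([event(1, 42.5, 3.5)], results,
                                    layer_policy="band_0_50")
        assert len(a) == 1 and a[0].layer.label == "BAND_0_50"

    def test_no_cell_result_reported_unmatched(self):
        results = [cell_result((10, 10), 0.03)]
        a, unmatched = match_events([event(1, 42.5, 3.5)], results)
        assert not a and unmatched == [("e1", "no trend result at event cell")]

    def test_containment_oracle(self):
        """Every assignment's cell contains the event point and its layers
        intersect the event depth range."""
        rng = np.random.default_rng(5)
        grid = GridSpec()
        results = [cell_result((i, j), float(rng.normal(0, 0.03)), ly)
                   for i in range(0, 6) for j in range(40, 44)
                   for ly in LAYERS]
        events = []
        for k in range(200):
            dmin = float(rng.uniform(0, 40))
            events.append(event(k, float(rng.uniform(40, 44)),
                                float(rng.uniform(0, 6)), dmin,
                                dmin + float(rng.uniform(0, 20))))
        a, unmatched = match_events(events, results, layer_policy="per_layer")
        ev = {e.event_id: e for e in events}
        for x in a:
            e = ev[x.event_id]
            lon0, lon1, lat0, lat1 = grid.bounds(x.cell)
            assert lon0 <= e.longitude < lon1 and lat0 <= e.latitude < lat1
            assert x.layer.overlaps(e.depth_min_m, e.depth_max_m)


class TestSignCounts:
    def test_printed_event_ratio(self):
        a = [assignment(-0.01, f"n{i}") for i in range(3)] + \
            [assignment(0.02, f"p{i}") for i in range(30)]
        sc = sign_counts(a)
        assert (sc.n_neg, sc.n_pos) == (3, 30)
        assert sc.event_ratio == (1.0, 10.0)

    def test_printed_area_ratio(self):
        cells = [cell_result((i, 0), -0.01) for i in range(25)] + \
                [cell_result((i, 1), 0.02) for i in range(104)]
        sc = sign_counts([], cells)
        assert (sc.cells_neg, sc.cells_pos) == (25, 104)
        assert sc.area_ratio == (1.0, pytest.approx(104 / 25))

    def test_degenerate_one_sided_ratio(self):
        sc = sign_counts([assignment(0.01, f"p{i}") for i in range(5)])
        assert sc.event_ratio == (0.0, 5.0)

    def test_order_invariance(self):
        a = [assignment(s, f"e{i}") for i, s in
             enumerate([-0.02, 0.01, 0.03, -0.01, 0.02])]
        sc1 = sign_counts(a)
        sc2 = sign_counts(list(reversed(a)))
        assert (sc1.n_neg, sc1.n_pos) == (sc2.n_neg, sc2.n_pos)

    def test_insignificant_assignments_excluded_by_default(self):
        a = [assignment(0.01, "a"), assignment(-0.01, "b", significant=False)]
        sc = sign_counts(a)
        assert (sc.n_neg, sc.n_pos) == (0, 1)
        sc_all = sign_counts(a, restrict_to_significant=False)
        assert (sc_all.n_neg, sc_all.n_pos) == (1, 1)


class TestBinDistribution:
    def test_edges_span_map_not_events(self):
        cells = [cell_result((0, 0), -0.05), cell_result((1, 0), 0.05)]
        a = [assignment(0.01)]
        edges, counts = bin_distribution(a, cells)
        assert edges[0] == -0.05 and edges[-1] == 0.05
        assert counts.sum() == 1

    def test_boundary_rules(self):
        cells = [cell_result((0, 0), 0.0), cell_result((1, 0), 0.05)]
        # bins: [0,0.01) [0.01,0.02) [0.02,0.03) [0.03,0.04) [0.04,0.05]
        a = [assignment(0.01, "edge"), assignment(0.05, "max")]
        edges, counts = bin_distribution(a, cells)
        np.testing.assert_allclose(edges, np.linspace(0, 0.05, 6), atol=1e-15)
        assert counts[1] == 1  # edge-sitter goes to the bin it opens
        assert counts[4] == 1  # the maximum joins the last bin

    def test_degenerate_range_single_bin(self):
        cells = [cell_result((0, 0), 0.02)]
        edges, counts = bin_distribution([assignment(0.02)], cells)
        assert len(counts) == 1 and counts[0] == 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        cells = [cell_result((i, 0), float(rng.uniform(-0.05, 0.07)))
                 for i in range(40)]
        slopes = [float(rng.choice([c.slope for c in cells]))
                  for _ in range(100)]
        a = [assignment(s, f"e{i}") for i, s in enumerate(slopes)]
        edges, counts = bin_distribution(a, cells)
        brute = np.zeros(5)
        for s in slopes:
            for b in range(5):
                lo, hi = edges[b], edges[b + 1]
                if (lo <= s < hi) or (b == 4 and s == hi):
                    brute[b] += 1
        np.testing.assert_allclose(counts, brute)
        assert counts.sum() == len(a)


def brute_force_ks_uniform(x, lo, hi):
    """Sup-norm gap between the empirical CDF and uniform CDF, scanned at
    all jump points from both sides."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    u = (x - lo) / (hi - lo)
    d = 0.0
    for i in range(n):
        d = max(d, abs((i + 1) / n - u[i]), abs(i / n - u[i]))
    return d


class TestKSUniform:
    def test_equi_quantile_closed_form(self):
        """Points at the (i-1/2)/n uniform quantiles give D = 1/(2n)."""
        cells = [cell_result((0, 0), 0.0), cell_result((1, 0), 0.1)]
        for n in (4, 9, 25):
            slopes = (np.arange(n) + 0.5) / n * 0.1
            a = [assignment(float(s), f"e{i}") for i, s in enumerate(slopes)]
            res = ks_uniform(a, cells)
            assert res.D == pytest.approx(1 / (2 * n), abs=1e-12)

    def test_all_events_at_maximum(self):
        cells = [cell_result((0, 0), 0.0), cell_result((1, 0), 0.1)]
        a = [assignment(0.1, f"e{i}") for i in range(20)]
        res = ks_uniform(a, cells)
        assert res.D >= 19 / 20
        assert res.p < 1e-6

    def test_underpowered_below_three(self):
        cells = [cell_result((0, 0), 0.0), cell_result((1, 0), 0.1)]
        res = ks_uniform([assignment(0.05)], cells)
        assert res.underpowered and res.p is None

    def test_matches_brute_force_supremum(self):
        rng = np.random.default_rng(12)
        cells = [cell_result((i, 0), float(rng.uniform(-0.04, 0.08)))
                 for i in range(30)]
        lo = min(c.slope for c in cells)
        hi = max(c.slope for c in cells)
        for _ in range(20):
            slopes = rng.uniform(lo, hi, size=rng.integers(3, 40))
            a = [assignment(float(s), f"e{i}") for i, s in enumerate(slopes)]
            res = ks_uniform(a, cells)
            assert res.D == pytest.approx(
                brute_force_ks_uniform(slopes, lo, hi), abs=1e-12)


class TestAssociateEndToEnd:
    def test_conservation_identity(self):
        rng = np.random.default_rng(3)
        results = [cell_result((i, j), float(rng.normal(0.01, 0.03)))
                   for i in range(5) for j in range(40, 43)]
        events = [event(k, float(rng.uniform(40, 43)), float(rng.uniform(0, 5)))
                  for k in range(25)]
        res = associate(events, results)
        total = sum(a.weight for a in res.assignments if a.significant)
        assert res.sign.n_neg + res.sign.n_pos == pytest.approx(total)
        assert res.histogram.sum() == pytest.approx(total)
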