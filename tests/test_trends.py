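"""Cell assignment, yearly aggregation and OLS trend fitting."""

import numpy as np
import pytest
from scipy import stats

from medheat import (BAND_0_50, CellLayerSeries, GridSpec, ProfileSet,
                     assign_cell, build_yearly_series, fit_trend, trend_map,
                     trend_table)
from medheat.interp import L0_10

from conftest import linear_profile, make_profile


def closed_form_ols(x, y):
    """Textbook normal-equations slope/intercept and slope t-test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    b = sxy / sxx
    a = y.mean() - b * x.mean()
    resid = y - (a + b * x)
    s2 = np.sum(resid ** 2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    if se == 0:
        p = 0.0 if b != 0 else 1.0
    else:
        t = b / se
        p = 2 * stats.t.sf(abs(t), n - 2)
    return b, a, p


class TestAssignCell:
    def test_interior_point(self):
        assert assign_cell(43.5, 9.5) == (9, 43)

    def test_lower_edge_inclusion(self):
        assert assign_cell(43.0, 9.0) == (9, 43)

    def test_negative_coordinates(self):
        assert assign_cell(35.2, -0.3) == (-1, 35)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            assign_cell(float("nan"), 5.0)

    def test_containment_exhaustive(self):
        """Every random point's assigned cell bounds contain it."""
        rng = np.random.default_rng(0)
        grid = GridSpec(1.0)
        lats = rng.uniform(-89, 89, 10_000)
        lons = rng.uniform(-179, 179, 10_000)
        for lat, lon in zip(lats, lons):
            cell = grid.cell_of(lat, lon)
            lon0, lon1, lat0, lat1 = grid.bounds(cell)
            assert lon0 <= lon < lon1 and lat0 <= lat < lat1


class TestYearlySeries:
    def test_mean_of_three_profiles(self):
        profs = [linear_profile(pid=f"p{i}", slope=0.0, t0=t)
                 for i, t in enumerate([14.0, 15.0, 16.0])]
        series = build_yearly_series(ProfileSet(profs), GridSpec(), BAND_0_50)
        (s,) = series.values()
        assert s.values == {1999: pytest.approx(15.0)}
        assert s.n_profiles == {1999: 3}

    def test_cells_do_not_leak(self):
        a = linear_profile(pid="a", lon=6.2)
        b = linear_profile(pid="b", lon=7.2)
        series = build_yearly_series(ProfileSet([a, b]), GridSpec(), BAND_0_50)
        assert len(series) == 2

    def test_off_month_profiles_excluded(self):
        a = linear_profile(pid="a", month=9)
        b = linear_profile(pid="b", month=1)
        series = build_yearly_series(ProfileSet([a, b]), GridSpec(), BAND_0_50)
        (s,) = series.values()
        assert s.n_profiles == {1999: 1}


class TestFitTrend:
    def _series(self, years, values):
        return CellLayerSeries((0, 0), BAND_0_50,
                               values=dict(zip(years, values)),
                               n_profiles={y: 1 for y in years})

    def test_exact_line_recovered(self):
        years = np.arange(1945, 1965)
        s = self._series(years, 15 + 0.05 * (years - 1945))
        r = fit_trend(s, min_years=10)
        assert r.slope == pytest.approx(0.05, abs=1e-12)
        assert r.p_value < 1e-10 and r.significant

    def test_constant_series_not_significant(self):
        years = np.arange(1945, 1965)
        r = fit_trend(self._series(years, np.full(20, 15.0)), min_years=10)
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert not r.significant

    def test_below_min_years_absent(self):
        years = np.arange(2000, 2005)
        assert fit_trend(self._series(years, years * 0.01), min_years=10) is None

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(10, 31)
            years = np.sort(rng.choice(np.arange(1945, 2012), n, replace=False))
            vals = 15 + 0.02 * (years - 1945) + rng.normal(0, 0.5, n)
            r = fit_trend(self._series(years, vals), min_years=10)
            b, a, p = closed_form_ols(years, vals)
            assert r.slope == pytest.approx(b, abs=1e-9)
            assert r.intercept == pytest.approx(a, abs=1e-9)
            assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_shift_invariance_of_slope(self):
        rng = np.random.default_rng(3)
        years = np.arange(1950, 1980)
        vals = 14 + 0.03 * (years - 1950) + rng.normal(0, 0.3, 30)
        r1 = fit_trend(self._series(years, vals), min_years=10)
        r2 = fit_trend(self._series(years, vals + 5.0), min_years=10)
        r3 = fit_trend(self._series(years + 7, vals), min_years=10)
        assert r2.slope == pytest.approx(r1.slope, abs=1e-12)
        assert r3.slope == pytest.approx(r1.slope, abs=1e-12)
        assert r2.intercept == pytest.approx(r1.intercept + 5.0, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


class TestTrendMap:
    def test_empty_set_empty_map(self):
        assert trend_map(ProfileSet([])) == []

    def test_one_dense_cell_yields_all_layers(self):
        profs = [linear_profile(pid=f"p{y}", year=y, slope=-0.1,
                                t0=20 + 0.05 * (y - 1945))
                 for y in range(1945, 1980)]
        res = trend_map(ProfileSet(profs))
        assert len(res) == 4  # three layers + merged band
        for r in res:
            assert r.slope == pytest.approx(0.05, abs=1e-9)
            assert r.significant

    def test_table_export_shape(self):
        profs = [linear_profile(pid=f"p{y}", year=y)
                 for y in range(1945, 1970)]
        res = trend_map(ProfileSet(profs))
        tab = trend_table(res)
        assert set(tab.columns) >= {"cell_lon_edge", "cell_lat_edge", "layer",
                                    "slope", "p_value", "n_years",
                                    "significant"}
        assert len(tab) == len(res)
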