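"""Two-period climatologies, event anomalies and warm-extreme counts."""

import numpy as np
import pytest

from medheat import (FULL_1945_2011, P1945_1982, P1983_2011, ProfileSet,
                     RegionBox, event_anomaly, extreme_frequency,
                     monthly_climatology)
from medheat.interp import BAND_0_50, L0_10

from conftest import linear_profile, make_profile

BOX = RegionBox("test", 39.0, 41.0, 5.0, 7.0)


def profiles_constant(temps_by_id, year=1999, month=9, **kw):
    return [linear_profile(pid=k, slope=0.0, t0=v, year=year, month=month,
                           **kw) for k, v in temps_by_id.items()]


class TestClimatology:
    def test_identical_profiles_zero_sd(self):
        ps = ProfileSet(profiles_constant({"a": 20.0, "b": 20.0, "c": 20.0}))
        c = monthly_climatology(ps, BOX, 9, P1983_2011)
        np.testing.assert_allclose(c.mean_t, 20.0)
        np.testing.assert_allclose(c.sd_t, 0.0, atol=1e-12)
        assert (c.n == 3).all()

    def test_two_profile_sample_sd(self):
        # sample SD of {18, 22} is |22-18|/sqrt(2) = 2.828...
        ps = ProfileSet(profiles_constant({"a": 18.0, "b": 22.0}))
        c = monthly_climatology(ps, BOX, 9, P1983_2011, n_min=2)
        np.testing.assert_allclose(c.mean_t, 20.0)
        np.testing.assert_allclose(c.sd_t, 4.0 / np.sqrt(2), rtol=1e-12)

    def test_n_min_masks_sparse_depths(self):
        ps = ProfileSet(profiles_constant({"a": 20.0, "b": 21.0}))
        c = monthly_climatology(ps, BOX, 9, P1983_2011, n_min=3)
        assert np.isnan(c.mean_t).all() and c.empty

    def test_out_of_box_and_period_excluded(self):
        inside = profiles_constant({"a": 20.0, "b": 20.0, "c": 20.0})
        outside = profiles_constant({"x": 30.0}, lat=45.0)
        early = profiles_constant({"y": 10.0}, year=1950)
        c = monthly_climatology(ProfileSet(inside + outside + early),
                                BOX, 9, P1983_2011)
        np.testing.assert_allclose(c.mean_t, 20.0)

    def test_pooling_periods_reproduces_full_mean(self):
        """Weighted P1/P2 means reproduce the FULL-period mean exactly."""
        rng = np.random.default_rng(11)
        profs = [linear_profile(pid=f"p{i}", slope=0.0,
                                t0=float(rng.uniform(15, 25)),
                                year=int(rng.integers(1945, 2012)))
                 for i in range(40)]
        ps = ProfileSet(profs)
        c1 = monthly_climatology(ps, BOX, 9, P1945_1982, n_min=1)
        c2 = monthly_climatology(ps, BOX, 9, P1983_2011, n_min=1)
        cf = monthly_climatology(ps, BOX, 9, FULL_1945_2011, n_min=1)
        n1, n2 = c1.n[0], c2.n[0]
        pooled = (n1 * c1.mean_t[0] + n2 * c2.mean_t[0]) / (n1 + n2)
        assert pooled == pytest.approx(cf.mean_t[0], abs=1e-9)


class TestEventAnomaly:
    def test_event_equal_to_climatology_gives_zero(self):
        base = profiles_constant({f"a{i}": 20.0 for i in range(3)}, year=1990)
        event = profiles_constant({"e1": 20.0}, year=1999)
        ps = ProfileSet(base + event)
        a = event_anomaly(ps, BOX, 1999, 9, reference_periods=(P1983_2011,))
        np.testing.assert_allclose(a.delta_t["P1983_2011"], 0.0, atol=1e-12)
        assert a.max_anomaly["P1983_2011"] is None

    def test_constant_shift_and_shallow_tie_break(self):
        # reference climatology from the earlier period only, so the event
        # month itself does not dilute it
        base = profiles_constant({f"a{i}": 20.0 for i in range(3)}, year=1950)
        event = profiles_constant({"e1": 24.6}, year=1999)
        ps = ProfileSet(base + event)
        a = event_anomaly(ps, BOX, 1999, 9, reference_periods=(P1945_1982,))
        val, depth = a.max_anomaly["P1945_1982"]
        assert val == pytest.approx(4.6)
        assert depth == 0  # first occurrence from the surface on ties

    def test_no_data_is_explicit(self):
        base = profiles_constant({f"a{i}": 20.0 for i in range(3)}, year=1990)
        a = event_anomaly(ProfileSet(base), BOX, 2005, 9)
        assert a.no_data and not a.delta_t


class TestExtremeFrequency:
    def test_all_equal_no_exceedances(self):
        profs = []
        for year in (1950, 1960, 1990, 2000):
            profs += profiles_constant({f"p{year}": 20.0}, year=year)
        tab = extreme_frequency(ProfileSet(profs), [BOX], layers=[L0_10],
                                months=[9])
        assert (tab.n_gt_mean == 0).all()
        assert (tab.n_gt_mean_plus_sd == 0).all()

    def test_hand_computed_four_values(self):
        """P1 {14,15}, P2 {16,17}: full mean 15.5, sample SD ~1.29;
        P2 exceeds the mean twice and mean+SD (16.79) once."""
        profs = (profiles_constant({"a": 14.0}, year=1950)
                 + profiles_constant({"b": 15.0}, year=1960)
                 + profiles_constant({"c": 16.0}, year=1990)
                 + profiles_constant({"d": 17.0}, year=2000))
        tab = extreme_frequency(ProfileSet(profs), [BOX], layers=[L0_10],
                                months=[9])
        p1 = tab[tab.period == "P1945_1982"].iloc[0]
        p2 = tab[tab.period == "P1983_2011"].iloc[0]
        assert p1.ref_mean == pytest.approx(15.5)
        assert p1.ref_sd == pytest.approx(np.std([14, 15, 16, 17], ddof=1))
        assert (p2.n_gt_mean, p2.n_gt_mean_plus_sd) == (2, 1)
        assert (p1.n_gt_mean, p1.n_gt_mean_plus_sd) == (0, 0)

    def test_count_ordering_invariant(self):
        rng = np.random.default_rng(2)
        profs = [linear_profile(pid=f"p{i}", slope=0.0,
                                t0=float(rng.uniform(14, 26)),
                                year=int(rng.integers(1945, 2012)))
                 for i in range(60)]
        tab = extreme_frequency(ProfileSet(profs), [BOX], months=[9])
        assert (tab.n_gt_mean_plus_sd <= tab.n_gt_mean).all()
        assert (tab.n_gt_mean <= tab.n).all()

    def test_sd_envelope_coverage_gaussian(self):
        """With Gaussian spread, ~68% of casts fall inside mean +/- SD."""
        rng = np.random.default_rng(9)
        profs = [linear_profile(pid=f"p{i}", slope=0.0,
                                t0=20.0 + float(rng.normal(0, 1.5)),
                                year=int(rng.integers(1983, 2012)))
                 for i in range(1000)]
        ps = ProfileSet(profs)
        c = monthly_climatology(ps, BOX, 9, P1983_2011)
        vals = np.array([p.temps[0] for p in ps])
        inside = np.mean(np.abs(vals - c.mean_t[0]) <= c.sd_t[0])
        assert 0.63 <= inside <= 0.73
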