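import numpy as np
import pytest

from medheat import ProfileSet, TemperatureProfile


def make_profile(pid="p1", lat=40.0, lon=6.0, year=1999, month=9, day=15,
                 instrument="CTD", depths=(0, 10, 30), temps=(24.0, 22.0, 16.0)):
    return TemperatureProfile(
        profile_id=pid, latitude=lat, longitude=lon, year=year, month=month,
        day=day, instrument=instrument,
        depths=np.asarray(depths, float), temps=np.asarray(temps, float))


def linear_profile(pid="lin", slope=-0.2, t0=25.0, depths=None, **kw):
    """T(z) = t0 + slope*z at the given depths (default every metre 0..50)."""
    z = np.arange(51.0) if depths is None else np.asarray(depths, float)
    return make_profile(pid=pid, depths=z, temps=t0 + slope * z, **kw)


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture
def small_set():
    return ProfileSet([
        make_profile("a", depths=(0, 5, 10, 20, 40), temps=(25, 24, 22, 18, 15)),
        make_profile("b", lat=40.5, lon=6.5, year=1980,
                     depths=(2, 12, 30), temps=(24.0, 21.0, 16.0)),
    ], provenance="unit")
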