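import datetime as dt

import pytest

from fieldsync import EavStore
from fieldsync import fixtures as fx
from fieldsync import protocols as fp

TZ = fx.TZ


@pytest.fixture
def store():
    return EavStore(device_tag="T1")


@pytest.fixture
def small_pop():
    """Two packs of 12-18, fixed seed; rebuilt per test (stores mutate)."""
    spec = fx.PopulationSpec(n_packs=2, pack_size_range=(12, 18), seed=7)
    return fx.simulate_population(spec), spec


@pytest.fixture
def visit_setup(store):
    """One active pack with a hand-built roster and an open visit."""
    pack = fp.add_pack(store, "1H")
    adults = {}
    for name, sex, born in [
        ("AF1", "F", dt.date(2012, 1, 1)),
        ("AF2", "F", dt.date(2013, 6, 1)),
        ("AM1", "M", dt.date(2011, 5, 1)),
        ("AM2", "M", dt.date(2012, 9, 1)),
        ("YF1", "F", dt.date(2014, 8, 1)),   # ~7 months at visit
        ("PUP1", None, None),
    ]:
        if name == "PUP1":
            sex, born = "M", dt.date(2015, 1, 15)  # ~45 days old
        adults[name] = fp.add_individual(store, pack.id, name, sex, born,
                                         today=dt.date(2015, 3, 2))
    start = dt.datetime(2015, 3, 2, 8, 0, tzinfo=TZ)
    session = fp.start_visit(store, pack.id, start,
                             gps_source=lambda t: (-0.19, 29.90))
    return store, pack, adults, session, start
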