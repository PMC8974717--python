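import numpy as np
import pytest

from pollenwave import load_table2_fixture
from pollenwave.aero_io import DailyPollenSeries


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_series(doys, concs, station="TST", taxon="Betula", year=2010, first_op=None):
    doys = list(doys)
    return DailyPollenSeries(
        station_id=station,
        taxon=taxon,
        year=year,
        first_operation_doy=doys[0] if first_op is None else first_op,
        values=tuple(zip(doys, [float(c) for c in concs])),
    )


@pytest.fixture
def series_factory():
    return make_series
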