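import numpy as np
import pytest

import droughtwheat as dw
from droughtwheat.scenarios import (REFERENCE_CULTIVAR, synthetic_dry_site,
                                    synthetic_wet_site)


@pytest.fixture(scope="session")
def soil():
    return dw.default_soil()


@pytest.fixture(scope="session")
def consts():
    return dw.ModelConstants()


@pytest.fixture(scope="session")
def sl_site():
    return dw.load_site("SL")


@pytest.fixture(scope="session")
def wet_site():
    return synthetic_wet_site()


@pytest.fixture(scope="session")
def dry_site():
    return synthetic_dry_site()


@pytest.fixture(scope="session")
def reference_cultivar():
    return REFERENCE_CULTIVAR


def make_constant_series(site_id="TST", n_years=1, tmin=10.0, tmax=20.0,
                         srad=15.0, precip=1.0):
    """A hand-built constant weather series for arithmetic checks."""
    n = 365 * n_years
    return dw.WeatherSeries(
        site_id=site_id,
        year=np.repeat(np.arange(1, n_years + 1), 365),
        doy=np.tile(np.arange(1, 366), n_years),
        tmin=np.full(n, tmin), tmax=np.full(n, tmax),
        srad=np.full(n, srad), precip=np.full(n, precip),
    )
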