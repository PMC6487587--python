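"""Synthetic benchmark scenarios isolating the grain-number mechanism.

Two constructed site climates bracket the drought exposure of the
reproductive window:

* ``synthetic_wet_site`` — cool, very wet (1400 mm, no summer deficit):
  the 15-day window around anthesis is never water-limited, so the
  drought-sensitive and drought-tolerant grain sets behave identically;
* ``synthetic_dry_site`` — warm, semi-arid (300 mm, strong spring-summer
  deficit): the window is stressed in essentially every year and grain
  number is reduced for the sensitive cultivar.

These are labelled synthetic: they are not any of the 13 packaged sites
and stand in for scenario extremes that real downscaled weather files
would provide.
"""

from __future__ import annotations

from .params import CultivarParams
from .sites import SiteClimate

#: mid-range reference cultivar used by the benchmark scenarios
REFERENCE_CULTIVAR = CultivarParams(Ph=100.0, Pp=0.60, Gf=650.0, A=0.006,
                                    SG=0.5, Ru=5.0, Wsa=0.5, Wss=1.27)


def synthetic_wet_site() -> SiteClimate:
    return SiteClimate(
        site_id="WETX", name="synthetic wet benchmark", country="-",
        latitude=47.0, longitude=0.0, mean_annual_temp=11.5,
        annual_precip=1400.0, sowing_date="10-01", summer_dryness=0.0,
        temp_amplitude=8.5, scenario="synthetic")


def synthetic_dry_site() -> SiteClimate:
    return SiteClimate(
        site_id="DRYX", name="synthetic dry benchmark", country="-",
        latitude=41.0, longitude=0.0, mean_annual_temp=14.0,
        annual_precip=300.0, sowing_date="11-01", summer_dryness=3.5,
        temp_amplitude=8.5, scenario="synthetic")
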