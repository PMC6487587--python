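"""Site climate descriptions for the 13 European wheat-growing sites.

Each site carries the 2050-scenario climate normals (mean annual
temperature, annual precipitation), location, local sowing date and the
scenario CO2 concentration, plus two generator knobs that the normals do
not pin down: the seasonal temperature half-range ``temp_amplitude`` and
the warm-season precipitation-deficit knob ``summer_dryness``.

Sites are packaged as editable YAML files under ``data/sites`` and group
into three drought-scenario presets: ``dry-south`` (Seville, Lleida),
``wet-northwest`` (Toulouse, Vienna, Rothamsted, Wageningen) and
``intermediate`` (the rest).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from importlib import resources

import yaml

SCENARIO_CO2_PPM = 541.0  # RCP8.5 concentration in 2050


@dataclass(frozen=True)
class SiteClimate:
    """Climate normals and generator configuration for one site."""

    site_id: str
    name: str
    country: str
    latitude: float  # degrees N
    longitude: float  # degrees E
    mean_annual_temp: float  # deg C
    annual_precip: float  # mm / year
    sowing_date: str  # "MM-DD"
    cultivar: str = ""
    summer_dryness: float = 1.0  # >= 0; scales warm-season precip deficit
    temp_amplitude: float = 9.0  # deg C, seasonal half-range
    co2_ppm: float = SCENARIO_CO2_PPM
    scenario: str = "intermediate"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.site_id}: latitude {self.latitude} outside [-90, 90]")
        if self.annual_precip <= 0:
            raise ValueError(f"{self.site_id}: annual_precip must be positive")
        if not -20.0 <= self.mean_annual_temp <= 40.0:
            raise ValueError(f"{self.site_id}: mean_annual_temp {self.mean_annual_temp} implausible")
        if self.co2_ppm <= 0:
            raise ValueError(f"{self.site_id}: co2_ppm must be positive")
        if self.summer_dryness < 0:
            raise ValueError(f"{self.site_id}: summer_dryness must be >= 0")

    @property
    def sowing_doy(self) -> int:
        """Day-of-year of sowing on the 365-day calendar."""
        month, day = (int(x) for x in self.sowing_date.split("-"))
        return datetime.date(2001, month, day).timetuple().tm_yday  # 2001: not a leap year


def _site_dir():
    return resources.files("droughtwheat") / "data" / "sites"


def list_site_ids() -> list[str]:
    """IDs of all packaged sites, ordered south to north."""
    ids = []
    for entry in _site_dir().iterdir():
        if entry.name.endswith(".yaml"):
            ids.append(entry.name[:-5])
    order = {sid: i for i, sid in enumerate(
        ["SL", "LL", "MO", "TU", "SR", "CF", "DC", "VI", "HA", "RR", "WA", "KA", "TR"])}
    return sorted(ids, key=lambda s: order.get(s, 99))


def load_site(site_id: str) -> SiteClimate:
    """Load one packaged site by its two-letter ID."""
    path = _site_dir() / f"{site_id}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown site {site_id!r}; known: {list_site_ids()}") from None
    return site_from_dict(raw)


def site_from_dict(raw: dict) -> SiteClimate:
    known = {f for f in SiteClimate.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return SiteClimate(**kwargs, extra=extra)


def load_all_sites() -> dict[str, SiteClimate]:
    return {sid: load_site(sid) for sid in list_site_ids()}
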