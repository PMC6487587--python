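"""Daily-time-step wheat season simulation and multi-year aggregation.

One season runs from sowing (soil profile full) to maturity (grain-filling
thermal time complete, or the canopy fully senesced). The daily loop:

1. thermal time from daily mean temperature (base 0 deg C);
2. before emergence (150 deg C day after sowing): bare-soil water balance only;
3. at emergence the final leaf number is fixed from the daylength response,
   which sets the anthesis and maturity thermal-time targets;
4. each day: Beer-law interception from green LAI, Priestley-Taylor demand,
   root uptake (Ta), stress factor SF = Ta/Tp, RUE-based assimilation reduced
   by SF**Wsa, stress-accelerated canopy senescence;
5. ear dry matter accumulates as a fixed fraction of assimilation over the
   last 300 deg C day before anthesis;
6. the drought stress factor DSF = sum(Ta)/sum(Tp) over the 15-day window
   around anthesis fixes the grain-number reduction R and hence the grain
   sink capacity (tolerant cultivars: R = 1);
7. grain filling draws on new assimilate plus a labile stem reserve set at
   anthesis, capped by the sink; yield is grain mass at maturity.

Every water flux is tracked so the seasonal balance closes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physiology as phys
from .canopy import Canopy, canopy_daily_update
from .params import CultivarParams, GrainSetParams, ModelConstants, SoilProfile
from .sites import SiteClimate
from .soilwater import infiltrate, soil_evaporation, soil_water_uptake
from .solar import daylength
from .weather import DAYS_PER_YEAR, WeatherSeries

G_M2_TO_T_HA = 0.01  # g m^-2 -> t ha^-1


class SeasonError(RuntimeError):
    """A season could not be completed within the supplied weather."""


@dataclass
class SeasonWeather:
    """Daily weather arrays for one season, starting at sowing."""

    doy: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    srad: np.ndarray
    precip: np.ndarray

    @property
    def n_days(self) -> int:
        return self.doy.size


@dataclass
class SeasonResult:
    yield_t_ha: float
    grain_number: float  # grains m^-2
    r: float  # grain-number reduction factor
    dsf: float
    anthesis_doy: int | None
    maturity_doy: int | None
    biomass_final_t_ha: float
    mean_sf_grainfill: float
    dm_ear: float  # g m^-2
    emerged: bool = True
    water_balance: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    @property
    def water_balance_residual(self) -> float:
        wb = self.water_balance
        return (wb["soil_initial"] + wb["precip"]
                - wb["soil_final"] - wb["transpiration"]
                - wb["evaporation"] - wb["drainage"])


@dataclass
class MultiYearResult:
    yields: np.ndarray  # t ha^-1, one per season
    seasons: list[SeasonResult]

    @property
    def mean_yield(self) -> float:
        return float(np.mean(self.yields))

    @property
    def cv(self) -> float:
        """Coefficient of variation of annual yield (sample sd / mean)."""
        m = self.mean_yield
        sd = float(np.std(self.yields, ddof=1)) if self.yields.size > 1 else 0.0
        if m > 0:
            return sd / m
        return 0.0 if sd == 0.0 else math.inf


def season_weather(series: WeatherSeries, season_index: int,
                   sowing_doy: int) -> SeasonWeather:
    """Slice season ``season_index`` (0-based): sowing in year season_index+1,
    weather through the end of the following year."""
    n_years = series.n_years
    if season_index < 0 or season_index >= n_years - 1:
        raise IndexError(f"season {season_index} needs years "
                         f"{season_index + 1}-{season_index + 2} of {n_years}")
    start = season_index * DAYS_PER_YEAR + sowing_doy - 1
    stop = (season_index + 2) * DAYS_PER_YEAR
    sl = slice(start, stop)
    return SeasonWeather(doy=series.doy[sl], tmin=series.tmin[sl],
                         tmax=series.tmax[sl], srad=series.srad[sl],
                         precip=series.precip[sl])


def simulate_season(weather: SeasonWeather, cultivar: CultivarParams,
                    grain: GrainSetParams, soil: SoilProfile, site: SiteClimate,
                    consts: ModelConstants = ModelConstants(),
                    diagnostics: bool = False) -> SeasonResult:
    """Simulate one season from sowing; see the module docstring for the loop."""
    n_days = weather.n_days
    rue_eff = (consts.rue_ref * (1.0 + consts.rue_uplift)
               * phys.rue_co2_multiplier(site.co2_ppm, consts.co2_ref,
                                         consts.rue_co2_slope))

    soil_water = soil.awc_per_layer.copy()  # profile full at sowing
    soil_initial = float(soil_water.sum())
    cum_precip = cum_evap = cum_transp = cum_drain = 0.0

    ta_daily = np.zeros(n_days)
    tp_daily = np.zeros(n_days)

    tt_sow = 0.0  # thermal time since sowing
    tt_pe = 0.0  # thermal time since emergence
    emerged = False
    canopy: Canopy | None = None
    tt_anthesis = tt_maturity = math.inf
    root_depth = soil.layer_thickness

    biomass = dm_ear = grain_mass = 0.0
    reserve = reserve_at_anthesis = 0.0
    anthesis_idx: int | None = None
    anthesis_doy: int | None = None
    window_closed = False
    dsf = 1.0
    r = 1.0
    grain_number = 0.0
    sink = math.inf
    sf_sum = 0.0
    sf_days = 0
    maturity_idx: int | None = None
    maturity_doy: int | None = None

    diag: dict[str, list] | None = None
    if diagnostics:
        diag = {k: [] for k in ("day", "doy", "tt", "lai", "sf", "ta", "tp",
                                "biomass", "dm_ear", "grain_mass", "soil_water")}

    def _close_window(day_idx: int) -> None:
        nonlocal window_closed, dsf, r, grain_number, sink, grain_mass, reserve
        w0 = max(0, anthesis_idx - consts.window_before)
        dsf = phys.compute_dsf(ta_daily[w0:day_idx + 1], tp_daily[w0:day_idx + 1])
        r = phys.grain_reduction_factor(dsf, grain)
        grain_number, sink = phys.sink_capacity(dm_ear, r, grain)
        if grain_mass > sink:  # provisional fill above the final sink returns to stem
            reserve += grain_mass - sink
            grain_mass = sink
        window_closed = True

    for d in range(n_days):
        tmin, tmax = float(weather.tmin[d]), float(weather.tmax[d])
        srad, precip = float(weather.srad[d]), float(weather.precip[d])
        tmean = (tmin + tmax) / 2.0
        tt_inc = phys.thermal_time_increment(tmin, tmax, consts.t_base)

        cum_precip += precip
        soil_water, drained = infiltrate(soil_water, precip, soil)
        cum_drain += drained

        pet = phys.priestley_taylor_et(srad, tmean, consts.pt_alpha,
                                       consts.rn_fraction)

        if not emerged:
            soil_water, ev = soil_evaporation(soil_water, pet, soil)
            cum_evap += ev
            tt_sow += tt_inc
            if tt_sow >= consts.emergence_tt:
                emerged = True
                dl = daylength(site.latitude, int(weather.doy[d]))
                fln = phys.final_leaf_number(cultivar.Pp, dl, consts.fln_base,
                                             consts.daylength_sat)
                canopy = Canopy(fln, cultivar, consts)
                tt_anthesis = canopy.n_layers * cultivar.Ph + consts.anthesis_lag_tt
                tt_maturity = tt_anthesis + cultivar.Gf
                tt_pe = 0.0
            continue

        lai = canopy.green_lai(tt_pe)
        f_int = phys.intercepted_fraction(lai, consts.k)
        tp = pet * f_int
        soil_water, ev = soil_evaporation(soil_water, pet * (1.0 - f_int), soil)
        cum_evap += ev
        ta, soil_water = soil_water_uptake(soil_water, tp, root_depth,
                                           cultivar.Ru, soil)
        cum_transp += ta
        sf = phys.stress_factor(ta, tp)
        ta_daily[d] = ta
        tp_daily[d] = tp

        assim = phys.assimilation(srad, f_int, rue_eff, sf, cultivar.Wsa,
                                  consts.par_fraction)
        biomass += assim
        if anthesis_idx is None and tt_pe >= tt_anthesis - consts.ear_growth_tt:
            dm_ear += consts.ear_partition * assim

        tt_pe += tt_inc
        canopy_daily_update(canopy, tt_pe, tt_inc, sf, cultivar.Wss)
        if anthesis_idx is None:
            root_depth = min(soil.max_root_depth,
                             root_depth + consts.root_elongation * tt_inc)
            if tt_pe >= tt_anthesis:
                anthesis_idx = d
                anthesis_doy = int(weather.doy[d])
                reserve = consts.reserve_fraction * biomass
                reserve_at_anthesis = reserve

        if anthesis_idx is not None and not window_closed \
                and d == anthesis_idx + consts.window_after - 1:
            _close_window(d)

        if anthesis_idx is not None:
            cap = sink if window_closed else dm_ear * grain.npot * grain.wpot
            withdraw = min(reserve, consts.reserve_withdrawal * reserve_at_anthesis)
            fill = min(consts.grain_partition * assim + withdraw,
                       max(0.0, cap - grain_mass))
            from_reserve = max(0.0, fill - consts.grain_partition * assim)
            reserve -= from_reserve
            grain_mass += fill
            sf_sum += sf
            sf_days += 1

        if diag is not None:
            diag["day"].append(d)
            diag["doy"].append(int(weather.doy[d]))
            diag["tt"].append(tt_pe)
            diag["lai"].append(canopy.green_lai(tt_pe))
            diag["sf"].append(sf)
            diag["ta"].append(ta)
            diag["tp"].append(tp)
            diag["biomass"].append(biomass)
            diag["dm_ear"].append(dm_ear)
            diag["grain_mass"].append(grain_mass)
            diag["soil_water"].append(float(soil_water.sum()))

        if anthesis_idx is not None and (
                tt_pe >= tt_maturity or canopy.green_lai(tt_pe) <= 1e-9):
            if not window_closed:  # canopy died inside the window
                _close_window(d)
            maturity_idx = d
            maturity_doy = int(weather.doy[d])
            break

    if not emerged:
        wb = dict(soil_initial=soil_initial, precip=cum_precip,
                  soil_final=float(soil_water.sum()), transpiration=cum_transp,
                  evaporation=cum_evap, drainage=cum_drain)
        return SeasonResult(0.0, 0.0, 1.0, 1.0, None, None, 0.0, 1.0, 0.0,
                            emerged=False, water_balance=wb)
    if maturity_idx is None:
        raise SeasonError("season ran past the end of the weather record "
                          f"({n_days} days) before maturity")

    wb = dict(soil_initial=soil_initial, precip=cum_precip,
              soil_final=float(soil_water.sum()), transpiration=cum_transp,
              evaporation=cum_evap, drainage=cum_drain)
    return SeasonResult(
        yield_t_ha=grain_mass * G_M2_TO_T_HA,
        grain_number=grain_number,
        r=r, dsf=dsf,
        anthesis_doy=anthesis_doy, maturity_doy=maturity_doy,
        biomass_final_t_ha=biomass * G_M2_TO_T_HA,
        mean_sf_grainfill=(sf_sum / sf_days) if sf_days else 1.0,
        dm_ear=dm_ear,
        water_balance=wb,
        diagnostics=pd.DataFrame(diag) if diag is not None else None,
    )


def simulate_years(series: WeatherSeries, cultivar: CultivarParams,
                   grain: GrainSetParams, soil: SoilProfile, site: SiteClimate,
                   consts: ModelConstants = ModelConstants()) -> MultiYearResult:
    """Simulate every complete season in ``series`` (sowing each autumn).

    An n-year series holds n-1 complete sowing-to-harvest seasons, since the
    season sown in the final year cannot be harvested. The soil profile is
    refilled at each sowing, so seasons are independent.
    """
    if series.n_years < 2:
        raise ValueError("need at least 2 weather years for one season")
    sowing_doy = site.sowing_doy
    results = []
    for s in range(series.n_years - 1):
        try:
            results.append(simulate_season(season_weather(series, s, sowing_doy),
                                           cultivar, grain, soil, site, consts))
        except Exception as exc:
            raise SeasonError(f"season {s} (sowing year {s + 1}): {exc}") from exc
    return MultiYearResult(
        yields=np.array([r.yield_t_ha for r in results]), seasons=results)
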