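"""Seeded synthetic daily weather emulating the 2050 site climates.

The generator stands in for downscaled climate-scenario files that are not
distributable: it produces, per site, ``n_years`` of daily Tmin/Tmax, global
radiation and precipitation whose long-run annual means match the site's
climate normals by construction, with a controllable early-summer drought
propensity (``SiteClimate.summer_dryness``).

Structure (deliberately minimal, LARS-WG-like):

* precipitation occurrence — first-order two-state Markov chain with monthly
  wet-day probabilities; wet-day amounts gamma-distributed with monthly scale;
* monthly precipitation targets are solved from (annual_precip,
  summer_dryness): a winter-peaked seasonal shape is multiplied by
  ``exp(-summer_dryness * s_m)`` on the warm months and renormalized, so the
  annual total is preserved while June-July precipitation strictly decreases
  in ``summer_dryness``;
* temperature — sinusoidal annual cycle (peak near day 200) plus an AR(1)
  daily anomaly; Tmin/Tmax from a diurnal range reduced on wet days;
* radiation — clear-sky envelope (extraterrestrial radiation x transmissivity)
  with lower transmissivity on wet days.

A 365-day calendar is used (no leap days).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sites import SiteClimate
from .solar import extraterrestrial_radiation

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: month (1..12) for each doy (1..365)
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)

#: warm-season weight of the dryness knob, months 1..12; the deficit builds
#: from early spring and peaks over May-July (Mediterranean-style dry season)
_SUMMER_WEIGHT = np.array([0, 0.1, 0.5, 0.8, 1.0, 1.0, 1.0, 0.6, 0.2, 0, 0, 0])
#: winter-peaked baseline seasonal shape (relative monthly weights)
_WINTER_AMPLITUDE = 0.15

SRAD_MAX = 42.0  # MJ m^-2 day^-1, physical ceiling for daily global radiation

CSV_COLUMNS = ["site_id", "year", "doy", "tmin_c", "tmax_c", "srad_mj_m2", "precip_mm"]


@dataclass(frozen=True)
class WeatherGenConfig:
    n_years: int = 100
    seed: int = 0
    wet_day_prob_by_month: np.ndarray | None = None  # override; else solved
    gamma_shape: float = 0.75  # shape of wet-day amount distribution
    diurnal_range_mean: float = 10.0  # deg C
    markov_persistence: float = 0.30  # wet-day clustering, in [0, 1)
    anomaly_sd: float = 2.0  # deg C, marginal sd of the AR(1) anomaly
    anomaly_phi: float = 0.70  # AR(1) autocorrelation
    tau_dry: float = 0.72  # atmospheric transmissivity, dry days
    tau_wet: float = 0.45  # atmospheric transmissivity, wet days

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.wet_day_prob_by_month is not None:
            p = np.asarray(self.wet_day_prob_by_month, dtype=float)
            if p.shape != (12,) or np.any(p < 0) or np.any(p > 1):
                raise ValueError("wet_day_prob_by_month must be 12 probabilities")
            object.__setattr__(self, "wet_day_prob_by_month", p)
        if not 0.0 <= self.markov_persistence < 1.0:
            raise ValueError("markov_persistence must lie in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


@dataclass
class WeatherSeries:
    """n_years of contiguous daily weather for one site (flat day arrays)."""

    site_id: str
    year: np.ndarray  # 1-based year index
    doy: np.ndarray  # 1..365
    tmin: np.ndarray  # deg C
    tmax: np.ndarray  # deg C
    srad: np.ndarray  # MJ m^-2 day^-1
    precip: np.ndarray  # mm day^-1

    def __post_init__(self) -> None:
        n = self.year.size
        for name in ("doy", "tmin", "tmax", "srad", "precip"):
            if getattr(self, name).size != n:
                raise ValueError("all day arrays must have equal length")
        if n == 0 or n % DAYS_PER_YEAR != 0:
            raise ValueError("series must cover complete 365-day years")
        expect_doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n // DAYS_PER_YEAR)
        if not np.array_equal(self.doy, expect_doy):
            raise ValueError("days must be contiguous, doy 1..365 per year")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin")
        if np.any(self.srad < 0) or np.any(self.srad > SRAD_MAX):
            raise ValueError(f"srad outside [0, {SRAD_MAX}]")
        if np.any(self.precip < 0):
            raise ValueError("negative precipitation")

    @property
    def n_years(self) -> int:
        return self.year.size // DAYS_PER_YEAR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_id": self.site_id, "year": self.year, "doy": self.doy,
            "tmin_c": self.tmin, "tmax_c": self.tmax,
            "srad_mj_m2": self.srad, "precip_mm": self.precip,
        })


@dataclass(frozen=True)
class ClimateSummary:
    mean_annual_temp: float  # deg C, mean of daily (tmin+tmax)/2
    mean_annual_precip: float  # mm year^-1, total / n_years
    monthly_mean_temp: np.ndarray  # 12 values, deg C
    monthly_mean_precip: np.ndarray  # 12 values, mm month^-1 (per-year mean)


def monthly_precip_targets(site: SiteClimate) -> np.ndarray:
    """Expected precipitation per calendar month (mm), summing to the annual total.

    The winter-peaked baseline shape is suppressed on warm months by
    exp(-summer_dryness * weight) and renormalized, so increasing
    ``summer_dryness`` strictly shifts precipitation out of early summer
    while preserving the annual total.
    """
    months = np.arange(12)
    base = 1.0 + _WINTER_AMPLITUDE * np.cos(2.0 * np.pi * months / 12.0)  # peak Jan
    shaped = base * np.exp(-site.summer_dryness * _SUMMER_WEIGHT)
    frac = shaped / shaped.sum()
    return site.annual_precip * frac


def solve_precip_params(site: SiteClimate, cfg: WeatherGenConfig):
    """Monthly wet-day probabilities and gamma scales meeting the targets.

    Wet-day probability follows the monthly precipitation share (capped to
    [0.05, 0.85]); the wet-day mean amount is then solved so that each
    month's expected total equals its target exactly, whatever the cap did.
    """
    targets = monthly_precip_targets(site)
    if cfg.wet_day_prob_by_month is not None:
        p_wet = cfg.wet_day_prob_by_month.copy()
    else:
        p_base = np.clip(site.annual_precip / 900.0, 0.15, 0.65)
        share = targets / targets.sum()
        p_wet = np.clip(p_base * np.sqrt(12.0 * share), 0.05, 0.85)
    mean_amount = targets / (MONTH_LENGTHS * np.maximum(p_wet, 1e-9))
    gamma_scale = mean_amount / cfg.gamma_shape
    return p_wet, gamma_scale


def generate_series(site: SiteClimate, cfg: WeatherGenConfig) -> WeatherSeries:
    """Generate a seeded-deterministic multi-year daily series for ``site``."""
    site_key = zlib.crc32(site.site_id.encode()) & 0x7FFFFFFF  # stable across runs
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, site_key)))
    n_days = cfg.n_years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), cfg.n_years)
    year = np.repeat(np.arange(1, cfg.n_years + 1), DAYS_PER_YEAR)
    month_idx = MONTH_OF_DOY[doy - 1] - 1  # 0-based month per day

    # --- precipitation occurrence: first-order Markov chain -----------------
    p_wet, gamma_scale = solve_precip_params(site, cfg)
    r = cfg.markov_persistence
    u = rng.random(n_days)
    wet = np.zeros(n_days, dtype=bool)
    prev = False
    for i in range(n_days):
        p = p_wet[month_idx[i]]
        # transition probabilities keep the stationary wet fraction at p
        p_trans = p + r * (1.0 - p) if prev else p * (1.0 - r)
        prev = u[i] < p_trans
        wet[i] = prev

    precip = np.zeros(n_days)
    n_wet = int(wet.sum())
    if n_wet:
        amounts = rng.gamma(cfg.gamma_shape, 1.0, size=n_wet)
        precip[wet] = amounts * gamma_scale[month_idx[wet]]

    # --- temperature: seasonal sinusoid + AR(1) anomaly ---------------------
    seasonal = site.mean_annual_temp + site.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - 200) / DAYS_PER_YEAR)
    eps = rng.normal(0.0, cfg.anomaly_sd * np.sqrt(1.0 - cfg.anomaly_phi**2), n_days)
    anomaly = np.empty(n_days)
    a = 0.0
    phi = cfg.anomaly_phi
    for i in range(n_days):
        a = phi * a + eps[i]
        anomaly[i] = a
    tmean = seasonal + anomaly
    diurnal = np.maximum(rng.normal(cfg.diurnal_range_mean, 2.0, n_days), 1.0)
    diurnal[wet] *= 0.75  # cloudy days have a smaller diurnal range
    tmin = tmean - diurnal / 2.0
    tmax = tmean + diurnal / 2.0

    # --- radiation: clear-sky envelope x transmissivity ---------------------
    ra = extraterrestrial_radiation(site.latitude, doy)
    tau = np.where(wet, cfg.tau_wet, cfg.tau_dry) + rng.normal(0.0, 0.06, n_days)
    srad = np.clip(ra * np.clip(tau, 0.10, 0.80), 0.0, SRAD_MAX)

    return WeatherSeries(site_id=site.site_id, year=year, doy=doy,
                         tmin=tmin, tmax=tmax, srad=srad, precip=precip)


def summarize_series(series: WeatherSeries) -> ClimateSummary:
    """Long-run climate summary of a series (validation against site normals)."""
    if series.year.size == 0:
        raise ValueError("empty series")
    tmean = (series.tmin + series.tmax) / 2.0
    month_idx = MONTH_OF_DOY[series.doy - 1] - 1
    monthly_temp = np.array([tmean[month_idx == m].mean() for m in range(12)])
    monthly_precip = np.array(
        [series.precip[month_idx == m].sum() / series.n_years for m in range(12)])
    return ClimateSummary(
        mean_annual_temp=float(tmean.mean()),
        mean_annual_precip=float(series.precip.sum() / series.n_years),
        monthly_mean_temp=monthly_temp,
        monthly_mean_precip=monthly_precip,
    )


def write_weather_csv(series: WeatherSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.4f")


def read_weather_csv(path) -> WeatherSeries:
    """Read and validate a weather CSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = CSV_COLUMNS[1:]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    problems = (coerced["tmax_c"] < coerced["tmin_c"]) | (coerced["precip_mm"] < 0) \
        | (coerced["srad_mj_m2"] < 0) | (coerced["srad_mj_m2"] > SRAD_MAX)
    if problems.any():
        lines = [int(i) + 2 for i in df.index[problems][:10]]
        raise ValueError(f"{path}: physically invalid rows at lines {lines}")
    site_ids = df["site_id"].unique()
    if site_ids.size != 1:
        raise ValueError(f"{path}: expected one site per file, got {list(site_ids)}")
    return WeatherSeries(
        site_id=str(site_ids[0]),
        year=coerced["year"].to_numpy(dtype=int),
        doy=coerced["doy"].to_numpy(dtype=int),
        tmin=coerced["tmin_c"].to_numpy(), tmax=coerced["tmax_c"].to_numpy(),
        srad=coerced["srad_mj_m2"].to_numpy(), precip=coerced["precip_mm"].to_numpy(),
    )
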