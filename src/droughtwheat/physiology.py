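"""Closed-form crop physiology operations.

These are the building blocks of the daily simulator: thermal time, final
leaf number, Beer-law light interception, the RUE-CO2 response, water-stress
multipliers, Priestley-Taylor transpiration demand, and the
reproductive-stage drought grain-number mechanism (DSF -> R -> sink capacity).
"""

from __future__ import annotations

import math

import numpy as np

from .params import GrainSetParams, ModelConstants

LATENT_HEAT = 2.45  # MJ kg^-1, latent heat of vaporization
PSYCHROMETRIC = 0.066  # kPa / deg C


def thermal_time_increment(tmin: float, tmax: float, t_base: float = 0.0) -> float:
    """Daily thermal time (deg C day): mean temperature above base, floored at 0."""
    if tmax < tmin:
        raise ValueError(f"tmax {tmax} < tmin {tmin}")
    return max(0.0, (tmin + tmax) / 2.0 - t_base)


def final_leaf_number(pp: float, daylength_at_emergence: float,
                      fln_base: float = 8.0, daylength_sat: float = 15.0) -> float:
    """Mainstem final leaf number from the daylength response.

    Short days at emergence add leaves in proportion to the cultivar's
    daylength response Pp; above ``daylength_sat`` hours FLN is at its base.
    Vernalization is assumed fully satisfied (autumn/winter sowing).
    """
    if not 0.0 <= daylength_at_emergence <= 24.0:
        raise ValueError("daylength must lie in [0, 24] h")
    return fln_base + pp * max(0.0, daylength_sat - daylength_at_emergence)


def intercepted_fraction(lai: float, k: float = 0.45) -> float:
    """Beer-law fraction of incident radiation intercepted by the canopy."""
    if lai < 0:
        raise ValueError("negative LAI")
    return 1.0 - math.exp(-k * lai)


def rue_co2_multiplier(co2: float, co2_ref: float, slope: float = 0.30) -> float:
    """RUE multiplier for CO2 fertilization: linear in concentration,
    1 at the reference and 1 + slope at a doubling."""
    if co2 <= 0 or co2_ref <= 0:
        raise ValueError("CO2 concentrations must be positive")
    return 1.0 + slope * (co2 / co2_ref - 1.0)


def water_stress_multiplier(sf: float, wsa: float) -> float:
    """Photosynthesis reduction SF**Wsa.

    A small exponent (Wsa -> 0.1) means a weak response, i.e. a cultivar
    tolerant to water shortage; Wsa = 1 makes assimilation proportional to SF.
    """
    if not 0.0 <= sf <= 1.0:
        raise ValueError("SF must lie in [0, 1]")
    if sf == 0.0:
        return 0.0 if wsa > 0 else 1.0
    return sf ** wsa


def assimilation(srad: float, f_int: float, rue_eff: float, sf: float,
                 wsa: float, par_fraction: float = 0.5) -> float:
    """Daily biomass production (g DM m^-2): intercepted PAR x effective RUE,
    reduced by the water-stress response SF**Wsa."""
    return par_fraction * srad * f_int * rue_eff * water_stress_multiplier(sf, wsa)


def priestley_taylor_et(srad: float, tmean: float, alpha: float = 1.26,
                        rn_fraction: float = 0.75) -> float:
    """Priestley-Taylor reference evapotranspiration (mm day^-1).

    Net radiation is approximated as ``rn_fraction`` of global radiation
    (no humidity or wind inputs are available from the generator).
    """
    if srad <= 0:
        return 0.0
    es = 0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))
    delta = 4098.0 * es / (tmean + 237.3) ** 2
    rn = rn_fraction * srad
    return max(0.0, alpha * delta / (delta + PSYCHROMETRIC) * rn / LATENT_HEAT)


def potential_transpiration(srad: float, tmean: float, f_int: float,
                            consts: ModelConstants) -> float:
    """Canopy transpiration demand Tp: reference ET times intercepted fraction."""
    if not 0.0 <= f_int <= 1.0:
        raise ValueError("f_int must lie in [0, 1]")
    return priestley_taylor_et(srad, tmean, consts.pt_alpha, consts.rn_fraction) * f_int


def stress_factor(ta: float, tp: float) -> float:
    """Daily water-stress factor SF = Ta/Tp; no demand means no stress (SF=1)."""
    if ta < 0 or tp < 0:
        raise ValueError("transpiration terms must be non-negative")
    if ta > tp + 1e-9:
        raise ValueError(f"Ta {ta} exceeds Tp {tp}")
    if tp <= 0.0:
        return 1.0
    return min(1.0, ta / tp)


def compute_dsf(daily_ta, daily_tp) -> float:
    """Drought stress factor over the reproductive window: ratio of sums.

    DSF = sum(Ta) / sum(Tp) over the 15-day window around anthesis
    (10 days before through 4 days after, anthesis day included); a window
    with no transpiration demand gives DSF = 1 (no stress).
    """
    ta = np.asarray(daily_ta, dtype=float)
    tp = np.asarray(daily_tp, dtype=float)
    if ta.shape != tp.shape:
        raise ValueError("Ta and Tp windows must align")
    if np.any(ta > tp + 1e-9):
        raise ValueError("Ta exceeds Tp within the window")
    total_tp = float(tp.sum())
    if total_tp <= 0.0:
        return 1.0
    return float(min(1.0, ta.sum() / total_tp))


def grain_reduction_factor(dsf: float, p: GrainSetParams) -> float:
    """Grain-number reduction factor R(DSF).

    Piecewise linear: R = dsgnr_max for DSF <= dsgns (saturated drought),
    rising with slope S = (1 - dsgnr_max)/(dsgnt - dsgns) between the
    breakpoints, and R = 1 for DSF >= dsgnt (no reduction). Continuous at
    both breakpoints. Tolerant cultivars have R = 1 at any DSF.
    """
    if not 0.0 <= dsf <= 1.0:
        raise ValueError("DSF must lie in [0, 1]")
    if p.tolerant:
        return 1.0
    if dsf <= p.dsgns:
        return p.dsgnr_max
    if dsf >= p.dsgnt:
        return 1.0
    slope = (1.0 - p.dsgnr_max) / (p.dsgnt - p.dsgns)
    return p.dsgnr_max + slope * (dsf - p.dsgns)


def sink_capacity(dm_ear: float, r: float, p: GrainSetParams) -> tuple[float, float]:
    """Grain number (m^-2) and grain sink capacity (g m^-2).

    grain_number = DM_ear x Npot x R; sink = grain_number x Wpot.
    """
    if dm_ear < 0:
        raise ValueError("negative ear dry mass")
    if not 0.0 < r <= 1.0:
        raise ValueError("R must lie in (0, 1]")
    grain_number = dm_ear * p.npot * r
    return grain_number, grain_number * p.wpot
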