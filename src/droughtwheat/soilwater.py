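"""Layered soil water bucket: infiltration, evaporation, root uptake.

Water state is a vector of plant-available water (mm) per 5-cm layer,
bounded by each layer's available water capacity. All fluxes are returned
explicitly so a season-level water balance can be closed exactly.
"""

from __future__ import annotations

import numpy as np

from .params import SoilProfile


def infiltrate(soil_water: np.ndarray, precip: float,
               profile: SoilProfile) -> tuple[np.ndarray, float]:
    """Cascade precipitation down the profile; the overflow is drainage.

    Returns (updated water, drainage in mm).
    """
    if precip < 0:
        raise ValueError("negative precipitation")
    water = soil_water.copy()
    remaining = precip
    for i in range(profile.n_layers):
        if remaining <= 0.0:
            break
        room = profile.awc_per_layer[i] - water[i]
        taken = min(room, remaining)
        water[i] += taken
        remaining -= taken
    return water, remaining


def soil_evaporation(soil_water: np.ndarray, demand: float,
                     profile: SoilProfile, n_top: int = 2) -> tuple[np.ndarray, float]:
    """Evaporate from the top ``n_top`` layers, throttled by their dryness.

    Actual evaporation = demand x (available/capacity of the top layers),
    removed proportionally to each layer's content. Returns (water, actual).
    """
    if demand < 0:
        raise ValueError("negative evaporative demand")
    water = soil_water.copy()
    top = slice(0, n_top)
    avail = float(water[top].sum())
    cap = float(profile.awc_per_layer[top].sum())
    if avail <= 0.0 or cap <= 0.0 or demand == 0.0:
        return water, 0.0
    actual = min(avail, demand * avail / cap)
    water[top] -= actual * water[top] / avail
    return water, actual


def soil_water_uptake(soil_water: np.ndarray, demand: float, root_depth: float,
                      ru: float, profile: SoilProfile) -> tuple[float, np.ndarray]:
    """Extract root water uptake Ta from the rooted layers, top-down.

    Each rooted layer offers (Ru/100) * lambda_layer * available_layer per
    day; layers are harvested from the top until the demand is met. Layers
    below the root front are untouched. Returns (Ta, updated water);
    conservation: sum(before) - sum(after) == Ta exactly.
    """
    if demand < 0:
        raise ValueError("negative transpiration demand")
    water = soil_water.copy()
    if demand == 0.0:
        return 0.0, water
    n_rooted = min(profile.n_layers,
                   int(np.ceil(root_depth / profile.layer_thickness - 1e-9)))
    ta = 0.0
    remaining = demand
    frac = ru / 100.0
    for i in range(n_rooted):
        if remaining <= 0.0:
            break
        extractable = frac * profile.lambda_profile[i] * water[i]
        taken = min(extractable, remaining)
        water[i] -= taken
        ta += taken
        remaining -= taken
    return ta, water
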