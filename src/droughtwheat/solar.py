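"""Standalone solar geometry: daylength and extraterrestrial radiation.

Self-contained implementations of the standard declination / hour-angle
formulas; no external astronomy dependency. A 365-day calendar is used
throughout (leap days are ignored).
"""

from __future__ import annotations

import numpy as np

#: Solar constant, MJ m^-2 min^-1
SOLAR_CONSTANT = 0.0820

DAYS_PER_YEAR = 365


def solar_declination(doy):
    """Solar declination (radians) for day-of-year ``doy``.

    Uses the cosine approximation delta = -23.44 deg * cos(2*pi*(doy+10)/365),
    accurate to ~1 deg, which is ample for daylength and clear-sky envelopes.
    """
    doy = np.asarray(doy, dtype=float)
    return np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / DAYS_PER_YEAR))


def daylength(latitude: float, doy) -> float | np.ndarray:
    """Astronomical daylength in hours at ``latitude`` (deg N) on ``doy``.

    The standard sunrise hour-angle formula H = acos(-tan(phi) tan(delta)),
    L = 24 H / pi.  Near the poles the argument of acos leaves [-1, 1]
    (polar day / polar night); it is clamped so the result stays in [0, 24].
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    phi = np.deg2rad(latitude)
    delta = solar_declination(doy)
    cos_h = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    h = np.arccos(cos_h)
    out = 24.0 * h / np.pi
    if np.ndim(out) == 0:
        return float(out)
    return out


def extraterrestrial_radiation(latitude: float, doy) -> np.ndarray:
    """Daily top-of-atmosphere radiation Ra (MJ m^-2 day^-1).

    Ra = (24*60/pi) * Gsc * dr * (ws sin(phi) sin(delta) + cos(phi) cos(delta) sin(ws))
    with dr the inverse relative earth-sun distance and ws the sunset hour angle.
    """
    phi = np.deg2rad(latitude)
    doy = np.asarray(doy, dtype=float)
    delta = solar_declination(doy)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / DAYS_PER_YEAR)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (
        (24.0 * 60.0 / np.pi)
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return np.maximum(ra, 0.0)
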