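"""Layered canopy: per-leaf expansion, lifespan, and stress-accelerated senescence.

Each mainstem leaf forms one canopy layer. A layer's potential area ramps
linearly with leaf rank up to the cultivar's flag-leaf area ``A`` and
expands over one phyllochron of thermal time. After expansion a layer stays
fully green for most of its thermal-time lifespan and then fades linearly
to zero. Lifespans are scheduled so that, unstressed and without stay-green,
the flag leaf dies exactly at the end of grain filling and lower leaves die
progressively earlier.

Water stress accelerates senescence: the per-layer senescence clock advances
by tt_inc x (1 + (Wss - 1)(1 - SF)) — exactly tt_inc when unstressed (SF=1)
and Wss x tt_inc under full stress (SF=0). Stay-green multiplies every
layer's lifespan by (1 + sg_scale x SG).
"""

from __future__ import annotations

import numpy as np

from .params import CultivarParams, ModelConstants


class Canopy:
    """Green-area state of all leaf layers; thermal time is post-emergence."""

    def __init__(self, fln: float, cultivar: CultivarParams,
                 consts: ModelConstants) -> None:
        n = max(1, int(round(fln)))
        self.n_layers = n
        self.cultivar = cultivar
        self.consts = consts
        ranks = np.arange(1, n + 1, dtype=float)
        #: thermal time at which each leaf appears (post-emergence)
        self.tt_emerge = ranks * cultivar.Ph
        #: potential area per plant, ramping with rank to A for the flag leaf
        self.pot_area = cultivar.A * ranks / n
        tt_anthesis = n * cultivar.Ph + consts.anthesis_lag_tt
        # unstressed death schedule: flag leaf dies with the end of grain
        # filling, lower leaves die earlier in proportion to rank
        death = tt_anthesis + cultivar.Gf * (0.3 + 0.7 * ranks / n)
        base_life = death - (self.tt_emerge + cultivar.Ph)
        if np.any(base_life <= 0):
            base_life = np.maximum(base_life, 50.0)  # degenerate parameter corner
        self.lifespan = base_life * (1.0 + consts.sg_scale * cultivar.SG)
        self.sen_clock = np.zeros(n)

    def green_lai(self, tt: float) -> float:
        """Green leaf area index at post-emergence thermal time ``tt``."""
        expansion = np.clip((tt - self.tt_emerge) / self.cultivar.Ph, 0.0, 1.0)
        plateau = self.consts.green_plateau * self.lifespan
        ramp = (1.0 - self.consts.green_plateau) * self.lifespan
        green = np.clip((self.lifespan - self.sen_clock) / ramp, 0.0, 1.0)
        green[self.sen_clock <= plateau] = 1.0
        return float(self.consts.plants_per_m2 * np.sum(self.pot_area * expansion * green))


def canopy_daily_update(canopy: Canopy, tt: float, tt_inc: float, sf: float,
                        wss: float) -> float:
    """Advance senescence clocks of fully expanded layers and return green LAI.

    ``tt`` is post-emergence thermal time after today's increment ``tt_inc``;
    ``sf`` the day's water-stress factor; ``wss`` the cultivar's maximum
    senescence acceleration.
    """
    if not 0.0 <= sf <= 1.0:
        raise ValueError("SF must lie in [0, 1]")
    factor = 1.0 + (wss - 1.0) * (1.0 - sf)
    expanded = tt >= canopy.tt_emerge + canopy.cultivar.Ph
    canopy.sen_clock[expanded] += factor * tt_inc
    return canopy.green_lai(tt)
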