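"""Parameter containers: cultivar traits, grain-set constants, soil, model constants.

The eight optimizable cultivar parameters and their optimization bounds:

========  =============================================  ======================  ===========
symbol    meaning                                        unit                    bounds
========  =============================================  ======================  ===========
Ph        phyllochron                                    deg C day per leaf      80 - 130
Pp        daylength response                             leaf h^-1 daylength     0.05 - 0.70
Gf        grain-filling duration                         deg C day               500 - 900
A         maximum flag-leaf area                         m^2 leaf m^-2 soil      0.003 - 0.01
SG        stay-green factor                              --                      0.0 - 1.5
Ru        rate of root water uptake                      % day^-1                1.0 - 7.0
Wsa       photosynthesis response to water stress        -- (exponent)           0.1 - 2.1
Wss       maximum acceleration of leaf senescence        --                      1.2 - 1.9
========  =============================================  ======================  ===========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

PARAM_NAMES = ("Ph", "Pp", "Gf", "A", "SG", "Ru", "Wsa", "Wss")

#: Optimization ranges for the eight cultivar parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Ph": (80.0, 130.0),
    "Pp": (0.05, 0.70),
    "Gf": (500.0, 900.0),
    "A": (0.003, 0.01),
    "SG": (0.0, 1.5),
    "Ru": (1.0, 7.0),
    "Wsa": (0.1, 2.1),
    "Wss": (1.2, 1.9),
}


@dataclass(frozen=True)
class CultivarParams:
    Ph: float
    Pp: float
    Gf: float
    A: float
    SG: float
    Ru: float
    Wsa: float
    Wss: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "CultivarParams":
        return cls(**{n: float(v) for n, v in zip(PARAM_NAMES, x)})

    def replace(self, **kw) -> "CultivarParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (lower, upper) box used by the optimizer."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"{name}: lower {lo} must be < upper {hi}")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, params: CultivarParams, atol: float = 1e-9) -> bool:
        x = params.as_array()
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class GrainSetParams:
    """Constants of the reproductive-drought grain-number mechanism.

    Grain number per unit ear dry mass is reduced by the factor R(DSF):
    R saturates at ``dsgnr_max`` for DSF <= ``dsgns``, rises linearly with
    slope S = (1 - dsgnr_max)/(dsgnt - dsgns), and is 1 for DSF >= ``dsgnt``.
    A ``tolerant`` cultivar has R identically 1.
    """

    npot: float = 100.0  # potential grains per g ear dry mass
    wpot: float = 0.050  # potential single-grain weight, g
    dsgnt: float = 0.9   # drought-stress grain-number threshold
    dsgns: float = 0.3   # saturation point
    dsgnr_max: float = 0.2  # maximum reduction factor (floor of R)
    tolerant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsgns < self.dsgnt <= 1.0:
            raise ValueError("require 0 <= dsgns < dsgnt <= 1")
        if not 0.0 < self.dsgnr_max <= 1.0:
            raise ValueError("require 0 < dsgnr_max <= 1")
        if self.npot <= 0 or self.wpot <= 0:
            raise ValueError("npot and wpot must be positive")


@dataclass(frozen=True)
class SoilProfile:
    """Cascade of equal-thickness layers with per-layer available water capacity.

    ``lambda_profile`` is the relative extraction efficiency per layer,
    non-increasing with depth; daily extractable water from layer i is
    (Ru/100) * lambda_i * available_i.
    """

    layer_thickness: float  # m
    awc_per_layer: np.ndarray  # mm per layer
    lambda_profile: np.ndarray  # (0, 1] per layer, non-increasing
    max_root_depth: float  # m

    def __post_init__(self) -> None:
        awc = np.asarray(self.awc_per_layer, dtype=float)
        lam = np.asarray(self.lambda_profile, dtype=float)
        object.__setattr__(self, "awc_per_layer", awc)
        object.__setattr__(self, "lambda_profile", lam)
        if awc.shape != lam.shape:
            raise ValueError("awc_per_layer and lambda_profile must align")
        if np.any(awc < 0):
            raise ValueError("negative layer AWC")
        if np.any(lam <= 0) or np.any(lam > 1):
            raise ValueError("lambda must lie in (0, 1]")
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("lambda must be non-increasing with depth")

    @property
    def n_layers(self) -> int:
        return self.awc_per_layer.size

    @property
    def total_awc(self) -> float:
        return float(self.awc_per_layer.sum())

    @property
    def layer_bottoms(self) -> np.ndarray:
        return self.layer_thickness * np.arange(1, self.n_layers + 1)


def _soil_from_dict(raw: dict) -> SoilProfile:
    n = int(raw["n_layers"])
    awc = np.full(n, float(raw["awc_total_mm"]) / n)
    lam = np.linspace(float(raw["lambda_surface"]), float(raw["lambda_bottom"]), n)
    return SoilProfile(
        layer_thickness=float(raw["layer_thickness_m"]),
        awc_per_layer=awc,
        lambda_profile=lam,
        max_root_depth=float(raw["max_root_depth_m"]),
    )


def load_soil(path) -> SoilProfile:
    """Load a soil profile file (same schema as the packaged default)."""
    with open(path) as fh:
        return _soil_from_dict(yaml.safe_load(fh))


def default_soil() -> SoilProfile:
    """The packaged default profile: 30 x 5 cm layers totalling 177 mm AWC."""
    raw = yaml.safe_load(
        (resources.files("droughtwheat") / "data" / "soil" / "default.yaml").read_text())
    return _soil_from_dict(raw)


@dataclass(frozen=True)
class ModelConstants:
    """Non-cultivar model constants (canopy, RUE, phenology, partitioning).

    Defaults encode the 2050 simulation set-up: reference CO2 350 ppm with a
    30% RUE gain per doubling, plus a 10% breeding/technology RUE uplift.
    """

    k: float = 0.45  # canopy extinction coefficient
    co2_ref: float = 350.0  # ppm, reference for the RUE-CO2 response
    rue_ref: float = 3.5  # g DM per MJ intercepted PAR at reference CO2
    rue_co2_slope: float = 0.30  # fractional RUE gain per CO2 doubling
    rue_uplift: float = 0.10  # 2050 technology uplift on RUE
    par_fraction: float = 0.5  # PAR fraction of global radiation
    t_base: float = 0.0  # deg C, base temperature for thermal time
    window_before: int = 10  # days before anthesis in the DSF window
    window_after: int = 5  # days from anthesis onward (anthesis day included)
    anthesis_lag_tt: float = 100.0  # deg C day, flag-leaf ligule to anthesis
    emergence_tt: float = 150.0  # deg C day, sowing to emergence
    fln_base: float = 9.5  # final leaf number under saturating daylength
    daylength_sat: float = 15.0  # h, daylength above which FLN stops rising
    plants_per_m2: float = 250.0  # canopy population scaling leaf areas to LAI
    sg_scale: float = 0.25  # leaf-lifespan gain per unit SG
    ear_partition: float = 0.30  # assimilate fraction to ear DM pre-anthesis
    ear_growth_tt: float = 300.0  # deg C day of ear growth before anthesis
    reserve_fraction: float = 0.25  # labile stem reserve fraction at anthesis
    reserve_withdrawal: float = 0.03  # fraction of anthesis reserve per day
    grain_partition: float = 0.90  # post-anthesis assimilate fraction to grain
    root_elongation: float = 0.0012  # m per deg C day
    pt_alpha: float = 1.26  # Priestley-Taylor coefficient
    rn_fraction: float = 0.55  # net radiation fraction of global radiation
    green_plateau: float = 0.7  # fraction of leaf lifespan at full greenness

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.window_before + self.window_after != 15:
            raise ValueError("the DSF window must span 15 days")
        for name in ("par_fraction", "ear_partition", "reserve_fraction",
                     "grain_partition", "rn_fraction", "green_plateau"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def window_days(self) -> int:
        return self.window_before + self.window_after


def load_cultivar(path_or_site: str) -> CultivarParams:
    """Load a cultivar parameter file, or a packaged ``<SITE>_initial`` set."""
    if len(path_or_site) == 2 and path_or_site.isupper():
        text = (resources.files("droughtwheat") / "data" / "cultivars"
                / f"{path_or_site}_initial.yaml").read_text()
    else:
        with open(path_or_site) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return CultivarParams(**{n: float(raw[n]) for n in PARAM_NAMES})


def initial_cultivars() -> dict[str, CultivarParams]:
    """All packaged per-site initial cultivar parameter sets."""
    out = {}
    for entry in (resources.files("droughtwheat") / "data" / "cultivars").iterdir():
        if entry.name.endswith("_initial.yaml"):
            sid = entry.name.split("_")[0]
            out[sid] = load_cultivar(sid)
    return out
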