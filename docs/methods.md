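# Methods

`droughtwheat` quantifies what tolerance to drought stress *during
reproductive development* is worth, in yield and yield stability, for wheat
ideotypes under a warm 2050-style climate at 13 contrasting European sites.
It couples three components: a daily process-based wheat simulator with an
explicit reproductive-stage grain-number mechanism, a stochastic daily
weather generator that emulates the 13 site climates, and a constrained
evolution strategy that optimizes eight cultivar parameters for 100-year
mean yield subject to a yield-variability cap.

## 1. Crop model

### Phenology

Development runs on thermal time `tt = max(0, (Tmin+Tmax)/2 − Tbase)` with
`Tbase = 0 °C`. Emergence occurs 150 °C d after sowing. At emergence the
final leaf number is fixed from the daylength response:

    FLN = fln_base + Pp · max(0, daylength_sat − daylength)

with `fln_base = 9.5`, `daylength_sat = 15 h`; shorter days at emergence add
leaves in proportion to the cultivar's daylength response `Pp`, delaying
anthesis. Vernalization is assumed fully satisfied (all 13 sites sow in
autumn or early winter); there is no explicit vernalization submodel.
Flag-leaf ligule appearance falls at `FLN · Ph` °C d after emergence
(`Ph` = phyllochron), anthesis 100 °C d later, and maturity after a further
`Gf` °C d of grain filling — or earlier if the canopy is fully senesced.

### Canopy

Each mainstem leaf is a canopy layer. Potential layer area ramps linearly
with leaf rank up to the flag-leaf area `A` (per plant; 250 plants m⁻²
converts to ground area), expanding over one phyllochron. Layer lifespans
are scheduled in thermal time so that, unstressed and without stay-green,
the flag leaf dies exactly when grain filling ends and lower leaves die
progressively earlier; a layer is fully green for the first 70 % of its
lifespan and fades linearly to zero over the remainder. Stay-green
multiplies every lifespan by `1 + 0.25·SG`. Water stress accelerates
senescence: the senescence clock advances by
`tt · (1 + (Wss − 1)(1 − SF))` — exactly `tt` when unstressed and `Wss·tt`
at full stress.

### Light, biomass and CO2

Interception follows the Beer law, `f_int = 1 − exp(−k·LAI)` with
`k = 0.45`. Daily biomass is intercepted PAR (half of global radiation)
times an effective radiation use efficiency

    RUE_eff = rue_ref · (1 + 0.30·(CO2/CO2_ref − 1)) · 1.10

with `rue_ref = 3.5 g DM MJ⁻¹ PAR` at `CO2_ref = 350 ppm`: a 30 % gain per
CO2 doubling and a 10 % technology uplift assumed for 2050. The scenario
concentration is 541 ppm. Under water stress, assimilation is multiplied by
`SF^Wsa`: a small exponent (`Wsa → 0.1`) is a weak response, i.e.
tolerance; `Wsa` absorbs the stress-response exponent as a cultivar
parameter, so lower optimized values mean flatter responses.

### Soil water and stress

The soil is a cascade of 30 × 5 cm layers totalling 177 mm of available
water, full at sowing. Precipitation cascades down the profile; the
overflow at the bottom is drainage. Daily uptake from each rooted layer is
`(Ru/100) · λ · available`, harvested top-down until the demand is met,
where `λ` is the relative extraction efficiency declining from 1.0 at the
surface to 0.9 at 1.5 m. *Note on the extraction scale:* with extraction
efficiencies in the conventional 0.02–0.08 per-day range this formula would
cap whole-profile uptake near 0.4 mm d⁻¹ and the crop would be permanently
and extremely stressed; `λ` here is therefore a relative (dimensionless)
efficiency near 1 and the rate is carried entirely by the cultivar's root
uptake parameter `Ru` (1–7 % d⁻¹), giving a full profile at `Ru = 3` about
5 mm d⁻¹ of supply. Roots elongate 1.2 mm per °C d until anthesis or 1.5 m.

Transpiration demand is Priestley–Taylor reference ET (α = 1.26, net
radiation taken as 0.55 of global radiation — no humidity or wind inputs
exist) times `f_int`; soil evaporation claims the complement `(1 − f_int)`,
throttled by the relative wetness of the top two layers. The daily stress
factor is `SF = Ta/Tp` (1 when there is no demand). Every flux is tracked
and the seasonal balance `initial + precip = final + Ta + evap + drainage`
closes to better than 10⁻⁶ mm (asserted in the test suite).

### Grain number under reproductive-stage drought

Ear dry matter `DM_ear` accumulates as 30 % of assimilation over the last
300 °C d before anthesis. The drought stress factor is

    DSF = Σ Ta / Σ Tp

over the 15-day window from 10 days before anthesis through 4 days after
(anthesis day included). The grain-number reduction factor is piecewise
linear in DSF:

    R = 0.2                          DSF ≤ 0.3   (saturated drought)
    R = 0.2 + (1−0.2)/(0.9−0.3)·(DSF−0.3)   0.3 < DSF < 0.9
    R = 1                            DSF ≥ 0.9   (no reduction)

continuous at both breakpoints. A *drought-tolerant* (DT) cultivar has
R ≡ 1; a *drought-sensitive* (DS) cultivar uses the response above. Grain
number is `N = DM_ear · Npot · R` with `Npot = 100 grains g⁻¹`, and the
grain sink capacity is `N · Wpot` with `Wpot = 50 mg`. Because everything
before the window close is identical for DS and DT, the per-year identity
`N_DS = R · N_DT` holds exactly, and DT yield dominates DS yield year by
year with equality exactly when `DSF ≥ 0.9`.

### Grain filling and yield

At anthesis a labile stem reserve of 25 % of shoot biomass is set aside;
it can be withdrawn at up to 3 % of its initial size per day. Daily grain
growth is `min(0.90 · assimilation + withdrawal, sink remaining)`. Yield is
grain mass at maturity (g m⁻² × 0.01 = t ha⁻¹); it can never exceed shoot
biomass (grain is part of it) nor the sink capacity. Zero radiation or
zero water produce zero yield without failure; a season in which the crop
never emerges returns a flagged zero-yield result.

## 2. Weather generator

The generator stands in for downscaled 2050 scenario files that cannot be
redistributed. Per site it produces seeded 365-day years (no leap days):

* **Occurrence** — first-order two-state Markov chain with monthly wet-day
  probabilities and persistence 0.30.
* **Amounts** — gamma (shape 0.75) with monthly scale.
* **Calibration by construction** — a winter-peaked seasonal shape
  (amplitude 0.15) is suppressed on warm months by
  `exp(−summer_dryness · w_m)` with weights rising from March (0.5)
  through May–July (1.0) and renormalized; monthly wet-day means are then
  solved so each month's expected total matches its target exactly, whatever
  the probability caps did. The annual total is preserved while June–July
  precipitation strictly decreases in the `summer_dryness` knob.
* **Temperature** — site mean + seasonal sinusoid (half-range 8–10 °C by
  latitude band, peak near day 200) + AR(1) anomaly (φ = 0.7, sd 2 °C);
  Tmin/Tmax from a diurnal range (mean 10 °C, reduced 25 % on wet days).
* **Radiation** — extraterrestrial radiation × transmissivity (0.72 dry /
  0.45 wet, ± noise), clipped to [0, 42] MJ m⁻² d⁻¹.

Over 100 years the realized annual means match every site's normals to
within 0.05 °C and 2 % of precipitation (tolerances 0.5 °C / 10 %). The
generator does **not** reproduce inter-annual regimes (blocking, NAO),
humidity, wind, spatial correlation, or precipitation extremes beyond the
gamma tail — so green tests establish that conclusions follow from the
*stated* climate normals and drought propensities, not that they would
survive every feature of real downscaled weather.

The per-site `summer_dryness` presets encode three scenario groups:
dry-south (Seville, Lleida: 4.0), wet-northwest (Toulouse, Vienna,
Rothamsted, Wageningen: 0.0) and intermediate (the rest: 0.3–1.0). They
were chosen once so that the reproductive windows of the southern sites are
drought-exposed and those of the north-west are not, mirroring the
qualitative site grouping of the study design, and were frozen before the
acceptance suite was written.

## 3. Ideotype optimizer

A (1 + 16) evolution strategy with log-normal step-size self-adaptation
(τ = 1/√16 = 0.25, initial σ = 10 % of each parameter range): each
generation 16 candidates are drawn as
`σ′ = σ·exp(τ·N(0,1))`, `x′ = clip(x + σ′·N(0,1), bounds)`; candidates
whose 100-year yield CV exceeds the limit (0.10, or 0.15 in the relaxed
variant) are excluded; the highest-mean-yield feasible candidate becomes
the next parent, with the incumbent retained when no offspring beats it
(ties keep the incumbent, then lowest index — selection is deterministic).
Exclusion applies to the incumbent too: if the *initial* cultivar violates
the CV cap, the first feasible offspring replaces it whatever its yield,
and while nothing is feasible the search selects the least-violating
candidate (lowest CV, ties by yield) — an approach phase that walks into
the feasible region instead of sitting on an infeasible incumbent.
Best-so-far is tracked over feasible candidates only, and the stagnation
contraction applies only to a feasible incumbent.
When the incumbent survives a generation its step sizes contract by 0.85
(a success-rule analogue), which sharpens final convergence. Stopping:
improvement below 0.01 t ha⁻¹ (configurable) for 30 consecutive
generations, or 500 generations, returning a non-converged flag.

Parameter bounds are the optimization ranges listed in
`droughtwheat.params.DEFAULT_BOUNDS` (Ph 80–130 °C d; Pp 0.05–0.70 leaf
h⁻¹; Gf 500–900 °C d; A 0.003–0.01 m² m⁻²; SG 0–1.5; Ru 1–7 % d⁻¹;
Wsa 0.1–2.1; Wss 1.2–1.9). On a separable concave test fitness the
optimizer recovers a 2001-point-per-axis grid-search argmax to well within
5 % of each range.

## 4. Experiment design

Per site, one weather realization is generated and shared by both
ideotypes; DS and DT are optimized from the same initial cultivar (the
packaged per-site "current variety" parameter sets) with the same optimizer
seed, so DT − DS differences are not search noise. The headline statistic
is `benefit % = 100·(DT − DS)/DS` on 100-year mean yields, plus the yield
CV contrast; cross-site averages are unweighted. The CV-limit sensitivity
re-runs both ideotypes with the cap at 0.15.

## 5. Numerical choices and degenerate inputs

* CV uses the sample standard deviation (ddof = 1); a zero-mean yield
  series gets CV = ∞ (never selected) unless all yields are zero.
* An n-year series yields n − 1 complete sowing-to-harvest seasons (the
  final year's sowing cannot be harvested); seasons are independent because
  the profile refills at sowing.
* `DSF = 1` when the window has no transpiration demand; grain filled
  provisionally (at R = 1) before the window closes is clamped back to the
  final sink, the excess returning to the stem reserve.
* If the canopy dies inside the window, the window closes at that day.
* Step sizes are bounded to [10⁻⁶, 1] × each parameter range.

## 6. Known limitations

* No nitrogen dynamics, no heat-stress-at-flowering effects, no
  pests/diseases, no tillering, no CO2 effect on transpiration efficiency —
  all outside scope by design.
* Absolute yield levels depend on partitioning constants (ear fraction
  0.30, grain fraction 0.90, reserve 0.25) chosen once so unstressed
  optimized yields land in a realistic 12–18 t ha⁻¹ band; site-specific
  absolute yields and benefit magnitudes are not reproduction targets,
  only directions, orderings and mechanism on/off contrasts are asserted.
* Northern late-flowering sites (Halle, Kaunas, Tylstrup) show large
  tolerance benefits because their anthesis windows fall in early summer;
  this is a genuine feature of the stated world (and was reported as a
  real surprise for Denmark), not a calibration target.
* In this synthetic world, full re-optimization of all eight parameters
  lets a drought-*sensitive* ideotype compensate almost completely at the
  representative sites (analysis driver 03): the optimizer pushes DS toward
  drought escape and avoidance — maximum root uptake rate (Ru → 7 % d⁻¹),
  a flat stress response (Wsa → 0.1) and a short early cycle — which is
  cheap here because the profile is full at sowing and springs are
  relatively wet. The tolerance benefit that is large for *current*
  cultivars (~20 % averaged over the 13 sites, CV reduced ~40 %) therefore
  shrinks toward zero for fully re-optimized ideotypes at desk scale.
  Residual negative "benefits" of a few percent in driver 03 are search
  noise of the scaled-down evolution strategy (25 years, ≤ 60 generations),
  visible as such because the relaxed-CV runs land DS and DT on identical
  optima.
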