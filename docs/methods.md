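# Methods

This note documents the models implemented in `ectogradient`, the
parameter choices that matter, what the synthetic data emulate (and do
not), and the numerical conventions, at the level of detail a user would
need to re-derive or challenge the results.

## Study design

The unit of simulation is one individual lizard at one site: a 16-year
hourly environmental series drives a behavioural model that picks a
microhabitat and body temperature every hour, and the body-temperature
series drives a standard Dynamic Energy Budget (DEB) model through the
whole life cycle, from an egg buried 5 cm below ground on day-of-year
140 to death.  The study grid crosses 15 sites (~240–1280 m a.s.l.,
five syntopic, five per single-species occurrence class) with two
species and two seasonal thermal-trait sets, giving 30 runs per set.
Six traits are extracted per run: egg development time (d), lifespan
(yr, post-hatch), number of calendar years with at least one clutch,
mean yearly basking and foraging hours over completed post-hatch years,
and mean yearly fecundity over the reproductive years.  The statistical
stage then regresses each trait on elevation, species and occurrence
class.

Every simulated year has 365 days (no leap days); day-of-year indexing
and the photoperiod calculations rely on this.  All temperatures are in
°C at module interfaces; Kelvin appears only inside the Arrhenius
factor.

## Synthetic microclimate generator

The generator replaces reanalysis-driven microclimate downscaling with
an additive parametric model per site:

* air temperature = sea-level mean (10.5 °C) + lapse × elevation
  (−0.0054 °C/m) + seasonal cosine (amplitude 10 °C, coldest
  mid-January) + diurnal cosine (amplitude 8 °C clear-sky, damped by
  cloud, warmest 14:00) + hourly AR(1) noise (φ = 0.8, innovation
  σ = 2 °C);
* shortwave radiation = 900 W m⁻² × sin(solar elevation) × (1 − 0.75 ×
  cloud), zero below the horizon, from the standard solar-declination
  geometry (δ = 23.45°·sin(2π(284+doy)/365)); cloud cover is a daily
  AR(1) process around 0.45.  Radiation carries no elevation term;
* relative humidity = 70 % + 0.015 %/m × elevation + a 5 % diurnal
  cycle peaking before dawn + noise, clamped to [0, 100];
* snow cover is a deterministic window over the coldest days of the
  seasonal cycle, sized so that snow-free days over the study's 16-year
  horizon decline with elevation at −1.053 d/m.  The per-year snow load
  is horizon-independent (the slope is expressed per the fixed 16-year
  reference), so short test runs behave sensibly.  Snow is a boolean
  occupancy: it gates surface activity and clamps the soil surface
  boundary to 0 °C; depth is not modelled.

Setting the AR(1) innovation σ to zero freezes all stochastic
components, including cloud; this single switch is what the
monotonicity property tests use.

Substrate temperature is a two-harmonic damped-conduction model.  The
forcing is the sun-exposed ground surface temperature, air + 0.035 °C
per W m⁻² of shortwave — bare ground under radiation runs well above
air temperature, and without this term 5-cm incubation is unreasonably
cold.  The (snow-masked) surface series is decomposed into an overall
mean, an annual harmonic, a slow day-to-day residual, per-day diurnal
harmonics and a fast intraday residual; at depth z the harmonics shrink
by exp(−z/D) and lag by z/D radians with D the diurnal (15 cm) or
annual (200 cm) damping depth, and the aperiodic residuals are damped
without lag in their frequency band.  At z = 0 the decomposition
reconstructs the forcing exactly.

What the generator does *not* emulate: wind (convection uses a fixed
1 m s⁻¹ default), soil moisture, terrain shading, cold-air drainage,
inter-annual climate trends, and weather covariance between sites.
Consequently, passing tests show that the pipeline recovers structure
the generator puts in (elevational slopes, snow season length, soil
damping) — they do not validate the generator against real weather.

## Operative temperature and behaviour

Operative temperature at shade fraction s:
`T_e = T_air + α(1−s)·Q / (h_c + 4σε T_air,K³)` with absorptivity
α = 0.9, a flat-plate forced-convection coefficient h_c from
Nu = 0.66·Re^0.5·Pr^(1/3) at 1 m s⁻¹ wind over a 6-cm animal
(h_c ≈ 16 W m⁻² K⁻¹), and a linearized radiative conductance
(ε = 0.95).  Evaporative and metabolic heat terms are omitted: for a
~5 g lizard they are small against the radiative and convective terms,
and the behavioural clamping to thermal thresholds absorbs most of the
residual error.  Body temperature equals the occupied option's
temperature (steady state — the thermal time constant of so small an
animal is far below the hourly step).

Microhabitat options each hour: ten surface positions (shade 0–0.9,
suppressed under snow) and eight retreat depths (0–200 cm).  The
decision tree: night → retreat; day with no surface option ≥ T_emerge →
cold-inactive in a retreat; otherwise select the surface option inside
[T_emerge, T_forage_max] closest to the seasonal T_pref — foraging if
above T_forage_min, basking below; if every emergence-capable option
overheats (> T_forage_max), move to the shallowest retreat within
[CT_min, T_forage_max].  Retreats target CT_min + 2 °C: an inactive
ectotherm conserves energy best just above its cold safety margin, and
this choice (rather than the warmest available retreat) is what lets
simulated lizards survive winter on their reserves.  Where no retreat
lies inside the critical band — deep soil at the highest sites sits
below CT_min in winter — the hour is flagged `lethal_exposure` but is
not lethal: the animals demonstrably overwinter at these sites, and
freeze tolerance is outside the model.  Ties between equally preferred
options break toward the lowest shade / shallowest depth.  Feeding
occurs if and only if the state is foraging.

The spring voluntary minimum for *I. horvathi* is read as 19.1 °C
(the source value is garbled); both species' seasonal threshold sets
are otherwise the measured values.

## Standard DEB model

Fluxes as in the README; the mobilization flux uses volume-specific
somatic maintenance, `p_C = E·TC·(E_G·v/L + p_M)/(E_G + κE/V)`, which
reproduces the standard closed forms (κp_C = p_S exactly at
L_∞ = κp_Am/p_M; von Bertalanffy growth at constant conditions).
A single Arrhenius factor corrects all rates (no high/low-temperature
enzyme deactivation: behavioural clamping to the CT limits would make
the five-parameter correction unidentifiable).  The ageing acceleration
h_a is corrected by TC², making a constant-temperature trajectory an
exact time rescaling of the reference trajectory (so lifespan at T is
lifespan at T_ref divided by TC).

Stages: embryo below E_Hb (no feeding — the embryo runs down its
initial reserve E_0), juvenile to E_Hp, then adult (maturation flux
diverted to the reproduction buffer with efficiency κ_R = 0.95).
E_0 is computed per species by bisection on the standard
initial-reserve condition (hatchling born at scaled reserve density
e = 1) and cached.

Starvation: when κp_C < p_S the κ-rule is suspended — mobilized reserve
pays somatic maintenance first and growth stops; any residual deficit
is paid from the reproduction buffer, then by catabolizing structure
(energy yield E_G per cm³); death occurs when structure falls below
70 % of its attained peak, or when the reserve itself is exhausted.
Maturity is never drained; an unpayable maturity-maintenance flux
stalls maturation for that step.  A harsher rule — death as soon as the
buffer is empty — kills every juvenile in its first winter under this
climate, which contradicts the observed multi-year field life
histories; the shrinkage rule is the standard starvation continuation
and the 70 % threshold is conservative (winter shrinkage in the
simulations is ~1 %).

Death by ageing uses the median-survival convention: the first time the
Weibull/Gompertz survival probability S drops below 0.5 (threshold
configurable).  If neither death mode triggers before the horizon ends,
lifespan is censored at the horizon; with a 16-year horizon chosen to
exceed the maximum known lifespans, censoring is rare and confined to
the coldest runs.  Lifespan is counted post-hatch.

Clutches: once per day at local noon, inside the photoperiod window
(opening at 12.6 h on the ascending limb — doy ≈ 92 at these latitudes —
and closing at 14 h on the descending limb, doy ≈ 226 under the
no-refraction daylength used throughout), with a 30-day refractory
period.  Candidate clutch size is round-half-away(a + b·SVL_mm) — with
documented placeholder coefficients (a, b) = (−2.0, 0.12) for
*P. muralis* and (−1.5, 0.10) for *I. horvathi* — capped at five eggs
and by the buffer's energy content at a cost of E_0/κ_R per egg (so the
buffer never goes negative).  SVL is 10·L/δ_M mm with shape coefficient
δ_M = 0.2.

### Species parameter defaults

The published core parameter tables for these species are not shipped;
the defaults are calibrated placeholders and are expected to be
replaced via the species JSON interface.  Calibration anchors, applied
once: ultimate SVL ~66 mm / ~60 mm (sets κ·p_Am/p_M); hatchling SVL
25 mm / 24 mm (sets E_Hb); lifespan 10 y / 9 y at the 20 °C reference
(sets h_a); and *field* maturation roughly a season earlier in
*P. muralis* than *I. horvathi* (sets E_Hp against whole-life
simulations at a mid-elevation site, because maturation in a thermally
constrained field year is much slower than at a constant 20 °C).
κ = 0.65 and k_J = 5×10⁻⁴ d⁻¹ leave a reproductive surplus of a few
eggs per year at low elevation, declining with altitude; the highland
species carries slightly higher volume-specific maintenance, consistent
with its higher measured metabolic potential.  v = 0.015 cm d⁻¹ trades
embryo speed against winter reserve persistence: higher conductance
hatches eggs faster but drains reserve faster through hibernation.

## Covariation estimation

Zero-variate predictions at a datum temperature run the same
integration kernel at constant T and f = 1 (embryo run for birth
quantities; juvenile/adult run for puberty and lifespan; closed forms
for ultimate size, weight and the reproduction rate at ultimate size),
exploiting the exact TC time rescaling.  The loss is the weighted
symmetric form Σ wᵢ(predᵢ−obsᵢ)²/(predᵢ²+obsᵢ²); MRE and SMSE are the
reported goodness-of-fit statistics.  Nelder–Mead searches log-space
(logit for κ) over the default free set {p_Am, v, κ, p_M, E_Hb, E_Hp,
h_a}; E_G, k_J, T_A, δ_M, κ_R stay fixed.  Non-viable proposals (no
hatch, no puberty within 50 y, no ageing death within 50 y, no
reproductive surplus) score +∞.  The optimizer is deterministic given
the initial point.  Pseudo-data assembled from the reported life
histories put weight 5 on the maturity-age and lifespan anchors and 1
on size/reproduction anchors, at a 20 °C field-active datum
temperature; both weights and temperature are configuration, since
neither is pinned down by the source material.

## Statistics

`fit_ols` solves the normal equations directly and reports
t-distribution p-values; AICc = n·log(rss/n) + 2k + 2k(k+1)/(n−k−1)
with k counting the error variance (coefficients + 1).  Model
simplification keeps the fuller model only when it improves AICc by
more than 2; ties and small gains go to the simpler model, and the
decision is invariant to argument order.  Treatment (dummy) coding uses
the first level in sorted order as reference — for the study grid that
is *I. horvathi* for species and `allotopy_horvathi` for location type.
Tukey–Kramer contrasts are computed from the dummy coefficients of
models additive in the factor, with p-values from the studentized-range
distribution at the model's residual degrees of freedom (for a
balanced one-way layout this reduces exactly to the classical q test).
Diagnostics: Shapiro–Wilk on residuals, Breusch–Pagan against the
design matrix, Q–Q coordinates with the (i−0.375)/(n+0.25) plotting
positions; skipped with a warning below n = 8.  NA trait rows (e.g.
non-viable eggs) are dropped listwise before the design matrix is
built.

## Numerical conventions

Integration is hourly explicit Euler with automatic sub-stepping
whenever the projected relative change of reserve or structure exceeds
1 % (embryos start at V = 10⁻⁶ cm³, where sub-stepping is essential);
the hourly kernel agrees with a dt = 10⁻³ d integrator to better than
1 % on embryo development and puberty timing.  The embryo has a 2-year
guard: eggs that have not hatched by then are recorded as non-viable
and produce a flagged NA trait row rather than aborting the study run.
All randomness flows from a single study seed through per-site
`SeedSequence` spawns; equal configurations give bit-identical trait
tables.  Simulation sizes in the test suite are scaled to the check at
hand (1–4 year horizons for behavioural and gradient properties, the
full 16-year grid for the end-to-end shape, slope-recovery and
sign checks).

## Known limitations

* The weather generator's realism is parametric, not meteorological;
  its slopes are inputs, so slope-recovery results are consistency
  checks of the pipeline, not validation against nature.
* Species DEB cores are calibrated placeholders; absolute trait values
  (particularly fecundity, which is energy-limited under these
  parameters at ~1–2 eggs per reproductive year) should be read as
  qualitative until fitted to real entries via the estimation module.
* Single individuals only: no population dynamics, density dependence,
  predation risk or interspecific interference.
* No hydration budget; humidity influences nothing downstream of the
  microclimate statistics.
* Thermal inertia, posture and substrate conduction are collapsed into
  the steady-state operative temperature.
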