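# ectogradient

Mechanistic life-history modelling of two elevationally segregated
lacertid lizards — the lowland common wall lizard (*Podarcis muralis*)
and the highland Horvath's rock lizard (*Iberolacerta horvathi*) — across
a gradient of 15 field sites (~240–1280 m a.s.l.) in the northern Dinaric
Mountains.  The package is aimed at ecophysiologists who want a
desk-scale, fully reproducible version of the microclimate → biophysics →
energy-budget → statistics modelling chain used to study how abiotic
conditions shape life histories and, through them, patterns of syntopy
and allotopy.

The pipeline has four stages:

1. **Synthetic microclimates** (`microclimate`): hourly air temperature,
   solar radiation, relative humidity, snow cover and a substrate
   temperature-depth profile for each site, generated by a parametric
   stochastic weather model whose elevation structure (lapse rate
   −0.0054 °C/m, humidity slope +0.015 %/m, longer snow season at
   altitude, no elevation trend in radiation) is what the statistical
   stage is designed to detect.
2. **Behavioural thermoregulation** (`behavior`): hourly operative
   temperatures across shade levels (0–90 %) and retreat depths, and a
   heliotherm decision tree — diurnal activity only, emergence above
   T_emerge, shade selection targeting the seasonal preferred temperature
   T_pref, foraging only inside the voluntary band
   [T_forage_min, T_forage_max], overheating avoided in shallow shelters,
   snow suppressing surface activity.
3. **Dynamic Energy Budget life cycle** (`deb`, `lifecycle`): the
   standard DEB model drives growth, maturation, reproduction, ageing and
   starvation from the behaviourally selected body temperatures (feeding
   only while foraging); an egg buried 5 cm below ground on day-of-year
   140 starts each 16-year simulation.  Six life-history traits are
   extracted per site × species × seasonal thermal set.
4. **Gradient statistics** (`stats`): OLS models
   `trait ~ elevation × species × location type` with AICc-based
   simplification (ΔAICc > 2 favours the simpler model), Tukey–Kramer
   post-hoc contrasts on location type, and residual diagnostics.

A fifth component (`estimation`) implements the DEB covariation method:
core parameters are fitted to zero-variate life-history data (ages,
sizes, lifespan, reproduction rate) by minimizing the weighted symmetric
loss Σ wᵢ(predᵢ−obsᵢ)²/(predᵢ²+obsᵢ²) with Nelder–Mead in transformed
parameter space, and the fit is scored by the mean relative error (MRE)
and symmetric mean squared error (SMSE).

## The model core

Standard DEB state variables: reserve `E` (J), structure `V` (cm³),
maturity `E_H` (J) and reproduction buffer `E_R` (J).  With
`L = V^(1/3)` and temperature correction
`TC = exp(T_A/T_ref − T_A/T_body)`,

```
p_A = TC · p_Am · f · L²                      assimilation (0 for embryos)
p_C = E · TC · (E_G·v/L + p_M) / (E_G + κE/V) mobilization
p_S = TC · p_M · V                            somatic maintenance
p_J = TC · k_J · E_H                          maturity maintenance
p_G = κ·p_C − p_S                             growth
p_R = (1−κ)·p_C − p_J                         maturation / reproduction
```

The κ-rule gives `p_C = p_G + p_S + p_J + p_R` identically.  Ultimate
length is `L_∞ = κ·p_Am/p_M`; at constant temperature and `f = 1` growth
follows von Bertalanffy with rate `r_B = p_M / 3(κE_m + E_G)`.  Ageing
follows the Weibull/Gompertz construction (`h_a`, `s_G`); death occurs
when survival drops below 0.5, or by starvation once reserve, buffer and
a tolerable fraction of structure are exhausted.  Clutches convert the
buffer into eggs (cost `E_0/κ_R` each) through a linear SVL rule capped
at five eggs, inside a photoperiod-bounded season (daylength rising
through 12.6 h to falling past 14 h).

## Worked example

```python
from ectogradient import StudyConfig, load_sites, run_study
from ectogradient.species import default_species

cfg = StudyConfig()          # 16 years, egg laid on doy 140 at 5 cm depth
table = run_study(load_sites(), default_species(), cfg,
                  season_sets=("spring",))
print(table.iloc[0])
```

prints (site 1 of 30 rows — Bilpa, 238 m, syntopic, spring thermal set):

```
site                       Bilpa
species               P. muralis
season_set                spring
occurrence               syntopy
elevation                  238.0
egg_dev_days           59.666667
lifespan_years          7.660959
reproductive_years           5.0
yearly_bask_h          47.142857
yearly_forage_h      2820.428571
yearly_fecundity             1.6
viable                      True
```

i.e. at the warmest site the wall lizard's egg hatches after ~60 days,
the animal lives ~7.7 years, reproduces in 5 calendar years at ~1.6 eggs
per reproductive year, and spends ~2820 h/yr foraging but only ~47 h/yr
basking (its 17.8 °C emergence threshold is rarely the binding
constraint at low elevation).  Across the grid, egg development time and
lifespan increase with elevation while activity and fecundity decrease,
and the lower emergence threshold of *I. horvathi* (15.6 °C) buys it far
more basking time (~400 h/yr) than *P. muralis*.

The same pipeline is scriptable from the shell:

```
ectogradient simulate --config cfg.yaml --out traits.csv
ectogradient estimate --data pseudo.csv --out params.json
ectogradient compare  --traits traits.csv --out stats.json
```

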