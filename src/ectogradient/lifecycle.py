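"""Whole life-cycle coupling: microclimate → behaviour → DEB → traits.

One simulated individual per site × species × seasonal parameter set: the
egg is buried at the configured depth on the configured day of year of
year 1; after hatching the hourly loop takes the behavioural decision,
uses the resulting body temperature to drive the DEB state (feeding, and
hence f = 1, only during foraging hours), checks clutch production once a
day at local noon inside the photoperiod-bounded reproductive window, and
terminates at death or at the end of the horizon.

Six life-history traits are extracted per run: egg development time,
lifespan (post-hatch, censored at the horizon if the survival criterion
never triggers), number of reproductive calendar years, mean yearly
basking and foraging hours over completed post-hatch years, and mean
yearly fecundity over the reproductive years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .behavior import ActivityState, BehaviorParams, decide_hours
from .config import DAYS_PER_YEAR, HOURS_PER_DAY, SiteSpec, StudyConfig, site_seed_sequences
from .deb import ClutchRule, DEBParams
from .microclimate import MicroclimateSeries, WeatherGenParams, generate_site_weather, photoperiod, soil_profile

HOURS_PER_YEAR = DAYS_PER_YEAR * HOURS_PER_DAY

#: minimum days between successive clutches
CLUTCH_REFRACTORY_DAYS = 30

TRAIT_COLUMNS = [
    "egg_dev_days",
    "lifespan_years",
    "reproductive_years",
    "yearly_bask_h",
    "yearly_forage_h",
    "yearly_fecundity",
]


class LifecycleError(ValueError):
    pass


@dataclass
class LifeHistoryTraits:
    site: str
    species: str
    season_set: str
    occurrence: str
    elevation: float
    egg_dev_days: float
    lifespan_years: float
    reproductive_years: float
    yearly_bask_h: float
    yearly_forage_h: float
    yearly_fecundity: float
    viable: bool = True


@dataclass
class SimulationLog:
    """Hourly records plus the event list of one individual's run."""

    site: SiteSpec
    species: str
    season_set: str
    n_hours: int
    state: np.ndarray          # ActivityState codes, hourly
    T_body: np.ndarray
    feeding: np.ndarray
    events: dict               # hatch/puberty/death indices, clutches, cause

    def completed_years_post_hatch(self) -> int:
        hatch = self.events["hatch_idx"]
        end = self.events["death_idx"]
        if end < 0:
            end = self.n_hours
        return (end - hatch) // HOURS_PER_YEAR


def reproductive_window(lat: float, cfg: StudyConfig) -> tuple[int, int]:
    """Day-of-year bounds of the photoperiod-gated reproductive season.

    Opens on the first day of the ascending limb whose daylength reaches
    the opening threshold (default 12.6 h, late March) and closes on the
    last day of the descending limb still at or above the closing
    threshold (default 14 h, early September).
    """
    doys = np.arange(1, DAYS_PER_YEAR + 1)
    dl = photoperiod(lat, doys)
    peak = int(doys[np.argmax(dl)])
    ascending = doys[(doys <= peak) & (dl >= cfg.repro_photoperiod_open)]
    descending = doys[(doys >= peak) & (dl >= cfg.repro_photoperiod_close)]
    if ascending.size == 0 or descending.size == 0:
        raise LifecycleError(
            f"photoperiod thresholds unreachable at latitude {lat}"
        )
    return int(ascending[0]), int(descending[-1])


def _na_traits(site: SiteSpec, species: str, season_set: str) -> LifeHistoryTraits:
    nan = float("nan")
    return LifeHistoryTraits(
        site=site.name, species=species, season_set=season_set,
        occurrence=site.occurrence, elevation=site.elevation,
        egg_dev_days=nan, lifespan_years=nan, reproductive_years=nan,
        yearly_bask_h=nan, yearly_forage_h=nan, yearly_fecundity=nan,
        viable=False,
    )


def run_individual(
    site: SiteSpec,
    micro: MicroclimateSeries,
    deb: DEBParams,
    beh: BehaviorParams,
    cfg: StudyConfig,
    clutch_rule: ClutchRule,
    species: str = "species",
    gp: WeatherGenParams | None = None,
    decisions: dict | None = None,
) -> tuple[SimulationLog, LifeHistoryTraits]:
    """Simulate one individual's full life cycle at one site.

    ``decisions`` may carry precomputed behavioural arrays (they do not
    depend on the DEB state) to avoid recomputation across season sets.
    """
    if micro.n_years < cfg.n_years:
        raise LifecycleError("microclimate horizon shorter than configured run")
    deb = deb.with_egg_energy()
    pv = deb.to_vector()
    n = micro.n_hours

    if decisions is None:
        decisions = decide_hours(micro, beh, cfg.season_set, cfg)

    # --- embryo at egg depth -------------------------------------------------
    if any(np.isclose(micro.depths, cfg.egg_depth)):
        egg_T = micro.soil_at(cfg.egg_depth)
    else:
        egg_T = soil_profile(micro.air_T, micro.snow, [cfg.egg_depth],
                             gp or WeatherGenParams())[0]
    start_idx = (int(cfg.start_doy) - 1) * HOURS_PER_DAY
    guard_steps = 2 * 365 * HOURS_PER_DAY
    status, steps, hatchling = K.run_embryo(
        egg_T[start_idx:], pv, 1.0 / HOURS_PER_DAY, guard_steps
    )
    events: dict = {"start_idx": start_idx}
    if status != 0:
        events.update(hatch_idx=-1, death_idx=-1, puberty_idx=-1,
                      clutches=[], death_cause="non_viable_egg")
        log = SimulationLog(site, species, cfg.season_set, n,
                            decisions["state"], decisions["T_body"],
                            decisions["feeding"], events)
        return log, _na_traits(site, species, cfg.season_set)
    hatch_idx = start_idx + steps
    egg_dev_days = steps / HOURS_PER_DAY

    # --- post-hatch hourly loop ---------------------------------------------
    open_doy, close_doy = reproductive_window(site.lat, cfg)
    clutch_check = (
        (micro.hour == 12) & (micro.doy >= open_doy) & (micro.doy <= close_doy)
    )
    death_idx, cause, puberty_idx, c_hours, c_sizes, n_clutch = K.run_life(
        decisions["T_body"],
        decisions["feeding"],
        clutch_check,
        pv,
        clutch_rule.a,
        clutch_rule.b,
        float(clutch_rule.cap_eggs),
        CLUTCH_REFRACTORY_DAYS * HOURS_PER_DAY,
        hatch_idx,
        hatchling,
        1.0 / HOURS_PER_DAY,
    )
    clutches = [
        {"hour_idx": int(c_hours[i]), "eggs": int(c_sizes[i]),
         "year": int(c_hours[i] // HOURS_PER_YEAR)}
        for i in range(n_clutch)
    ]
    events.update(
        hatch_idx=int(hatch_idx),
        egg_dev_days=float(egg_dev_days),
        puberty_idx=int(puberty_idx),
        death_idx=int(death_idx),
        death_cause={K.ALIVE: "horizon", K.DEAD_STARVATION: "starvation",
                     K.DEAD_AGEING: "ageing"}[cause],
        clutches=clutches,
    )
    log = SimulationLog(site, species, cfg.season_set, n,
                        decisions["state"], decisions["T_body"],
                        decisions["feeding"], events)
    return log, extract_traits(log, cfg)


def extract_traits(log: SimulationLog, cfg: StudyConfig) -> LifeHistoryTraits:
    """Reduce a simulation log to the six life-history traits."""
    ev = log.events
    if ev.get("hatch_idx", -1) < 0:
        raise LifecycleError("missing hatch event in log")
    hatch = ev["hatch_idx"]
    death = ev["death_idx"] if ev["death_idx"] >= 0 else log.n_hours
    lifespan_years = (death - hatch) / HOURS_PER_YEAR

    # clutch years are calendar years of the simulation
    eggs_by_year: dict[int, int] = {}
    for c in ev["clutches"]:
        eggs_by_year[c["year"]] = eggs_by_year.get(c["year"], 0) + c["eggs"]
    reproductive_years = len(eggs_by_year)
    total_eggs = sum(eggs_by_year.values())
    yearly_fecundity = total_eggs / reproductive_years if reproductive_years else 0.0

    n_completed = (death - hatch) // HOURS_PER_YEAR
    if n_completed >= 1:
        span = log.state[hatch : hatch + n_completed * HOURS_PER_YEAR]
        bask = float(np.count_nonzero(span == ActivityState.BASKING)) / n_completed
        forage = float(np.count_nonzero(span == ActivityState.FORAGING)) / n_completed
    else:
        bask = forage = 0.0

    return LifeHistoryTraits(
        site=log.site.name,
        species=log.species,
        season_set=log.season_set,
        occurrence=log.site.occurrence,
        elevation=log.site.elevation,
        egg_dev_days=float(ev["egg_dev_days"]),
        lifespan_years=float(lifespan_years),
        reproductive_years=float(reproductive_years),
        yearly_bask_h=bask,
        yearly_forage_h=forage,
        yearly_fecundity=float(yearly_fecundity),
        viable=True,
    )


def run_study(
    sites: list[SiteSpec],
    species_configs: dict,
    cfg: StudyConfig,
    seed: int | None = None,
    gp: WeatherGenParams | None = None,
    season_sets: tuple = ("spring", "summer"),
) -> pd.DataFrame:
    """Run the full site × species × season grid and return the trait table.

    ``species_configs`` maps species name → object with ``deb``,
    ``behavior`` and ``clutch_rule`` attributes (see
    :mod:`ectogradient.species`).  Site weather is generated once per site
    (one independent seed stream per site, spawned from the study seed)
    and shared across species and season sets.
    """
    if len(sites) == 0:
        raise LifecycleError("need at least one site")
    names = [s.name for s in sites]
    if len(set(names)) != len(names):
        raise LifecycleError("duplicate site names")
    gp = gp or WeatherGenParams()
    seed = cfg.rng_seed if seed is None else seed
    seqs = site_seed_sequences(seed, len(sites))

    rows = []
    for site, seq in zip(sites, seqs):
        micro = generate_site_weather(site, gp, cfg, seq)
        for sp_name, sp in species_configs.items():
            for season in season_sets:
                run_cfg = cfg if cfg.season_set == season else _with_season(cfg, season)
                decisions = decide_hours(micro, sp.behavior, season, run_cfg)
                _, traits = run_individual(
                    site, micro, sp.deb, sp.behavior, run_cfg,
                    sp.clutch_rule, species=sp_name, gp=gp, decisions=decisions,
                )
                rows.append(traits)
    df = pd.DataFrame([t.__dict__ for t in rows])
    ordered = ["site", "species", "season_set", "occurrence", "elevation"] + TRAIT_COLUMNS + ["viable"]
    return df[ordered]


def _with_season(cfg: StudyConfig, season: str) -> StudyConfig:
    from dataclasses import replace

    return replace(cfg, season_set=season)
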