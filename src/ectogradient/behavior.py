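"""Operative temperatures and behavioural thermoregulation rules.

Each hour the lizard can occupy one of a discrete set of microhabitats:
surface positions at shade fractions between 0 and 0.9, or substrate
retreats at the configured depths.  Operative (steady-state body)
temperature at the surface combines air temperature with absorbed
shortwave radiation balanced against convective and linearized radiative
losses; for these small-bodied animals (thermal time constant well under
an hour) body temperature is taken equal to the occupied microhabitat's
operative temperature.

The decision tree follows the heliotherm activity rules: strictly diurnal
activity, emergence once any surface option reaches T_emerge, shade
selection targeting the seasonal preferred temperature T_pref, foraging
only within the voluntary thermal band [T_forage_min, T_forage_max],
overheating avoided in the shallowest tolerable retreat, and snow
suppressing all surface activity.  Feeding happens if and only if the
animal forages.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .microclimate import MicroclimateSeries

STEFAN_BOLTZMANN = 5.670374419e-8  # W m^-2 K^-4
EMISSIVITY = 0.95
AIR_CONDUCTIVITY = 0.0257          # W m^-1 K^-1
AIR_KINEMATIC_VISCOSITY = 1.5e-5   # m^2 s^-1
PRANDTL = 0.71
#: retreat temperature targeted when inactive: just above the cold limit,
#: minimizing maintenance costs while staying out of the danger zone
RETREAT_MARGIN_C = 2.0
_FAR = 1e6


class BehaviorError(ValueError):
    pass


class ActivityState(IntEnum):
    NOCTURNAL_RETREAT = 0
    INACTIVE_COLD = 1
    BASKING = 2
    FORAGING = 3
    SHELTER_HEAT = 4


@dataclass(frozen=True)
class BehaviorParams:
    """Species thermal-behaviour thresholds (°C) with seasonal sets.

    ``T_forage_min``, ``T_forage_max`` and ``T_pref`` are mappings with
    keys ``spring`` and ``summer``.  The chain
    CT_min < T_emerge <= T_forage_min < T_pref < T_forage_max < CT_max
    must hold for each season.
    """

    T_emerge: float
    T_forage_min: dict
    T_forage_max: dict
    T_pref: dict
    CT_min: float
    CT_max: float
    absorptivity: float = 0.9
    char_dim: float = 0.06       # m, characteristic dimension
    wind_default: float = 1.0    # m s^-1

    def __post_init__(self) -> None:
        for season in self.T_pref:
            chain = (
                self.CT_min,
                self.T_emerge,
                self.T_forage_min[season],
                self.T_pref[season],
                self.T_forage_max[season],
                self.CT_max,
            )
            if not (chain[0] < chain[1] <= chain[2] < chain[3] < chain[4] < chain[5]):
                raise BehaviorError(
                    f"threshold chain violated for season {season!r}: {chain}"
                )


@dataclass
class HourDecision:
    state: ActivityState
    T_body: float
    microhabitat: tuple  # ("shade", fraction) or ("depth", cm)
    feeding: bool
    lethal_exposure: bool = False


def convective_coefficient(bp: BehaviorParams) -> float:
    """Flat-plate forced-convection coefficient h_c (W m^-2 K^-1)."""
    re = bp.wind_default * bp.char_dim / AIR_KINEMATIC_VISCOSITY
    nu = 0.66 * np.sqrt(re) * PRANDTL ** (1.0 / 3.0)
    return AIR_CONDUCTIVITY * nu / bp.char_dim


def operative_temperature(air_T, solar, shade, bp: BehaviorParams):
    """Steady-state operative temperature (°C) at a shade fraction.

    T_e = T_air + α(1−shade)·Q / (h_c + 4σε T_air,K³); equals air
    temperature when there is no shortwave load and decreases strictly
    with shade when there is.
    """
    shade_arr = np.asarray(shade, dtype=float)
    if np.any(shade_arr < 0.0) or np.any(shade_arr > 0.9):
        raise BehaviorError("shade must lie in [0, 0.9]")
    air = np.asarray(air_T, dtype=float)
    h_c = convective_coefficient(bp)
    h_r = 4.0 * STEFAN_BOLTZMANN * EMISSIVITY * (air + 273.15) ** 3
    out = air + bp.absorptivity * (1.0 - shade_arr) * np.asarray(solar, float) / (h_c + h_r)
    if out.ndim == 0:
        return float(out)
    return out


def season_of(doy: int, season_mode: str) -> str:
    """Season governing the thermal thresholds.

    ``spring_run`` / ``summer_run`` reproduce the whole-run seasonal sets;
    ``switching`` flips from spring to summer at the summer solstice.
    """
    if season_mode == "spring_run":
        return "spring"
    if season_mode == "summer_run":
        return "summer"
    if season_mode == "switching":
        return "spring" if doy < 172 else "summer"
    raise BehaviorError(f"unknown season_mode {season_mode!r}")


def enumerate_microhabitats(hour_env: dict, cfg, bp: BehaviorParams) -> list[tuple]:
    """All microhabitat options for one hour as (kind, value, T_body).

    Surface options (one per shade level) are suppressed while snow is
    present; retreat options are the substrate temperatures on the depth
    grid.  Body temperature equals the option temperature (small-body
    steady state).
    """
    if len(cfg.depth_grid) == 0:
        raise BehaviorError("empty depth grid")
    soil = hour_env["soil_T"]
    if len(soil) != len(cfg.depth_grid):
        raise BehaviorError("soil profile does not match depth grid")
    options: list[tuple] = []
    if not hour_env.get("snow", False):
        for s in cfg.shade_levels:
            options.append(
                ("shade", s, operative_temperature(hour_env["air_T"], hour_env["solar"], s, bp))
            )
    for d, T in zip(cfg.depth_grid, soil):
        options.append(("depth", d, float(T)))
    return options


def _retreat_choice(options, bp: BehaviorParams):
    """Retreat minimizing |T − (CT_min + margin)| within the CT band.

    If no depth lies within the critical band, the depth closest to the
    band is taken and the choice is flagged as lethal exposure.
    """
    target = bp.CT_min + RETREAT_MARGIN_C
    best = None
    best_key = np.inf
    lethal = True
    for kind, value, T in options:
        if kind != "depth":
            continue
        in_band = bp.CT_min <= T <= bp.CT_max
        if in_band:
            lethal_here = False
            key = abs(T - target)
        else:
            lethal_here = True
            key = _FAR + min(abs(T - bp.CT_min), abs(T - bp.CT_max))
        if key < best_key:
            best_key = key
            best = (kind, value, T)
        if in_band:
            lethal = False
    return best, lethal


def select_microhabitat(
    options: list[tuple],
    bp: BehaviorParams,
    season: str,
    is_day: bool,
) -> HourDecision:
    """Pick the hour's microhabitat following the activity decision tree."""
    if not options:
        raise BehaviorError("options must be non-empty")
    t_pref = bp.T_pref[season]
    t_fmin = bp.T_forage_min[season]
    t_fmax = bp.T_forage_max[season]

    surface = [o for o in options if o[0] == "shade"]

    if not is_day:
        best, lethal = _retreat_choice(options, bp)
        return HourDecision(ActivityState.NOCTURNAL_RETREAT, best[2], best[:2], False, lethal)

    emergeable = [o for o in surface if o[2] >= bp.T_emerge]
    if not emergeable:
        best, lethal = _retreat_choice(options, bp)
        return HourDecision(ActivityState.INACTIVE_COLD, best[2], best[:2], False, lethal)

    eligible = [o for o in emergeable if o[2] <= t_fmax]
    if eligible:
        best = min(eligible, key=lambda o: (abs(o[2] - t_pref), o[1]))
        state = (
            ActivityState.FORAGING if best[2] >= t_fmin else ActivityState.BASKING
        )
        return HourDecision(state, best[2], best[:2], state == ActivityState.FORAGING)

    # surface accessible but everywhere too hot: shallowest tolerable shelter
    shelter = None
    for kind, value, T in options:
        if kind == "depth" and bp.CT_min <= T <= t_fmax:
            shelter = (kind, value, T)
            break
    if shelter is not None:
        return HourDecision(ActivityState.SHELTER_HEAT, shelter[2], shelter[:2], False)
    best, lethal = _retreat_choice(options, bp)
    return HourDecision(ActivityState.SHELTER_HEAT, best[2], best[:2], False, lethal)


def decide_hours(series: MicroclimateSeries, bp: BehaviorParams, season: str, cfg):
    """Vectorized hourly decisions over a whole microclimate series.

    Returns a dict of aligned arrays: ``state`` (ActivityState codes),
    ``T_body`` (°C), ``feeding`` (bool), ``lethal`` (bool),
    ``microhabitat_kind`` (0 = shade, 1 = depth) and ``microhabitat_value``.
    Equivalent, hour for hour, to :func:`select_microhabitat` on the
    enumerated options (property-tested).
    """
    n = series.n_hours
    shades = np.asarray(cfg.shade_levels, dtype=float)
    depths = series.depths
    soil = series.soil_T
    t_pref = bp.T_pref[season]
    t_fmin = bp.T_forage_min[season]
    t_fmax = bp.T_forage_max[season]
    target = bp.CT_min + RETREAT_MARGIN_C

    is_day = series.solar > 0.0

    h_c = convective_coefficient(bp)
    h_r = 4.0 * STEFAN_BOLTZMANN * EMISSIVITY * (series.air_T + 273.15) ** 3
    Te = series.air_T[None, :] + (
        bp.absorptivity * (1.0 - shades)[:, None] * series.solar[None, :] / (h_c + h_r)[None, :]
    )  # (n_shades, n)

    surface_ok = is_day & ~series.snow
    emergeable = (Te >= bp.T_emerge) & surface_ok[None, :]
    eligible = emergeable & (Te <= t_fmax)
    any_emerge = emergeable.any(axis=0)
    any_elig = eligible.any(axis=0)

    pref_key = np.where(eligible, np.abs(Te - t_pref), np.inf)
    sel_shade = np.argmin(pref_key, axis=0)  # first (lowest shade) wins ties
    T_active = Te[sel_shade, np.arange(n)]

    in_band = (soil >= bp.CT_min) & (soil <= bp.CT_max)
    band_dist = np.minimum(np.abs(soil - bp.CT_min), np.abs(soil - bp.CT_max))
    ret_key = np.where(in_band, np.abs(soil - target), _FAR + band_dist)
    sel_depth = np.argmin(ret_key, axis=0)  # shallowest wins ties
    T_retreat = soil[sel_depth, np.arange(n)]
    lethal_ret = ~in_band.any(axis=0)

    shelter_mask = in_band & (soil <= t_fmax)
    has_shelter = shelter_mask.any(axis=0)
    sel_shelter = np.argmax(shelter_mask, axis=0)  # shallowest tolerable
    T_shelter = np.where(
        has_shelter, soil[sel_shelter, np.arange(n)], T_retreat
    )

    state = np.empty(n, dtype=np.int8)
    T_body = np.empty(n)
    mh_kind = np.empty(n, dtype=np.int8)
    mh_value = np.empty(n)
    lethal = np.zeros(n, dtype=bool)

    night = ~is_day
    cold = is_day & ~any_emerge
    hot = is_day & any_emerge & ~any_elig
    active = is_day & any_elig

    for mask, st in ((night, ActivityState.NOCTURNAL_RETREAT), (cold, ActivityState.INACTIVE_COLD)):
        state[mask] = st
        T_body[mask] = T_retreat[mask]
        mh_kind[mask] = 1
        mh_value[mask] = depths[sel_depth[mask]]
        lethal[mask] = lethal_ret[mask]

    state[hot] = ActivityState.SHELTER_HEAT
    T_body[hot] = T_shelter[hot]
    mh_kind[hot] = 1
    mh_value[hot] = np.where(
        has_shelter[hot], depths[sel_shelter[hot]], depths[sel_depth[hot]]
    )
    lethal[hot] = np.where(has_shelter[hot], False, lethal_ret[hot])

    state[active] = np.where(
        T_active[active] >= t_fmin, ActivityState.FORAGING, ActivityState.BASKING
    )
    T_body[active] = T_active[active]
    mh_kind[active] = 0
    mh_value[active] = shades[sel_shade[active]]

    feeding = state == ActivityState.FORAGING
    return {
        "state": state,
        "T_body": T_body,
        "feeding": feeding,
        "lethal": lethal,
        "microhabitat_kind": mh_kind,
        "microhabitat_value": mh_value,
        "is_day": is_day,
    }
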