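"""Numba-jitted integration kernels for the standard DEB state dynamics.

Single source of truth for the energy bookkeeping: the public dataclass
API in :mod:`ectogradient.deb`, the life-cycle driver and the
constant-environment predictor used by parameter estimation all call the
same scalar step.  Hourly Euler with automatic sub-stepping whenever the
relative change of reserve or structure within one step would exceed 1 %.

State vector layout: [E, V, E_H, E_R, q, h, S, age_d, V_peak].
Parameter vector layout: see the index constants below.
"""

import numpy as np
from numba import njit

# parameter vector indices
IP_AM, IV, IKAP, IP_M, IE_G, IK_J, IE_HB, IE_HP, IT_A, IT_REF, IH_A, IS_G, \
    IKAP_R, IE_0, IDEL_M, IE_M, IL_I, IV_I, ISURV = range(19)

# state vector indices
SE, SV, SEH, SER, SQ, SH, SS, SAGE, SVPEAK = range(9)
N_STATE = 9

# step return codes
ALIVE = 0
DEAD_STARVATION = 1
DEAD_AGEING = 2

_REL_TOL = 0.01     # max relative state change per (sub)step
_MAX_SUB = 4096
V_INIT = 1e-6       # cm^3, structural volume of a freshly started embryo
#: structure fraction of the attained peak below which starvation is fatal
SHRINK_DEATH_FRACTION = 0.7


@njit(cache=True)
def arrhenius_factor(T_body_C, T_A, T_ref):
    return np.exp(T_A / T_ref - T_A / (T_body_C + 273.15))


@njit(cache=True)
def fluxes(E, V, E_H, pv, TC, f):
    """Return (p_A, p_C, p_S, p_J, p_G, p_R) in J/d for one state."""
    L = V ** (1.0 / 3.0)
    if E_H < pv[IE_HB]:
        p_A = 0.0  # embryos feed on reserve only
    else:
        p_A = TC * pv[IP_AM] * f * L * L
    p_S = TC * pv[IP_M] * V
    p_J = TC * pv[IK_J] * E_H
    p_C = E * TC * (pv[IE_G] * pv[IV] / L + pv[IP_M]) / (pv[IE_G] + pv[IKAP] * E / V)
    p_G = pv[IKAP] * p_C - p_S
    p_R = (1.0 - pv[IKAP]) * p_C - p_J
    return p_A, p_C, p_S, p_J, p_G, p_R


@njit(cache=True)
def _substep(s, pv, TC, f, dt):
    """Advance the state by dt days at fixed TC and f.  Returns a status code."""
    E = s[SE]
    V = s[SV]
    E_H = s[SEH]
    E_R = s[SER]
    embryo = E_H < pv[IE_HB]
    adult = E_H >= pv[IE_HP]

    p_A, p_C, p_S, p_J, p_G, p_R = fluxes(E, V, E_H, pv, TC, f)

    growth = p_G * dt
    invest = p_R * dt
    if growth >= 0.0:
        if invest < 0.0:
            # maturity-maintenance shortfall: drain the reproduction
            # buffer while it lasts, otherwise maturation simply stalls
            deficit = -invest
            paid = deficit if deficit <= E_R else E_R
            E_R -= paid
            invest = 0.0
    else:
        # somatic deficit: the kappa-rule is suspended — the whole
        # mobilized flux pays somatic maintenance first, any remainder
        # covers maturity maintenance and investment; growth stops
        growth = 0.0
        avail = (p_C - p_S) * dt
        if avail < 0.0:
            # mobilization cannot cover somatic maintenance: pay the
            # shortfall from the reproduction buffer, then catabolize
            # structure; fatal once structure drops below the survivable
            # fraction of its attained peak
            shortfall = -avail
            pay = shortfall if shortfall <= E_R else E_R
            E_R -= pay
            shortfall -= pay
            if shortfall > 0.0:
                V -= shortfall / pv[IE_G]
                if V < SHRINK_DEATH_FRACTION * s[SVPEAK]:
                    s[SV] = V
                    s[SS] = 0.0
                    return DEAD_STARVATION
            invest = 0.0
        else:
            invest = avail - p_J * dt
            if invest < 0.0:
                invest = 0.0

    E += (p_A - p_C) * dt
    if E <= 0.0:
        s[SE] = 0.0
        s[SS] = 0.0
        return DEAD_STARVATION
    V += growth / pv[IE_G]
    if V > s[SVPEAK]:
        s[SVPEAK] = V
    if adult:
        E_R += pv[IKAP_R] * invest
    else:
        E_H += invest

    s[SE] = E
    s[SV] = V
    s[SEH] = E_H
    s[SER] = E_R
    s[SAGE] += dt

    if not embryo:
        L = V ** (1.0 / 3.0)
        e_scaled = E / (V * pv[IE_M])
        r = growth / (dt * pv[IE_G] * V)  # realized specific growth rate
        sr = e_scaled * (TC * pv[IV] / L - r)
        if sr < 0.0:
            sr = 0.0
        h_a_T = pv[IH_A] * TC * TC
        dq = ((s[SQ] * (V / pv[IV_I]) * pv[IS_G] + h_a_T) * sr - r * s[SQ]) * dt
        dh = (s[SQ] - r * s[SH]) * dt
        s[SQ] += dq
        s[SH] += dh
        if s[SH] < 0.0:
            s[SH] = 0.0
        s[SS] *= np.exp(-s[SH] * dt)
        if s[SS] < pv[ISURV]:
            return DEAD_AGEING
    return ALIVE


@njit(cache=True)
def step(s, pv, T_body_C, f, dt):
    """One forcing step (dt days), sub-stepping to keep relative changes < 1 %."""
    TC = arrhenius_factor(T_body_C, pv[IT_A], pv[IT_REF])
    # estimate the needed number of substeps from the current derivatives
    p_A, p_C, p_S, p_J, p_G, p_R = fluxes(s[SE], s[SV], s[SEH], pv, TC, f)
    relE = abs(p_A - p_C) * dt / max(s[SE], 1e-30)
    g = p_G if p_G > 0.0 else 0.0
    relV = g * dt / (pv[IE_G] * max(s[SV], 1e-30))
    rel = relE if relE > relV else relV
    n = int(rel / _REL_TOL) + 1
    if n > _MAX_SUB:
        n = _MAX_SUB
    h = dt / n
    for _ in range(n):
        status = _substep(s, pv, TC, f, h)
        if status != ALIVE:
            return status
    return ALIVE


@njit(cache=True)
def init_embryo_state(E_0):
    s = np.zeros(N_STATE)
    s[SE] = E_0
    s[SV] = V_INIT
    s[SS] = 1.0
    s[SVPEAK] = V_INIT
    return s


@njit(cache=True)
def run_embryo(soil_T, pv, dt, max_steps):
    """Step an embryo on a soil-temperature trace until maturity reaches birth.

    Returns (status, steps_used, state): status 0 = hatched, 1 = died
    (reserve exhausted), 2 = did not hatch within max_steps.
    """
    s = init_embryo_state(pv[IE_0])
    n = soil_T.shape[0]
    limit = max_steps if max_steps < n else n
    for i in range(limit):
        status = step(s, pv, soil_T[i], 0.0, dt)
        if status != ALIVE:
            return 1, i + 1, s
        if s[SEH] >= pv[IE_HB]:
            return 0, i + 1, s
    return 2, limit, s


@njit(cache=True)
def run_embryo_const(pv, T_C, E_0, dt, max_steps):
    """Constant-temperature embryo run; returns (status, days, E_b, V_b)."""
    s = init_embryo_state(E_0)
    for i in range(max_steps):
        status = step(s, pv, T_C, 0.0, dt)
        if status != ALIVE:
            return 1, s[SAGE], s[SE], s[SV]
        if s[SEH] >= pv[IE_HB]:
            return 0, s[SAGE], s[SE], s[SV]
    return 2, s[SAGE], s[SE], s[SV]


@njit(cache=True)
def run_const_life(s, pv, T_C, f, dt, max_steps):
    """Constant-environment run from a hatchling state.

    Returns (age_at_puberty_d, age_at_death_d, L_at_puberty_cm, status):
    ages are -1 if the event was not reached; status is the final step code.
    """
    t_pub = -1.0
    L_pub = -1.0
    status = ALIVE
    for i in range(max_steps):
        status = step(s, pv, T_C, f, dt)
        if t_pub < 0.0 and s[SEH] >= pv[IE_HP]:
            t_pub = s[SAGE]
            L_pub = s[SV] ** (1.0 / 3.0)
        if status != ALIVE:
            return t_pub, s[SAGE], L_pub, status
    return t_pub, -1.0, L_pub, status


@njit(cache=True)
def round_half_away(x):
    if x >= 0.0:
        return np.floor(x + 0.5)
    return np.ceil(x - 0.5)


@njit(cache=True)
def clutch_size(V, E_R, pv, rule_a, rule_b, rule_cap):
    """Candidate clutch at the current state: SVL rule capped by energy."""
    svl_mm = 10.0 * V ** (1.0 / 3.0) / pv[IDEL_M]
    n_star = int(round_half_away(rule_a + rule_b * svl_mm))
    if n_star < 0:
        n_star = 0
    energy_cap = int(np.floor(E_R * pv[IKAP_R] / pv[IE_0]))
    n = n_star
    if n > rule_cap:
        n = int(rule_cap)
    if n > energy_cap:
        n = energy_cap
    return n


@njit(cache=True)
def run_life(
    T_body,
    feeding,
    clutch_check,
    pv,
    rule_a,
    rule_b,
    rule_cap,
    refractory_hours,
    start_idx,
    state,
    dt,
):
    """Post-hatch hourly life-cycle integration with clutch events.

    Returns (death_idx, death_cause, puberty_idx, clutch_hours, clutch_sizes,
    n_clutches).  death_idx = -1 means alive at the end of the horizon;
    cause codes follow the step return codes.
    """
    n = T_body.shape[0]
    max_clutches = 400
    clutch_hours = np.full(max_clutches, -1, dtype=np.int64)
    clutch_sizes = np.zeros(max_clutches, dtype=np.int64)
    n_clutches = 0
    puberty_idx = -1
    last_clutch = -10 ** 9

    for i in range(start_idx, n):
        f = 1.0 if feeding[i] else 0.0
        status = step(state, pv, T_body[i], f, dt)
        if puberty_idx < 0 and state[SEH] >= pv[IE_HP]:
            puberty_idx = i
        if status != ALIVE:
            return i, status, puberty_idx, clutch_hours, clutch_sizes, n_clutches
        if (
            clutch_check[i]
            and state[SEH] >= pv[IE_HP]
            and i - last_clutch >= refractory_hours
            and state[SER] >= pv[IE_0]
        ):
            eggs = clutch_size(state[SV], state[SER], pv, rule_a, rule_b, rule_cap)
            if eggs > 0:
                state[SER] -= eggs * pv[IE_0] / pv[IKAP_R]
                if n_clutches < max_clutches:
                    clutch_hours[n_clutches] = i
                    clutch_sizes[n_clutches] = eggs
                    n_clutches += 1
                last_clutch = i
    return -1, ALIVE, puberty_idx, clutch_hours, clutch_sizes, n_clutches
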