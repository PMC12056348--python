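"""Standard Dynamic Energy Budget model: state, fluxes, stepping, clutches.

The standard DEB model tracks four energetic state variables of an
individual — reserve E (J), structure V (cm³), maturity E_H (J) and the
reproduction buffer E_R (J) — plus the ageing pair (q, h) and survival S.
Assimilated energy enters the reserve; mobilized reserve is split by the
κ-rule between soma (somatic maintenance + growth) and maturation
(maturity maintenance + maturation or reproduction).  All rates carry a
single-Arrhenius temperature correction; the ageing acceleration h_a is
corrected by TC² so that constant-temperature trajectories are exact time
rescalings of the reference-temperature trajectory.

Life stages are determined by maturity: embryo below E_Hb (no feeding),
juvenile between E_Hb and E_Hp, adult above E_Hp (reproduction buffer
filling).  Under a somatic maintenance shortfall the κ-rule is suspended:
mobilized reserve pays somatic maintenance first and growth stops; the
remaining deficit is paid from the reproduction buffer, then by
catabolizing structure, and starvation is fatal (S := 0) once structure
drops below 70 % of its attained peak.  Maturity is never drained;
maturity-maintenance arrears merely stall maturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .config import HOURS_PER_DAY


class DEBError(ValueError):
    pass


class NonViableEggError(RuntimeError):
    """The embryo failed to reach birth maturity within the guard horizon."""


@dataclass(frozen=True)
class DEBParams:
    """Core parameters of the standard DEB model (units in comments).

    ``E_0`` is the initial egg energy; when left at 0 it is computed by
    :func:`initial_egg_energy` (bisection on the standard initial-reserve
    condition that the hatchling is born with scaled reserve density 1)
    and cached with :meth:`with_egg_energy`.
    """

    p_Am: float          # J cm^-2 d^-1, max surface-specific assimilation
    v: float             # cm d^-1, energy conductance
    kappa: float         # -, allocation fraction to soma
    p_M: float           # J cm^-3 d^-1, volume-specific somatic maintenance
    E_G: float           # J cm^-3, cost of structure
    k_J: float           # d^-1, maturity maintenance rate
    E_Hb: float          # J, maturity at birth
    E_Hp: float          # J, maturity at puberty
    T_A: float = 9000.0  # K, Arrhenius temperature
    T_ref: float = 293.15  # K, reference temperature (20 degC)
    h_a: float = 1e-9    # d^-2, Weibull ageing acceleration
    s_G: float = 1e-2    # -, Gompertz stress coefficient
    del_M: float = 0.2   # -, shape coefficient (structural length / SVL)
    E_0: float = 0.0     # J, initial egg energy (0 = not yet computed)
    kap_R: float = 0.95  # -, reproduction efficiency
    survival_threshold: float = 0.5  # S below which the individual is dead

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa < 1.0):
            raise DEBError("kappa must lie in (0, 1)")
        if not (0.0 < self.kap_R <= 1.0):
            raise DEBError("kap_R must lie in (0, 1]")
        if not (self.E_Hb < self.E_Hp):
            raise DEBError("E_Hb must be < E_Hp")
        for name in ("p_Am", "v", "p_M", "E_G", "k_J", "T_A", "T_ref"):
            if getattr(self, name) <= 0:
                raise DEBError(f"{name} must be > 0")
        if self.h_a < 0 or self.E_0 < 0:
            raise DEBError("h_a and E_0 must be >= 0")

    @property
    def E_m(self) -> float:
        """Maximum reserve density, J cm^-3."""
        return self.p_Am / self.v

    @property
    def L_i(self) -> float:
        """Ultimate structural length at f=1: kappa * p_Am / p_M, cm."""
        return self.kappa * self.p_Am / self.p_M

    @property
    def r_B(self) -> float:
        """von Bertalanffy growth rate at f=1 and T_ref, d^-1."""
        return self.p_M / (3.0 * (self.E_m * self.kappa + self.E_G))

    def to_vector(self) -> np.ndarray:
        pv = np.empty(19)
        pv[K.IP_AM] = self.p_Am
        pv[K.IV] = self.v
        pv[K.IKAP] = self.kappa
        pv[K.IP_M] = self.p_M
        pv[K.IE_G] = self.E_G
        pv[K.IK_J] = self.k_J
        pv[K.IE_HB] = self.E_Hb
        pv[K.IE_HP] = self.E_Hp
        pv[K.IT_A] = self.T_A
        pv[K.IT_REF] = self.T_ref
        pv[K.IH_A] = self.h_a
        pv[K.IS_G] = self.s_G
        pv[K.IKAP_R] = self.kap_R
        pv[K.IE_0] = self.E_0
        pv[K.IDEL_M] = self.del_M
        pv[K.IE_M] = self.E_m
        pv[K.IL_I] = self.L_i
        pv[K.IV_I] = self.L_i ** 3
        pv[K.ISURV] = self.survival_threshold
        return pv

    def with_egg_energy(self) -> "DEBParams":
        """Return a copy with ``E_0`` filled in (computed if missing)."""
        if self.E_0 > 0:
            return self
        return replace(self, E_0=initial_egg_energy(self))


@dataclass
class DEBState:
    """Energetic state of one individual."""

    E: float             # J, reserve
    V: float             # cm^3, structure
    E_H: float = 0.0     # J, maturity
    E_R: float = 0.0     # J, reproduction buffer
    q: float = 0.0       # d^-2, ageing acceleration
    h: float = 0.0       # d^-1, hazard
    S: float = 1.0       # -, survival probability
    age: float = 0.0     # d
    V_peak: float = 0.0  # cm^3, largest structure attained (starvation ref)

    def stage(self, p: DEBParams) -> str:
        if self.E_H < p.E_Hb:
            return "embryo"
        if self.E_H < p.E_Hp:
            return "juvenile"
        return "adult"

    def to_vector(self) -> np.ndarray:
        return np.array([self.E, self.V, self.E_H, self.E_R, self.q, self.h,
                         self.S, self.age, max(self.V_peak, self.V)])

    @classmethod
    def from_vector(cls, s: np.ndarray) -> "DEBState":
        return cls(E=s[K.SE], V=s[K.SV], E_H=s[K.SEH], E_R=s[K.SER],
                   q=s[K.SQ], h=s[K.SH], S=s[K.SS], age=s[K.SAGE],
                   V_peak=s[K.SVPEAK])

    def validate(self) -> None:
        vals = self.to_vector()
        if np.any(np.isnan(vals)):
            raise DEBError(f"NaN in DEB state: {self}")
        if min(self.E, self.V, self.E_H, self.E_R) < 0:
            raise DEBError(f"negative energy/structure in DEB state: {self}")


@dataclass(frozen=True)
class ClutchRule:
    """Linear SVL → clutch-size rule with a species cap.

    Candidate clutch = round_half_away(a + b · SVL_mm), capped by
    ``cap_eggs`` and by the energy content of the reproduction buffer.
    """

    a: float
    b: float
    cap_eggs: int

    def __post_init__(self) -> None:
        if self.cap_eggs < 1:
            raise DEBError("cap_eggs must be >= 1")


def arrhenius_tc(T_body: float, p: DEBParams) -> float:
    """Rate multiplier TC = exp(T_A/T_ref − T_A/T_K); TC(T_ref) = 1."""
    return float(K.arrhenius_factor(float(T_body), p.T_A, p.T_ref))


def deb_fluxes(s: DEBState, p: DEBParams, f: float, TC: float):
    """Energy fluxes (p_A, p_C, p_S, p_J, p_G, p_R) in J/d.

    Embryos assimilate nothing regardless of ``f``.  The κ-rule partition
    satisfies p_C = p_G + p_S + p_J + p_R identically.
    """
    if s.V <= 0:
        raise DEBError("state must have V > 0 (initialize via an embryo)")
    return K.fluxes(s.E, s.V, s.E_H, p.to_vector(), float(TC), float(f))


def deb_step(s: DEBState, p: DEBParams, T_body: float, f: float, dt: float) -> DEBState:
    """Advance the state by dt days (dt ≤ 1/24) at body temperature T_body.

    Sub-steps internally whenever the relative change of reserve or
    structure would exceed 1 % per step.
    """
    if dt > 1.0 / HOURS_PER_DAY + 1e-12:
        raise DEBError("dt must be <= 1/24 d (hourly stepping)")
    s.validate()
    sv = s.to_vector()
    K.step(sv, p.to_vector(), float(T_body), float(f), float(dt))
    out = DEBState.from_vector(sv)
    if np.any(np.isnan(sv)):
        raise DEBError(f"NaN produced by deb_step; last valid state: {s}")
    return out


def initial_egg_energy(p: DEBParams, tol: float = 1e-4) -> float:
    """Initial egg energy E_0 by bisection on the initial-reserve condition.

    E_0 is chosen so that the hatchling's scaled reserve density
    e_b = E_b / (V_b · E_m) equals 1 (feeding starts at equilibrium).
    """
    pv = p.to_vector()
    dt = 1.0 / HOURS_PER_DAY
    max_steps = 5 * 365 * HOURS_PER_DAY

    def e_at_birth(E_0: float) -> float:
        status, _, E_b, V_b = K.run_embryo_const(pv, p.T_ref - 273.15, E_0, dt, max_steps)
        if status != 0:
            return -1.0  # embryo died or stalled: E_0 too small
        return E_b / (V_b * p.E_m)

    lo = p.E_Hb  # certainly too small: maturation alone needs (1-kappa) share
    hi = max(10.0 * p.E_Hb, 1.0)
    for _ in range(60):
        if e_at_birth(hi) > 1.0:
            break
        hi *= 2.0
    else:
        raise DEBError("could not bracket E_0")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if e_at_birth(mid) > 1.0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) / hi < tol:
            break
    return 0.5 * (lo + hi)


def simulate_embryo(
    p: DEBParams,
    soil_T_series: np.ndarray,
    start_index: int = 0,
    max_years: float = 2.0,
) -> tuple[float, DEBState]:
    """Incubate an egg on an hourly soil-temperature trace.

    Returns (development time in days, hatchling state).  Raises
    :class:`NonViableEggError` if the embryo does not hatch within
    ``max_years`` simulated years (arrested or failed development).
    """
    p = p.with_egg_energy()
    if p.E_0 <= 0:
        raise DEBError("E_0 must be > 0")
    trace = np.asarray(soil_T_series, dtype=float)[start_index:]
    max_steps = int(max_years * 365 * HOURS_PER_DAY)
    status, steps, sv = K.run_embryo(trace, p.to_vector(), 1.0 / HOURS_PER_DAY, max_steps)
    if status == 2 and steps < max_steps:
        raise NonViableEggError("soil series ended before hatching")
    if status != 0:
        raise NonViableEggError(
            f"non-viable egg under this microclimate (status={status}, "
            f"{steps / HOURS_PER_DAY:.0f} d simulated)"
        )
    return steps / HOURS_PER_DAY, DEBState.from_vector(sv)


def clutch_from_buffer(
    s: DEBState,
    p: DEBParams,
    species_rule: ClutchRule,
    in_window: bool,
) -> tuple[int, DEBState]:
    """Convert reproduction buffer to a clutch if inside the laying window.

    The candidate clutch follows the linear SVL rule, capped by the species
    maximum and by the energy available in the buffer (cost per egg is
    E_0/kap_R, so the buffer can never go negative).  Outside the window,
    or with a buffer below one egg, nothing happens.
    """
    if s.stage(p) != "adult":
        raise DEBError("only adults produce clutches")
    p = p.with_egg_energy()
    if not in_window or s.E_R < p.E_0:
        return 0, s
    eggs = int(
        K.clutch_size(s.V, s.E_R, p.to_vector(), species_rule.a, species_rule.b,
                      species_rule.cap_eggs)
    )
    if eggs <= 0:
        return 0, s
    new = replace_state(s, E_R=s.E_R - eggs * p.E_0 / p.kap_R)
    return eggs, new


def replace_state(s: DEBState, **kw) -> DEBState:
    from dataclasses import replace as _r

    return _r(s, **kw)
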