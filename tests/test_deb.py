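import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectogradient import _kernels as K
from ectogradient.deb import (
    ClutchRule,
    DEBError,
    DEBParams,
    DEBState,
    NonViableEggError,
    arrhenius_tc,
    clutch_from_buffer,
    deb_fluxes,
    deb_step,
    initial_egg_energy,
    simulate_embryo,
)


@pytest.fixture(scope="module")
def p(muralis):
    return muralis.deb


@pytest.fixture(scope="module")
def hatchling(p):
    _, state = simulate_embryo(p, np.full(24 * 365, 20.0))
    return state


class TestArrhenius:
    def test_unity_at_reference(self, p):
        assert arrhenius_tc(20.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_direct_evaluation(self, p):
        expect = math.exp(9000.0 / 293.15 - 9000.0 / 303.15)
        assert arrhenius_tc(30.0, p) == pytest.approx(expect, rel=1e-12)

    def test_strictly_increasing(self, p):
        temps = np.arange(-10, 50, 5.0)
        tcs = [arrhenius_tc(t, p) for t in temps]
        assert all(b > a for a, b in zip(tcs, tcs[1:]))


class TestFluxes:
    def test_kappa_rule_balance_on_random_states(self, p, rng):
        """Mobilization is exactly partitioned: p_C = p_G + p_S + p_J + p_R."""
        for _ in range(200):
            s = DEBState(
                E=rng.uniform(10, 5000),
                V=rng.uniform(0.05, 2.0),
                E_H=rng.uniform(p.E_Hb, 2 * p.E_Hp),
            )
            f = rng.uniform(0, 1)
            TC = rng.uniform(0.1, 3.0)
            p_A, p_C, p_S, p_J, p_G, p_R = deb_fluxes(s, p, f, TC)
            assert p_C == pytest.approx(p_G + p_S + p_J + p_R, rel=1e-9)

    def test_growth_stops_at_equilibrium_ultimate_size(self, p):
        s = DEBState(E=p.E_m * p.L_i ** 3, V=p.L_i ** 3, E_H=p.E_Hp)
        _, _, p_S, _, p_G, _ = deb_fluxes(s, p, 1.0, 1.0)
        assert abs(p_G) < 1e-8 * p_S

    def test_soma_share_equals_maintenance_at_ultimate_length(self, p):
        s = DEBState(E=p.E_m * p.L_i ** 3, V=p.L_i ** 3, E_H=p.E_Hp)
        _, p_C, p_S, _, _, _ = deb_fluxes(s, p, 1.0, 1.0)
        assert p.kappa * p_C == pytest.approx(p_S, rel=1e-12)

    def test_embryo_never_assimilates(self, p):
        s = DEBState(E=100.0, V=0.01, E_H=0.5 * p.E_Hb)
        p_A = deb_fluxes(s, p, 1.0, 1.0)[0]
        assert p_A == 0.0

    def test_zero_structure_rejected(self, p):
        with pytest.raises(DEBError):
            deb_fluxes(DEBState(E=1.0, V=0.0), p, 1.0, 1.0)


class TestStepping:
    def test_von_bertalanffy_growth_at_constant_conditions(self, p, hatchling):
        """At f=1 and T_ref the length trajectory is von Bertalanffy."""
        sv = hatchling.to_vector()
        pv = p.to_vector()
        L_b = hatchling.V ** (1 / 3)
        checks = {365: None, 2 * 365: None, 4 * 365: None}
        for day in range(1, 4 * 365 + 1):
            for _ in range(24):
                K.step(sv, pv, 20.0, 1.0, 1.0 / 24.0)
            if day in checks:
                checks[day] = sv[K.SV] ** (1 / 3)
        for day, L in checks.items():
            expect = p.L_i - (p.L_i - L_b) * math.exp(-p.r_B * day)
            assert L == pytest.approx(expect, rel=0.01)

    def test_reserve_balance_bookkeeping(self, p, hatchling):
        """Assimilated energy equals Δreserve + mobilized energy."""
        s = hatchling
        assimilated = mobilized = 0.0
        E0 = s.E
        dt = 1.0 / 24.0
        for _ in range(24 * 30):
            p_A, p_C, *_ = deb_fluxes(s, p, 1.0, 1.0)
            assimilated += p_A * dt
            mobilized += p_C * dt
            s = deb_step(s, p, 20.0, 1.0, dt)
        assert assimilated == pytest.approx((s.E - E0) + mobilized, rel=1e-8)

    def test_starvation_from_juvenile_is_fatal_in_finite_time(self, p, hatchling):
        s = hatchling.to_vector()
        pv = p.to_vector()
        E_prev = s[K.SE]
        status = K.ALIVE
        for i in range(20 * 365 * 24):
            status = K.step(s, pv, 20.0, 0.0, 1.0 / 24.0)
            assert s[K.SE] <= E_prev + 1e-12  # reserve monotone under f=0
            E_prev = s[K.SE]
            if status != K.ALIVE:
                break
        assert status == K.DEAD_STARVATION

    def test_no_ageing_means_no_hazard(self, p, hatchling):
        from dataclasses import replace

        p0 = replace(p, h_a=0.0, E_0=p.E_0)
        sv = hatchling.to_vector()
        pv = p0.to_vector()
        for _ in range(24 * 365):
            K.step(sv, pv, 25.0, 1.0, 1.0 / 24.0)
        assert sv[K.SS] == pytest.approx(1.0, abs=1e-12)

    def test_survival_non_increasing(self, p, hatchling):
        sv = hatchling.to_vector()
        pv = p.to_vector()
        S_prev = 1.0
        for _ in range(24 * 200):
            K.step(sv, pv, 30.0, 1.0, 1.0 / 24.0)
            assert sv[K.SS] <= S_prev + 1e-15
            S_prev = sv[K.SS]

    def test_maturity_never_decreases(self, p, hatchling):
        sv = hatchling.to_vector()
        pv = p.to_vector()
        EH_prev = sv[K.SEH]
        for i in range(24 * 400):
            K.step(sv, pv, 20.0, 1.0 if i % 48 < 24 else 0.0, 1.0 / 24.0)
            assert sv[K.SEH] >= EH_prev - 1e-12
            EH_prev = sv[K.SEH]

    def test_too_large_dt_rejected(self, p, hatchling):
        with pytest.raises(DEBError):
            deb_step(hatchling, p, 20.0, 1.0, 0.5)

    def test_nan_state_rejected(self, p, hatchling):
        from dataclasses import replace as r

        bad = r(hatchling, E=float("nan"))
        with pytest.raises(DEBError, match="NaN"):
            deb_step(bad, p, 20.0, 1.0, 1.0 / 24.0)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    p_Am=st.floats(60.0, 200.0),
    v=st.floats(0.01, 0.03),
    kappa=st.floats(0.5, 0.9),
    p_M=st.floats(30.0, 90.0),
)
def test_ultimate_length_property(p_Am, v, kappa, p_M):
    """Asymptotic length at f=1 equals κ·p_Am/p_M for any valid parameters."""
    p = DEBParams(
        p_Am=p_Am, v=v, kappa=kappa, p_M=p_M, E_G=7800.0, k_J=0.0005,
        E_Hb=50.0, E_Hp=500.0, h_a=0.0, s_G=0.01,
    )
    L_i = kappa * p_Am / p_M
    sv = K.init_embryo_state(0.0)
    # start from a juvenile at 40% of ultimate length with full reserve
    sv[K.SV] = (0.4 * L_i) ** 3
    sv[K.SVPEAK] = sv[K.SV]
    sv[K.SE] = (p_Am / v) * sv[K.SV]
    sv[K.SEH] = 60.0
    pv = p.to_vector()
    horizon_d = int(8.0 / p.r_B)  # e^-8 of the gap remains
    for _ in range(horizon_d):
        K.step(sv, pv, 20.0, 1.0, 1.0)  # dt=1 d is fine: state changes slowly
    assert sv[K.SV] ** (1 / 3) == pytest.approx(L_i, rel=0.005)


class TestEmbryo:
    def test_initial_reserve_condition(self, p):
        """E_0 yields a hatchling born at scaled reserve density 1."""
        status, _, E_b, V_b = K.run_embryo_const(
            p.to_vector(), 20.0, p.E_0, 1.0 / 24.0, 5 * 365 * 24
        )
        assert status == 0
        assert E_b / (V_b * p.E_m) == pytest.approx(1.0, abs=2e-3)

    def test_development_slower_when_colder(self, p):
        t25, _ = simulate_embryo(p, np.full(2 * 365 * 24, 25.0))
        t20, _ = simulate_embryo(p, np.full(2 * 365 * 24, 20.0))
        assert t20 > t25

    def test_matches_fine_step_oracle(self, p):
        """Hourly kernel vs an independent Euler integrator at dt=1e-3 d."""
        t_kernel, state = simulate_embryo(p, np.full(365 * 24, 20.0))

        # independent integration of the embryo ODEs, written from scratch
        dt = 1e-3
        E, V, EH = p.E_0, 1e-6, 0.0
        t = 0.0
        while EH < p.E_Hb:
            L = V ** (1 / 3)
            p_C = E * (p.E_G * p.v / L + p.p_M) / (p.E_G + p.kappa * E / V)
            p_S = p.p_M * V
            p_J = p.k_J * EH
            p_G = p.kappa * p_C - p_S
            E -= p_C * dt
            V += max(p_G, 0.0) / p.E_G * dt
            EH += max((1 - p.kappa) * p_C - p_J, 0.0) * dt
            t += dt
            assert t < 1000.0
        assert t_kernel == pytest.approx(t, rel=0.01)
        assert state.V ** (1 / 3) == pytest.approx(V ** (1 / 3), rel=0.01)

    def test_arrested_development_hits_guard(self, p):
        with pytest.raises(NonViableEggError):
            simulate_embryo(p, np.full(3 * 365 * 24, 2.0))

    def test_E0_bracketing_from_scratch(self, p):
        from dataclasses import replace

        E0 = initial_egg_energy(replace(p, E_0=0.0))
        assert E0 == pytest.approx(p.E_0, rel=5e-3)


class TestClutch:
    def test_saturated_buffer_emits_species_cap(self, p, muralis):
        s = DEBState(E=1.0, V=(0.66 * 2.0) ** 3, E_H=p.E_Hp, E_R=100 * p.E_0)
        eggs, s2 = clutch_from_buffer(s, p, muralis.clutch_rule, True)
        assert eggs == 5
        assert s2.E_R == pytest.approx(s.E_R - 5 * p.E_0 / p.kap_R)

    def test_insufficient_buffer_yields_nothing(self, p, muralis):
        s = DEBState(E=1.0, V=1.0, E_H=p.E_Hp, E_R=0.5 * p.E_0)
        eggs, s2 = clutch_from_buffer(s, p, muralis.clutch_rule, True)
        assert eggs == 0 and s2.E_R == s.E_R

    def test_outside_window_yields_nothing(self, p, muralis):
        s = DEBState(E=1.0, V=1.0, E_H=p.E_Hp, E_R=100 * p.E_0)
        eggs, s2 = clutch_from_buffer(s, p, muralis.clutch_rule, False)
        assert eggs == 0 and s2.E_R == s.E_R

    def test_rounding_convention_vs_enumeration(self, p):
        """a + b·SVL = 3.4 rounds to 3; energy cap floor(E_R·κ_R/E_0)."""
        rule = ClutchRule(a=3.4, b=0.0, cap_eggs=5)
        s = DEBState(E=1.0, V=1.0, E_H=p.E_Hp, E_R=4.0 * p.E_0)
        eggs, _ = clutch_from_buffer(s, p, rule, True)
        # brute enumeration: largest n with n <= 3.4 rounded and affordable
        affordable = math.floor(s.E_R * p.kap_R / p.E_0)
        assert eggs == min(round(3.4), 5, affordable) == 3

    def test_half_up_rounding(self, p):
        rule = ClutchRule(a=2.5, b=0.0, cap_eggs=5)
        s = DEBState(E=1.0, V=1.0, E_H=p.E_Hp, E_R=50.0 * p.E_0)
        eggs, _ = clutch_from_buffer(s, p, rule, True)
        assert eggs == 3  # round half away from zero

    def test_juvenile_cannot_lay(self, p, muralis):
        s = DEBState(E=1.0, V=0.5, E_H=0.5 * p.E_Hp, E_R=100 * p.E_0)
        with pytest.raises(DEBError):
            clutch_from_buffer(s, p, muralis.clutch_rule, True)


class TestParamInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            {"kappa": 1.2},
            {"kappa": 0.0},
            {"E_Hb": 10.0, "E_Hp": 5.0},
            {"p_M": -1.0},
            {"kap_R": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        base = dict(
            p_Am=100.0, v=0.02, kappa=0.8, p_M=50.0, E_G=7800.0,
            k_J=0.002, E_Hb=100.0, E_Hp=1000.0,
        )
        base.update(kw)
        with pytest.raises(DEBError):
            DEBParams(**base)
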