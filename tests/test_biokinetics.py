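"""Reaction-diffusion kinetics: conservation, oracles, and limiting cases."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from chondrosim.biokinetics import (
    KineticsGrid,
    KineticsParams,
    KineticsSimulator,
    SpeciesState,
    TreatmentSchedule,
    enzyme_diffusivity,
    pg_kinetics_rhs,
    relative_pg,
    run_kinetics,
    stimulus_rhs,
    wellmixed_damage_exposure,
    wellmixed_viability,
)
from chondrosim.cell_damage import SUPERFICIAL_IMPACTED_ZONE, CellField, zone_average

HOUR = 3600.0
DAY = 86400.0


def _state(grid=None, damage=0.56, params=None):
    grid = grid or KineticsGrid(n_r=8, n_z=5)
    params = params or KineticsParams()
    n = grid.n_cells
    r, z = grid.points()
    cells = CellField(r=r, z=z,
                      C_h=np.full(n, (1 - damage) * params.C_init),
                      C_dmg=np.full(n, damage * params.C_init),
                      C_dead=np.zeros(n), C_init=params.C_init)
    return SpeciesState.initial(grid, cells, np.full(n, 150.0))


class TestWellMixedOracle:
    def test_reduces_to_pure_death_without_protection(self):
        v1 = wellmixed_viability(0.56, 6.9e-5, 0.0, 2.0, 0.0, 4 * HOUR)
        v2 = 0.44 + 0.56 * np.exp(-6.9e-5 * 4 * HOUR)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_matches_ode_integration_with_delay(self):
        kd, kr, c, delay, T = 6.9e-5, 0.53e-4, 2.0, 4 * HOUR, 48 * HOUR

        def rhs(t, y):
            dmg, dead = y
            rec = kr * c * dmg if t >= delay else 0.0
            return [-kd * dmg - rec, kd * dmg]

        sol = solve_ivp(rhs, (0, T), [0.56, 0.0], rtol=1e-10, atol=1e-14,
                        max_step=60.0)
        assert wellmixed_viability(0.56, kd, kr, c, delay, T) == pytest.approx(
            1.0 - sol.y[1, -1], abs=1e-6)

    def test_exposure_integral_matches_quadrature(self):
        kd, kr, c, delay, T = 6.9e-5, 0.53e-4, 2.0, 4 * HOUR, 14 * DAY

        def dmg(t):
            if t <= delay:
                return 0.56 * np.exp(-kd * t)
            return 0.56 * np.exp(-kd * delay) * np.exp(-(kd + kr * c) * (t - delay))

        num, _ = quad(dmg, 0, T, points=[delay], limit=200)
        assert wellmixed_damage_exposure(0.56, kd, kr, c, delay, T) == pytest.approx(
            num, rel=1e-8)


class TestStepInvariants:
    def test_undamaged_untreated_state_is_stationary(self):
        st = _state(damage=0.0)
        before = {k: getattr(st, k).copy() for k in
                  ("C_h", "C_dmg", "C_dead", "S", "C_enz", "C_PG", "C_NAC")}
        sim = KineticsSimulator(st, KineticsParams(), TreatmentSchedule.untreated())
        for _ in range(20):
            sim.step(300.0)
        for k, v in before.items():
            assert np.allclose(getattr(st, k), v, rtol=1e-12, atol=1e-20), k

    def test_cell_conservation_and_positivity_under_treatment(self):
        st = _state()
        sim = KineticsSimulator(st, KineticsParams(),
                                TreatmentSchedule(delay=0.0))
        for _ in range(200):
            sim.step(60.0)
            assert st.conservation_error() < 1e-10
            assert st.min_field_value() >= 0.0

    def test_nac_mass_conserved_with_zero_flux_boundaries(self, rng):
        # untreated schedule -> no bath Dirichlet anywhere: pure zero-flux
        # diffusion of an initial NAC distribution must conserve total mass
        st = _state(damage=0.0)
        st.C_NAC = rng.uniform(0.0, 2.0, st.grid.n_cells)
        std0 = st.C_NAC.std()
        w = st.grid.volumes()
        m0 = float(np.sum(st.C_NAC * w))
        params = KineticsParams(k_rec=0.0)  # NAC not consumed anyway
        sim = KineticsSimulator(st, params, TreatmentSchedule.untreated())
        for _ in range(50):
            sim.step(600.0)
        m1 = float(np.sum(st.C_NAC * w))
        assert m1 == pytest.approx(m0, rel=1e-10)
        # and the spread shrinks as the field homogenizes
        assert st.C_NAC.std() < 0.5 * std0


class TestWellMixedLimit:
    def test_large_diffusivity_matches_analytic_viability(self):
        """With D_NAC large the PDE collapses onto the well-mixed two-rate
        model; zone viability must agree to 0.1 percentage point."""
        params = KineticsParams(D_NAC=1e-4)
        st = _state(grid=KineticsGrid(n_r=10, n_z=8), params=params)
        sched = TreatmentSchedule(delay=0.0, bath_concentration=2.0,
                                  duration=2 * DAY)
        st, _ = run_kinetics(st, params, sched, 24 * HOUR, dt=60.0, dt_fine=10.0)
        r, z = st.grid.points()
        w = st.grid.volumes()
        v_pde = zone_average(st.viability, r, z, SUPERFICIAL_IMPACTED_ZONE, weights=w)
        v_ref = wellmixed_viability(0.56, params.k_death, params.k_rec, 2.0,
                                    0.0, 24 * HOUR)
        assert v_pde == pytest.approx(v_ref, abs=1e-3)

    def test_superficial_zone_equilibrates_within_minutes(self):
        """Physical D_NAC: the top 200 um reach near-bath concentration on
        the L^2/D timescale (~6 min), not hours."""
        params = KineticsParams()
        st = _state(grid=KineticsGrid(n_r=10, n_z=20), params=params)
        sched = TreatmentSchedule(delay=0.0)
        st, _ = run_kinetics(st, params, sched, 15 * 60.0, dt=30.0, dt_fine=30.0)
        r, z = st.grid.points()
        w = st.grid.volumes()
        c_sup = zone_average(st.C_NAC, r, z, SUPERFICIAL_IMPACTED_ZONE, weights=w)
        assert c_sup > 0.8 * sched.bath_concentration


class TestReactionOracles:
    def test_uniform_fields_match_coupled_ode_oracle(self):
        """Uniform zero-flux problem: the simulator must track the coupled
        (C_dmg, S, C_enz) ODE system integrated independently."""
        params = KineticsParams(k_aga=2e-18, D_NAC=0.0)
        st = _state(params=params)
        d0 = st.C_dmg[0]

        def rhs(t, y):
            dmg, S, enz = y
            return [-params.k_death * dmg,
                    stimulus_rhs(S, dmg, params),
                    S - params.k_enz_clear * enz]

        T = 2 * DAY
        sol = solve_ivp(rhs, (0, T), [d0, 0.0, 0.0], rtol=1e-10, atol=1e-12)
        sim = KineticsSimulator(st, params, TreatmentSchedule.untreated())
        t = 0.0
        while t < T - 1e-9:
            sim.step(60.0)
            t = st.time
        assert st.C_dmg[0] == pytest.approx(sol.y[0, -1], rel=1e-3)
        assert st.S[0] == pytest.approx(sol.y[1, -1], rel=2e-3)
        assert st.C_enz[0] == pytest.approx(sol.y[2, -1], rel=2e-3)

    def test_stimulus_time_integral_property(self):
        """integral of S equals k_aga * integral of C_dmg when S(0)=0 and
        both are integrated to exhaustion (numeric quadrature oracle)."""
        params = KineticsParams(k_aga=3e-18)
        kd = params.k_death
        d0 = 2.8e13

        def rhs(t, y):
            return [-kd * y[0], stimulus_rhs(y[1], y[0], params)]

        T = 80 * DAY  # both transients fully decayed
        sol = solve_ivp(rhs, (0, T), [d0, 0.0], rtol=1e-11, atol=1e-14,
                        dense_output=True)
        ts = np.linspace(0, T, 20001)
        dmg, S = sol.sol(ts)
        int_S = np.trapezoid(S, ts)
        int_dmg = np.trapezoid(dmg, ts)
        assert int_S == pytest.approx(params.k_aga * int_dmg, rel=1e-3)

    def test_pg_michaelis_menten_limits(self):
        params = KineticsParams(k_basal=0.0)
        enz, viable = 5.0, 1.0
        big = 1e4 * params.K_M
        rate_big = pg_kinetics_rhs(big, enz, viable, big, params)
        assert rate_big == pytest.approx(-params.k_cat * enz, rel=1e-3)
        small = 1e-4 * params.K_M
        rate_small = pg_kinetics_rhs(small, enz, viable, small, params)
        assert rate_small == pytest.approx(
            -params.k_cat / params.K_M * enz * small, rel=1e-3)

    def test_intact_tissue_is_at_steady_state(self):
        params = KineticsParams()
        rate = pg_kinetics_rhs(150.0, 0.0, 1.0, 150.0, params)
        assert rate == pytest.approx(0.0, abs=1e-18)

    def test_enzyme_diffusivity_monotone_in_pg(self):
        params = KineticsParams()
        d_low = enzyme_diffusivity(50.0, 150.0, params)
        d_high = enzyme_diffusivity(150.0, 150.0, params)
        assert d_low > d_high  # depleted matrix is more permeable


class TestRelativePG:
    def test_identical_zones_give_unity(self):
        st = _state(grid=KineticsGrid(n_r=40, n_z=5))
        assert relative_pg(st) == pytest.approx(1.0)

    def test_uniform_depletion_in_impacted_zone(self):
        st = _state(grid=KineticsGrid(n_r=40, n_z=5))
        r, _ = st.grid.points()
        st.C_PG = np.where(r <= 2.0e-3, 0.85 * st.C_PG, st.C_PG)
        assert relative_pg(st) == pytest.approx(0.85, rel=1e-12)


class TestTreatmentSchedule:
    def test_bath_window(self):
        s = TreatmentSchedule(delay=HOUR, bath_concentration=2.0, duration=DAY)
        assert s.bath_at(0.0) == 0.0          # pre-treatment: bath present, empty
        assert s.bath_at(HOUR) == 2.0
        assert s.bath_at(HOUR + DAY + 1) == 0.0
        assert TreatmentSchedule.untreated().bath_at(10.0) is None
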