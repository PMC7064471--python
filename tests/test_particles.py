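"""Particle force balance: drag bands, relaxation time, integration,
injection bookkeeping and dispersion."""

import numpy as np
import pytest

from cellseed.flow import FluidProperties, box_state
from cellseed.particles import (CellParticle, CellProperties, InjectionSpec,
                                Injector, drag_coefficient,
                                particle_reynolds, random_walk_kick,
                                relaxation_time, step_particle,
                                stokes_relaxation_time)

FLUID = FluidProperties()
CELL = CellProperties()


class TestReynolds:
    def test_hand_value(self):
        # rho=1000, v=0.01 m/s, d=15 um, mu=0.001 -> Re = 0.15
        assert particle_reynolds(FLUID, 0.01, 15e-6) == pytest.approx(0.15)

    def test_zero_velocity(self):
        assert particle_reynolds(FLUID, 0.0, 15e-6) == 0.0

    def test_linear_in_speed(self):
        assert particle_reynolds(FLUID, 0.02, 15e-6) == pytest.approx(
            2 * particle_reynolds(FLUID, 0.01, 15e-6))


class TestDragCoefficient:
    def test_stokes_band(self):
        assert drag_coefficient(0.05) == pytest.approx(480.0)

    def test_stokes_limit_cd_re(self):
        for re in (1e-4, 1e-3, 1e-2, 0.09):
            assert drag_coefficient(re) * re == pytest.approx(24.0)

    def test_monotone_decreasing_to_100(self):
        re = np.linspace(1e-3, 100.0, 20000)
        cd = drag_coefficient(re)
        assert np.all(np.diff(cd) < 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            drag_coefficient(0.0)


class TestRelaxationTime:
    def test_stokes_value(self):
        # rho_cell=1000, d=15 um, mu=0.001 -> rho d^2/(18 mu) = 1.25e-5 s
        tau = stokes_relaxation_time(CELL, FLUID)
        assert tau == pytest.approx(1.25e-5, rel=1e-12)
        assert relaxation_time(CELL, FLUID, 0.0) == pytest.approx(tau, rel=1e-12)

    def test_cd_re_24_reproduces_stokes_formula(self):
        # in the Stokes band C_D * Re = 24 exactly, so the general formula
        # collapses onto rho d^2 / 18 mu
        tau_gen = relaxation_time(CELL, FLUID, 0.05)
        assert tau_gen == pytest.approx(stokes_relaxation_time(CELL, FLUID),
                                        rel=1e-12)

    def test_scales_as_diameter_squared(self):
        big = CellProperties(d_cell=30e-6)
        assert relaxation_time(big, FLUID, 0.05) == pytest.approx(
            4 * relaxation_time(CELL, FLUID, 0.05), rel=1e-12)


def _still_state(n=4, size=1e-3):
    """Quiescent liquid box for integrator tests."""
    return box_state(n, size, FLUID)


class TestStepParticle:
    def test_neutral_buoyancy_stays_at_rest(self):
        st = _still_state()
        p = CellParticle(0, np.full(3, 5e-4), np.zeros(3), mass=CELL.mass)
        step_particle(p, st, CELL, dt=1e-3)
        assert np.allclose(p.velocity, 0.0)

    def test_exponential_decay_matches_closed_form(self):
        """Still fluid, no gravity: v(t) = v0 exp(-t/tau) to 1e-6 relative."""
        st = _still_state()
        v0 = 1e-4  # small enough to stay in the Stokes band throughout
        tau = stokes_relaxation_time(CELL, FLUID)
        p = CellParticle(0, np.full(3, 5e-4), np.array([v0, 0.0, 0.0]),
                         mass=CELL.mass)
        t = 0.0
        dt = 2e-6
        for _ in range(10):
            step_particle(p, st, CELL, dt=dt, g=0.0)
            t += dt
        expected = v0 * np.exp(-t / tau)
        assert p.velocity[0] == pytest.approx(expected, rel=1e-6)

    def test_relaxes_to_uniform_flow(self):
        st = _still_state()
        st.u[:] = 0.01  # uniform +x flow
        p = CellParticle(0, np.full(3, 5e-4), np.zeros(3), mass=CELL.mass)
        step_particle(p, st, CELL, dt=1e-2, g=0.0)  # dt >> tau
        assert p.velocity[0] == pytest.approx(0.01, rel=1e-6)

    def test_settling_reaches_terminal_velocity(self):
        """rho_cell > rho_fluid: v_term = g tau (rho_c - rho_f)/rho_c."""
        heavy = CellProperties(rho_cell=1100.0)
        st = _still_state()
        tau = stokes_relaxation_time(heavy, FLUID)
        p = CellParticle(0, np.full(3, 5e-4), np.zeros(3), mass=heavy.mass)
        for _ in range(5):
            step_particle(p, st, heavy, dt=tau)
        v_term = -FLUID.g * tau * (1100.0 - 1000.0) / 1100.0
        assert p.velocity[2] == pytest.approx(v_term, rel=0.01)

    def test_effectively_passive_tracer(self):
        """tau_r << dt: particle path tracks a massless tracer to < 1%."""
        st = _still_state(n=8, size=2e-3)
        # a gently varying field: shear in x
        for k in range(st.u.shape[2]):
            st.u[:, :, k] = 0.005 * (k + 1) / st.u.shape[2]
        p = CellParticle(0, np.array([2e-4, 1e-3, 1e-3]), np.zeros(3),
                         mass=CELL.mass)
        tracer = np.array([2e-4, 1e-3, 1e-3])
        from cellseed.flow import sample_velocity
        dt = 5e-4
        path = 0.0
        for _ in range(100):
            step_particle(p, st, CELL, dt=dt, g=0.0)
            uf = sample_velocity(st, tracer)
            tracer = tracer + uf * dt
            path += np.linalg.norm(uf) * dt
        assert np.linalg.norm(p.position - tracer) < 0.01 * path


class TestInjection:
    def test_total_count_by_stepping(self, rng):
        """Default rates over 5 s yield ~2315 whole cells, step-size free."""
        spec = InjectionSpec()
        expected = int(np.floor(spec.mass_flow_rate * spec.duration / CELL.mass))
        inj = Injector(spec, CELL, rng)
        total = 0
        t = 0.0
        while t < spec.duration:
            dt = 0.01 if (total % 2) else 0.013  # uneven steps
            total += len(inj.inject(t, dt))
            t += dt
        # 8.18e-10 kg/s * 5 s / (rho pi/6 d^3) = 2314.4 -> 2314 whole cells
        assert 2310 <= expected <= 2320
        assert total == expected

    def test_mass_exact_with_remainder_carry(self, rng):
        spec = InjectionSpec(mass_flow_rate=8.18e-10, duration=1.0)
        inj = Injector(spec, CELL, rng)
        n = 0
        for i in range(100):
            n += len(inj.inject(i * 0.01, 0.01))
        assert n == int(np.floor(spec.mass_flow_rate * 1.0 / CELL.mass + 1e-9))

    def test_zero_rate_injects_nothing(self, rng):
        inj = Injector(InjectionSpec(mass_flow_rate=0.0), CELL, rng)
        assert inj.inject(0.0, 1.0) == []

    def test_positions_on_inlet_disk(self, rng):
        spec = InjectionSpec(inlet_center=np.array([0.0, 5e-3, 7.5e-3]),
                             inlet_normal=np.array([1.0, 0, 0]),
                             inlet_radius=1e-3)
        inj = Injector(spec, CELL, rng)
        ps = inj.inject(0.0, 1.0)
        pos = np.array([p.position for p in ps])
        assert np.allclose(pos[:, 0], 0.0, atol=1e-12)
        r = np.hypot(pos[:, 1] - 5e-3, pos[:, 2] - 7.5e-3)
        assert np.all(r <= 1e-3 + 1e-12)


class TestRandomWalk:
    def test_off_by_default_is_deterministic(self, rng):
        assert np.all(random_walk_kick(rng, 0.0) == 0.0)

    def test_seeded_reproducibility(self):
        a = random_walk_kick(np.random.default_rng(42), 0.01)
        b = random_walk_kick(np.random.default_rng(42), 0.01)
        np.testing.assert_array_equal(a, b)

    def test_moments(self):
        rng = np.random.default_rng(5)
        sigma = 0.02
        kicks = np.array([random_walk_kick(rng, sigma) for _ in range(100_000 // 3)])
        flat = kicks.ravel()
        se = sigma / np.sqrt(flat.size)
        assert abs(flat.mean()) < 3 * se
        assert flat.var() == pytest.approx(sigma**2, rel=0.05)
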