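"""Impingement model: impact energy, regime map, regime application,
well-wall reflection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellseed.impingement import (E_SPLASH, E_STICK, ImpingementEvent, Regime,
                                  ThermalContext, WallFilm,
                                  apply_regime, boundary_layer_thickness,
                                  classify_regime, critical_temperature,
                                  impact_energy, reflect_well_wall)
from cellseed.particles import CellParticle, CellProperties, ParticleStatus

CELL = CellProperties()
CULTURE = ThermalContext()  # 37 C wall, Tc = 100 C


class TestBoundaryLayer:
    def test_hand_value(self):
        # d=15 um, Re=0.15 -> 15e-6/sqrt(0.15) = 3.873e-5 m
        assert boundary_layer_thickness(15e-6, 0.15) == pytest.approx(
            3.873e-5, rel=1e-3)

    def test_unit_reynolds(self):
        assert boundary_layer_thickness(15e-6, 1.0) == pytest.approx(15e-6)

    def test_decreasing_in_re(self):
        re = np.linspace(0.01, 10, 50)
        d = [boundary_layer_thickness(15e-6, r) for r in re]
        assert np.all(np.diff(d) < 0)

    def test_rejects_nonpositive_re(self):
        with pytest.raises(ValueError):
            boundary_layer_thickness(15e-6, 0.0)


class TestImpactEnergy:
    def test_dry_wall_hand_value(self):
        """rho=1000, V=0.01, d=15 um, sigma=0.03, dry wall, Re=0.15:
        E^2 = rho V^2 d sqrt(Re) / sigma -> E ~ 4.4e-3."""
        dbl = boundary_layer_thickness(15e-6, 0.15)
        E = impact_energy(1000.0, 0.01, 15e-6, 0.03, h_o=0.0, delta_bl=dbl)
        expected = np.sqrt(1000.0 * 1e-4 * 15e-6 * np.sqrt(0.15) / 0.03)
        assert E == pytest.approx(expected, rel=1e-12)
        assert E == pytest.approx(4.4e-3, rel=0.02)

    def test_zero_normal_speed(self):
        assert impact_energy(1000.0, 0.0, 15e-6, 0.03, 0.0, 1e-5) == 0.0

    def test_deep_film_clamps_to_one(self):
        d = 15e-6
        dbl = 5e-6
        deep = impact_energy(1000.0, 0.01, d, 0.03, h_o=10 * d, delta_bl=dbl)
        expected = np.sqrt(1000.0 * 1e-4 * d / 0.03 / (1.0 + dbl / d))
        assert deep == pytest.approx(expected, rel=1e-12)

    def test_degenerate_dry_no_boundary_layer(self):
        with pytest.raises(ValueError):
            impact_energy(1000.0, 0.01, 15e-6, 0.03, 0.0, 0.0)

    def test_literal_form_is_alternative_reading(self):
        d = 15e-6
        std = impact_energy(1000.0, 0.01, d, 0.03, d, 5e-6, form="standard")
        lit = impact_energy(1000.0, 0.01, d, 0.03, d, 5e-6, form="literal")
        assert std != pytest.approx(lit)


class TestRegimeMap:
    @pytest.mark.parametrize("E,twall,expected", [
        (10.0, 310.0, Regime.STICK),    # E < 16, cool wall
        (30.0, 310.0, Regime.SPREAD),   # 16 <= E <= 57.7
        (70.0, 310.0, Regime.SPLASH),   # E > 57.7 at any temperature
        (70.0, 400.0, Regime.SPLASH),
        (30.0, 400.0, Regime.REBOUND),  # E < 57.7 above critical temperature
        (10.0, 400.0, Regime.REBOUND),
    ])
    def test_reference_examples(self, E, twall, expected):
        th = ThermalContext(T_wall=twall)
        assert classify_regime(E, th) is expected

    @given(E=st.floats(0.0, 500.0), twall=st.floats(250.0, 600.0))
    @settings(max_examples=300, deadline=None)
    def test_total_and_deterministic(self, E, twall):
        th = ThermalContext(T_wall=twall)
        r1 = classify_regime(E, th)
        r2 = classify_regime(E, th)
        assert r1 is r2
        assert r1 in (Regime.STICK, Regime.REBOUND, Regime.SPREAD, Regime.SPLASH)
        # partition boundaries are exactly 16 / 57.7
        if twall <= critical_temperature(th):
            if E < E_STICK:
                assert r1 is Regime.STICK
            elif E <= E_SPLASH:
                assert r1 is Regime.SPREAD
            else:
                assert r1 is Regime.SPLASH

    def test_rebound_never_fires_in_culture_conditions(self):
        for E in np.linspace(0, 57.7, 100):
            assert classify_regime(E, CULTURE) in (Regime.STICK, Regime.SPREAD)


class TestCriticalTemperature:
    def test_factor_one_equals_saturation(self):
        assert critical_temperature(ThermalContext()) == pytest.approx(373.15)

    def test_factor_1p5(self):
        th = ThermalContext(Tc_star=1.5)
        assert critical_temperature(th) == pytest.approx(559.725)

    def test_linear_in_ts(self):
        a = critical_temperature(ThermalContext(T_s=300.0))
        b = critical_temperature(ThermalContext(T_s=600.0))
        assert b == pytest.approx(2 * a)

    def test_out_of_range_factor(self):
        with pytest.raises(ValueError):
            ThermalContext(Tc_star=0.5)


def _event(regime, v_pn=0.01, element=0):
    return ImpingementEvent(
        particle_id=0, element=element, V_pn=v_pn, E=1.0, delta_bl=1e-5,
        regime=regime, t=0.0, normal=np.array([0.0, 0.0, 1.0]),
        position=np.array([1e-3, 1e-3, 1e-3]))


class TestApplyRegime:
    def test_stick_takes_wall_velocity(self, rng):
        p = CellParticle(0, np.zeros(3), np.array([0.0, 0.0, -0.01]),
                         mass=CELL.mass)
        film = WallFilm(h_o=np.zeros(4), areas=np.full(4, 1e-8))
        out = apply_regime(p, _event(Regime.STICK), film, rng)
        assert out == []
        assert p.status is ParticleStatus.ATTACHED
        assert np.all(p.velocity == 0.0)

    def test_spread_raises_film_height(self, rng):
        """One 15-um cell on a 100x100 um element: dh = (pi/6 d^3)/A."""
        p = CellParticle(0, np.zeros(3), np.zeros(3), mass=CELL.mass)
        area = (100e-6) ** 2
        film = WallFilm(h_o=np.zeros(1), areas=np.array([area]))
        apply_regime(p, _event(Regime.SPREAD), film, rng)
        dh = (np.pi / 6.0) * (15e-6) ** 3 / area
        assert film.h_o[0] == pytest.approx(dh, rel=1e-12)
        assert dh == pytest.approx(1.77e-7, rel=0.01)

    def test_splash_six_equal_fragments_conserve_mass(self, rng):
        p = CellParticle(0, np.zeros(3), np.array([0, 0, -0.1]), mass=CELL.mass)
        film = WallFilm(h_o=np.zeros(1), areas=np.array([1e-8]))
        frags = apply_regime(p, _event(Regime.SPLASH, v_pn=0.1), film, rng)
        assert len(frags) == 6
        assert p.status is ParticleStatus.DEAD_ATTACHED
        masses = [f.mass for f in frags]
        assert np.allclose(masses, CELL.mass / 6.0)
        assert sum(masses) + p.mass == pytest.approx(CELL.mass, rel=1e-12)
        for f in frags:
            assert f.status is ParticleStatus.FRAGMENT
            assert np.dot(f.velocity, [0, 0, 1]) >= 0  # into the flow

    def test_rebound_reverses_normal_velocity(self, rng):
        p = CellParticle(0, np.zeros(3), np.array([0.01, 0.0, -0.02]),
                         mass=CELL.mass)
        film = WallFilm(h_o=np.zeros(1), areas=np.array([1e-8]))
        apply_regime(p, _event(Regime.REBOUND), film, rng, restitution_n=0.9)
        assert p.status is ParticleStatus.SUSPENDED
        assert p.velocity[2] == pytest.approx(0.9 * 0.02)
        assert p.velocity[0] == pytest.approx(0.01)


class TestWellWallReflection:
    CENTER = np.array([5.5e-3, 5.5e-3])
    R = 5.5e-3

    def test_normal_incidence_on_bottom(self):
        pos, vel = reflect_well_wall(
            np.array([5.5e-3, 5.5e-3, -1e-5]), np.array([0.0, 0.0, -0.03]),
            self.CENTER, self.R)
        assert pos[2] == pytest.approx(1e-5)
        assert vel[2] == pytest.approx(0.03)

    def test_tangential_velocity_unchanged(self):
        pos, vel = reflect_well_wall(
            np.array([5.5e-3, 5.5e-3, -1e-5]), np.array([0.02, -0.01, -0.03]),
            self.CENTER, self.R)
        assert vel[0] == pytest.approx(0.02)
        assert vel[1] == pytest.approx(-0.01)

    def test_monte_carlo_containment(self):
        """10^5 random reflective steps never leave the cylinder."""
        rng = np.random.default_rng(99)
        pos = np.array([5.5e-3, 5.5e-3, 7.5e-3])
        vel = rng.normal(0, 0.05, 3)
        for _ in range(100_000):
            pos = pos + vel * 1e-3
            pos, vel = reflect_well_wall(pos, vel, self.CENTER, self.R)
            if rng.uniform() < 0.01:
                vel = rng.normal(0, 0.05, 3)
            r = np.hypot(pos[0] - 5.5e-3, pos[1] - 5.5e-3)
            assert r <= self.R + 1e-12
            assert pos[2] >= -1e-12
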