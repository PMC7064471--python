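"""Cell impingement model (CIM): wall-impact regime physics.

Adapted spray–wall impingement physics (Stanton–Rutland family) applied to
cells striking the scaffold: each impact is classified by a dimensionless
impact energy

    E^2 = (rho V_pn^2 d_p / sigma) * 1 / (min(h_o/d_p, 1) + delta_bl/d_p)

with wall-normal impact speed ``V_pn``, local wall-film height ``h_o`` and
laminar boundary-layer thickness ``delta_bl = d_p / sqrt(Re)``. Regimes:

    stick   E < 16                 cell attaches, keeps its shape, takes
                                   the (zero) wall velocity
    spread  16 <= E <= 57.7        cell attaches and feeds the wall film
    rebound E < 57.7 and           cell leaves intact with reduced normal
            T_wall > T_c           velocity (non-lethal by assumption)
    splash  E > 57.7               cell fragments into 6 equal droplets;
                                   all splash products count as dead

``T_c = Tc* T_s`` is the critical transition temperature (Tc* = 1 by
default, i.e. T_c equals the saturation temperature), so at culture
temperature (37 C wall, far below T_c) the rebound branch never fires and
every scaffold impact is stick or spread.

Well walls are not part of the CIM: they reflect cells specularly and
never trap them; only the scaffold traps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

from .particles import CellParticle, ParticleStatus

__all__ = [
    "Regime",
    "ThermalContext",
    "WallFilm",
    "ImpingementEvent",
    "boundary_layer_thickness",
    "impact_energy",
    "classify_regime",
    "critical_temperature",
    "apply_regime",
    "reflect_well_wall",
    "E_STICK",
    "E_SPLASH",
    "N_SPLASH_FRAGMENTS",
]

#: Regime thresholds on the impact energy.
E_STICK = 16.0
E_SPLASH = 57.7

#: Number of equal droplets a splashing cell separates into.
N_SPLASH_FRAGMENTS = 6


class Regime(IntEnum):
    STICK = 0
    REBOUND = 1
    SPREAD = 2
    SPLASH = 3


@dataclass(frozen=True)
class ThermalContext:
    """Wall/saturation temperatures governing the rebound branch."""

    T_wall: float = 310.15  # K, culture conditions (37 C)
    T_s: float = 373.15  # K, saturation temperature
    Tc_star: float = 1.0  # critical temperature factor, in [1, 1.5]

    def __post_init__(self):
        if not 1.0 <= self.Tc_star <= 1.5:
            raise ValueError("Tc_star must lie in [1, 1.5]")


def critical_temperature(thermal: ThermalContext) -> float:
    """Critical transition temperature T_c = Tc* * T_s (K)."""
    return thermal.Tc_star * thermal.T_s


@dataclass
class WallFilm:
    """Liquid film height per scaffold surface element.

    Elements are coarse surface bins; ``areas`` is the wetted scaffold
    surface area within each element (m^2) and ``h_o`` the accumulated
    film height (m). A pre-wetting height may be applied to elements the
    filling front has already passed.
    """

    h_o: np.ndarray  # (n_elements,), m
    areas: np.ndarray  # (n_elements,), m^2

    def __post_init__(self):
        self.h_o = np.asarray(self.h_o, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(self.h_o < 0):
            raise ValueError("film height must be >= 0")

    def add_volume(self, element: int, volume: float) -> float:
        """Spread ``volume`` (m^3) over an element; returns the new h_o."""
        a = self.areas[element]
        if a > 0:
            self.h_o[element] += volume / a
        return self.h_o[element]


@dataclass
class ImpingementEvent:
    particle_id: int
    element: int  # surface element index (film bin)
    V_pn: float  # wall-normal impact speed (m/s), >= 0
    E: float  # impact energy (dimensionless)
    delta_bl: float  # boundary layer thickness used (m)
    regime: Regime
    t: float  # s
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))


def boundary_layer_thickness(d_p: float, re: float) -> float:
    """delta_bl = d_p / sqrt(Re)."""
    if re <= 0:
        raise ValueError("Re must be > 0")
    return d_p / np.sqrt(re)


def impact_energy(fluid_rho: float, V_pn: float, d_p: float, sigma: float,
                  h_o: float, delta_bl: float, form: str = "standard") -> float:
    """Dimensionless impact energy E of a wall impact.

    ``standard``: E^2 = (rho V^2 d / sigma) / (min(h_o/d, 1) + delta_bl/d),
    the spray-impingement form; a dry wall (h_o = 0) leaves only the
    boundary-layer term in the denominator.

    ``literal``: E^2 = (rho V^2 d / sigma) * (1/min(h_o/d, 1) + delta_bl/d)
    with min(h_o/d, 1) floored at delta_bl/d on a dry wall — kept only for
    sensitivity checks of the typographically ambiguous printed form.
    """
    if d_p <= 0 or sigma <= 0:
        raise ValueError("d_p and sigma must be positive")
    if V_pn < 0 or h_o < 0 or delta_bl < 0:
        raise ValueError("V_pn, h_o, delta_bl must be >= 0")
    we = fluid_rho * V_pn**2 * d_p / sigma
    film = min(h_o / d_p, 1.0)
    bl = delta_bl / d_p
    if form == "standard":
        denom = film + bl
        if denom <= 0:
            raise ValueError("degenerate impact: no film and no boundary layer")
        return float(np.sqrt(we / denom))
    if form == "literal":
        inv = max(film, bl)
        if inv <= 0:
            raise ValueError("degenerate impact: no film and no boundary layer")
        return float(np.sqrt(we * (1.0 / inv + bl)))
    raise ValueError(f"unknown impact-energy form {form!r}")


def classify_regime(E: float, thermal: Optional[ThermalContext] = None) -> Regime:
    """Total, deterministic regime map on (E, wall temperature)."""
    if E < 0:
        raise ValueError("impact energy must be >= 0")
    thermal = thermal or ThermalContext()
    if E > E_SPLASH:
        return Regime.SPLASH
    if thermal.T_wall > critical_temperature(thermal):
        return Regime.REBOUND
    if E < E_STICK:
        return Regime.STICK
    return Regime.SPREAD


def apply_regime(p: CellParticle, event: ImpingementEvent, film: WallFilm,
                 rng: np.random.Generator,
                 restitution_n: float = 0.9, restitution_t: float = 1.0) -> list:
    """Apply the classified regime to a particle; returns new fragments.

    stick   -> status ATTACHED, velocity set to the wall velocity (zero).
    spread  -> ATTACHED; the particle volume is spread over the surface
               element, raising its film height.
    rebound -> stays SUSPENDED; normal velocity reversed with restitution
               ``restitution_n``, tangential scaled by ``restitution_t``.
    splash  -> parent DEAD_ATTACHED; 6 equal-mass FRAGMENT particles are
               emitted into the flow on reflected directions (all counted
               as dead). Total mass is conserved exactly.
    """
    n = event.normal / np.linalg.norm(event.normal)
    if event.regime is Regime.STICK:
        p.status = ParticleStatus.ATTACHED
        p.velocity = np.zeros(3)
        p.position = event.position.copy()
        return []
    if event.regime is Regime.SPREAD:
        p.status = ParticleStatus.ATTACHED
        p.velocity = np.zeros(3)
        p.position = event.position.copy()
        film.add_volume(event.element, _volume_of(p))
        return []
    if event.regime is Regime.REBOUND:
        vn = np.dot(p.velocity, n)
        vt = p.velocity - vn * n
        p.velocity = restitution_t * vt - restitution_n * vn * n
        p.position = event.position + 1e-9 * n
        return []
    # splash
    p.status = ParticleStatus.DEAD_ATTACHED
    p.position = event.position.copy()
    p.velocity = np.zeros(3)
    frag_mass = p.mass / N_SPLASH_FRAGMENTS
    parent_mass = p.mass
    p.mass = 0.0  # mass carried away by the fragments
    speed = max(float(event.V_pn), 1e-6)
    frags = []
    for i in range(N_SPLASH_FRAGMENTS):
        # scatter into the half-space above the wall
        d = rng.normal(size=3)
        d -= min(0.0, np.dot(d, n)) * 2.0 * n / np.dot(n, n)
        d = d / np.linalg.norm(d)
        if np.dot(d, n) < 0.1:
            d = n.copy()
        frags.append(CellParticle(
            id=-1,  # assigned by the caller
            position=event.position + 1e-9 * n,
            velocity=0.5 * speed * d,
            status=ParticleStatus.FRAGMENT,
            mass=frag_mass,
            birth_time=event.t,
        ))
    assert abs(sum(f.mass for f in frags) - parent_mass) < 1e-30
    return frags


def _volume_of(p: CellParticle, rho: float = 1.0e3) -> float:
    return p.mass / rho


def reflect_well_wall(position: np.ndarray, velocity: np.ndarray,
                      well_center_xy: np.ndarray, well_radius: float,
                      restitution: float = 1.0) -> tuple:
    """Specular reflection of a particle that crossed the well boundary.

    Handles the cylindrical side wall and the flat bottom (z = 0); the top
    is open. Position is mirrored about the wall, the normal velocity
    component reversed (scaled by ``restitution``), tangential kept. No
    impingement physics on well walls — they never trap cells.
    """
    pos = position.copy()
    vel = velocity.copy()
    if pos[2] < 0.0:
        pos[2] = -pos[2]
        vel[2] = -restitution * vel[2]
    d = pos[:2] - well_center_xy
    r = np.linalg.norm(d)
    if r > well_radius and r > 0:
        n = d / r
        pos[:2] = well_center_xy + (2.0 * well_radius - r) * n
        vn = np.dot(vel[:2], n)
        vel[:2] -= (1.0 + restitution) * vn * n
    return pos, vel
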