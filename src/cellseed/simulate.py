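"""Coupled seeding simulation: filling flow + cell transport + impingement.

Drives one complete seeding run: medium is injected through the side-wall
inlet of the well while cells enter as Lagrangian particles with the
stream; each flow sub-step the particles are advected through the
interpolated velocity field, collided against the fine scaffold voxel
grid (ray–voxel traversal between successive positions), classified by
the impingement model, and booked as attached / dead / rebounding. Well
walls reflect; only the scaffold traps.

The per-particle inner loop is numba-compiled; particle state lives in
flat arrays (position, velocity, status, mass) with statuses
0 = suspended, 1 = attached (live), 2 = dead attached, 3 = fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import geometry as geo
from .analysis import DEFAULT_BIN_EDGES_MM, SeedingResult, lateral_bin_counts
from .flow import (FluidProperties, WellDomain, advance_flow_step,
                   init_flow, inlet_flow, kozeny_carman_permeability)
from .impingement import E_SPLASH, E_STICK, N_SPLASH_FRAGMENTS, ThermalContext, \
    critical_temperature
from .particles import CellProperties, InjectionSpec, Injector

__all__ = ["SeedingConfig", "run_seeding", "build_domain"]

# status codes shared with particles.ParticleStatus
_SUSPENDED, _ATTACHED, _DEAD, _FRAGMENT = 0, 1, 2, 3


@dataclass
class SeedingConfig:
    """Complete configuration of one seeding run (defaults = study setup)."""

    design: str = "cubic"  # cubic | truncated_octahedron | to
    grid_n: int = 64
    total_time: float = 6.0  # s simulated
    rate_ml: float = 0.5  # injected medium volume (ml)
    inject_s: float = 5.0  # fluid injection duration (s)
    cell_inject_s: float = 5.0  # particle injection duration (s)
    mass_flow_rate: float = 8.18e-10  # kg/s of cells
    seed: int = 1
    scaffold_voxel_um: float = 25.0
    darcy_mode: str = "auto"
    sample_dt: float = 0.05  # s between recorded samples
    sigma_source: str = "cell"  # cell | solution (sigma used in E)
    eq9_form: str = "standard"  # standard | literal
    restitution_n: float = 0.9
    restitution_t: float = 1.0
    drw_rms: float = 0.0  # random-walk RMS velocity (m/s); 0 = off
    prewet_h: float = 1.0e-6  # m film on elements wetted by the front
    fluid: FluidProperties = field(default_factory=FluidProperties)
    cells: CellProperties = field(default_factory=CellProperties)
    thermal: ThermalContext = field(default_factory=ThermalContext)
    well_depth: float = 15e-3
    well_diameter: float = 11e-3
    inlet_diameter: float = 2e-3

    @property
    def rate_m3s(self) -> float:
        return self.rate_ml * 1e-6 / self.inject_s


def build_domain(config: SeedingConfig, model: Optional[geo.ScaffoldModel] = None):
    """Build the scaffold (if not given) and the well domain around it."""
    if model is None:
        spec = geo.default_spec(_canon_design(config.design))
        model = geo.build_scaffold(spec, voxel=config.scaffold_voxel_um * 1e-3)
    metrics = geo.measure_geometry(model)
    perm = kozeny_carman_permeability(
        metrics.porosity_pct / 100.0, metrics.sa_to_v * 1e3
    )
    pore = (model.spec.pore_side_um * 1e-6) if model.spec is not None else None
    domain = WellDomain(
        depth=config.well_depth,
        diameter=config.well_diameter,
        scaffold_occupancy=model.occupancy,
        scaffold_voxel=model.voxel * 1e-3,
        inlet_diameter=config.inlet_diameter,
        darcy_mode=config.darcy_mode,
        pore_size=pore,
        permeability=perm,
    )
    return model, domain, metrics


def _canon_design(design: str) -> str:
    d = design.lower()
    if d in ("to", "truncated_octahedron", "truncated-octahedron"):
        return "truncated_octahedron"
    if d == "cubic":
        return "cubic"
    raise ValueError(f"unknown design {design!r}")


def run_seeding(config: Optional[SeedingConfig] = None,
                model: Optional[geo.ScaffoldModel] = None,
                progress: bool = False) -> SeedingResult:
    """Run one full seeding simulation and aggregate the result.

    Deterministic for a fixed ``config.seed``.
    """
    cfg = config or SeedingConfig()
    rng = np.random.default_rng(cfg.seed)
    model, domain, metrics = build_domain(cfg, model)

    state = init_flow(domain, cfg.fluid, cfg.grid_n)
    inlet_flow(state, cfg.rate_m3s, cfg.inject_s)

    # particle storage (capacity: whole cells + room for splash fragments)
    n_cells_total = int(np.floor(cfg.mass_flow_rate * cfg.cell_inject_s
                                 / cfg.cells.mass + 1e-9))
    cap = (n_cells_total + 16) * (1 + N_SPLASH_FRAGMENTS)
    pos = np.zeros((cap, 3))
    vel = np.zeros((cap, 3))
    status = np.full(cap, -1, dtype=np.int8)  # -1 = not yet injected
    mass = np.zeros(cap)
    attach_t = np.full(cap, np.nan)
    n_alive = np.zeros(1, dtype=np.int64)

    # injection disk just inside the wall at the inlet faces
    i0 = int(state.inlet_faces[:, 0].min())
    inlet_x = state.origin[0] + (i0 + 0.5) * state.h
    inj_spec = InjectionSpec(
        mass_flow_rate=cfg.mass_flow_rate,
        duration=cfg.cell_inject_s,
        inlet_center=np.array([inlet_x, domain.diameter / 2.0, domain.inlet_height]),
        inlet_normal=np.array([1.0, 0.0, 0.0]),
        inlet_radius=domain.inlet_diameter / 2.0,
    )
    injector = Injector(inj_spec, cfg.cells, rng)

    occ = np.ascontiguousarray(model.occupancy.astype(np.uint8))
    s_origin = domain.scaffold_origin
    voxel = domain.scaffold_voxel

    # wall-film elements on the flow grid: exposed scaffold surface per cell
    film_area = _film_areas(occ, voxel, s_origin, state)
    film_h = np.zeros_like(film_area)

    sigma = cfg.cells.sigma_cell if cfg.sigma_source == "cell" \
        else cfg.fluid.sigma_solution
    rebound_on = cfg.thermal.T_wall > critical_temperature(cfg.thermal)
    regime_counts = np.zeros(4, dtype=np.int64)  # stick/rebound/spread/splash
    rng_state = np.array([rng.integers(1, 2**63 - 1)], dtype=np.uint64)

    times, n_inj_s, n_att_s, n_dead_s, m_att_s = [], [], [], [], []
    n_injected = 0
    next_sample = 0.0
    eps = 1e-12
    while state.t < cfg.total_time - eps:
        t0 = state.t
        dt_cap = min(cfg.sample_dt, cfg.total_time - t0)
        # keep particle path per step well under a pore width
        sub = advance_flow_step(state, dt_cap)
        # inject new cells with the stream
        for p in injector.inject(t0, sub, state):
            idx = n_alive[0]
            pos[idx] = p.position
            vel[idx] = p.velocity
            status[idx] = _SUSPENDED
            mass[idx] = p.mass
            n_alive[0] += 1
            n_injected += 1
        # pre-wet film elements reached by the filling front
        if cfg.prewet_h > 0:
            wet = (state.alpha.ravel() > 0.5) & (film_area > 0)
            np.maximum(film_h, np.where(wet, cfg.prewet_h, 0.0), out=film_h)
        _advance_particles(
            pos, vel, status, mass, attach_t, int(n_alive[0]),
            state.u, state.v, state.w, state.alpha, state.origin, state.h,
            occ, s_origin, voxel,
            film_h, film_area, state.shape[1], state.shape[2],
            sub, state.t,
            cfg.fluid.rho_fluid, cfg.fluid.mu, cfg.fluid.g,
            cfg.cells.rho_cell, cfg.cells.d_cell, sigma,
            domain.diameter / 2.0, domain.diameter / 2.0,
            domain.diameter / 2.0, domain.depth,
            E_STICK, E_SPLASH, rebound_on, cfg.restitution_n, cfg.restitution_t,
            cfg.eq9_form == "literal", cfg.drw_rms, rng_state,
            regime_counts, n_alive,
        )
        if state.t >= next_sample - eps or state.t >= cfg.total_time - eps:
            live = status == _ATTACHED
            times.append(state.t)
            n_inj_s.append(n_injected)
            n_att_s.append(int(live.sum()))
            n_dead_s.append(int((status == _DEAD).sum()))
            m_att_s.append(float(mass[live].sum()))
            next_sample += cfg.sample_dt
            if progress:  # pragma: no cover
                print(f"t={state.t:6.3f}s inj={n_injected} att={n_att_s[-1]} "
                      f"cg={state.last_cg_iters}")

    # lateral binning from the injection-side scaffold face (-x side)
    live = status == _ATTACHED
    dead = status == _DEAD
    dist_mm = (pos[:, 0] - s_origin[0]) * 1e3
    bins_live, over_live = lateral_bin_counts(dist_mm[live], DEFAULT_BIN_EDGES_MM)
    bins_dead, over_dead = lateral_bin_counts(dist_mm[dead], DEFAULT_BIN_EDGES_MM)

    result = SeedingResult(
        times=np.array(times),
        injected_count=np.array(n_inj_s),
        attached_count=np.array(n_att_s),
        dead_count=np.array(n_dead_s),
        attached_mass=np.array(m_att_s),
        bin_edges_mm=DEFAULT_BIN_EDGES_MM.copy(),
        bin_counts_live=bins_live,
        bin_counts_dead=bins_dead,
        overflow_live=over_live,
        overflow_dead=over_dead,
        design=_canon_design(cfg.design),
        seed=cfg.seed,
    )
    result.regime_counts = {
        "stick": int(regime_counts[0]),
        "rebound": int(regime_counts[1]),
        "spread": int(regime_counts[2]),
        "splash": int(regime_counts[3]),
    }
    result.flow_state = state
    result.metrics = metrics
    result.particle_positions = pos[: n_alive[0]].copy()
    result.particle_status = status[: n_alive[0]].copy()
    return result


def _film_areas(occ, voxel, s_origin, state) -> np.ndarray:
    """Exposed scaffold surface area (m^2) binned onto flow-grid cells."""
    nx, ny, nz = state.shape
    exposed = np.zeros(occ.shape, dtype=np.int32)
    solid = occ.astype(bool)
    for axis in range(3):
        lo = np.ones(occ.shape, dtype=bool)
        hi = np.ones(occ.shape, dtype=bool)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(1, None)
        sl_hi[axis] = slice(None, -1)
        lo[tuple(sl_lo)] = ~solid[tuple(sl_hi)]
        hi[tuple(sl_hi)] = ~solid[tuple(sl_lo)]
        exposed += (solid & lo).astype(np.int32) + (solid & hi).astype(np.int32)
    idx = np.nonzero(exposed)
    areas = np.zeros(nx * ny * nz)
    if len(idx[0]):
        cx = ((s_origin[0] - state.origin[0] + (idx[0] + 0.5) * voxel)
              / state.h).astype(int)
        cy = ((s_origin[1] - state.origin[1] + (idx[1] + 0.5) * voxel)
              / state.h).astype(int)
        cz = ((s_origin[2] + (idx[2] + 0.5) * voxel) / state.h).astype(int)
        ok = (cx >= 0) & (cx < nx) & (cy >= 0) & (cy < ny) & (cz >= 0) & (cz < nz)
        flat = cx[ok] * ny * nz + cy[ok] * nz + cz[ok]
        np.add.at(areas, flat, exposed[idx][ok] * voxel**2)
    return areas


# ---------------------------------------------------------------------------
# numba core
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _xorshift(state_arr):
    x = state_arr[0]
    x ^= x << np.uint64(13)
    x ^= x >> np.uint64(7)
    x ^= x << np.uint64(17)
    state_arr[0] = x
    return np.float64(x & np.uint64(0xFFFFFFFFFFFF)) / np.float64(0x1000000000000)


@njit(cache=True, fastmath=True)
def _interp_face(fld, rx, ry, rz, h, axis):
    if axis == 0:
        fx, fy, fz = rx / h, ry / h - 0.5, rz / h - 0.5
    elif axis == 1:
        fx, fy, fz = rx / h - 0.5, ry / h, rz / h - 0.5
    elif axis == 2:
        fx, fy, fz = rx / h - 0.5, ry / h - 0.5, rz / h
    else:  # cell-centered field (alpha)
        fx, fy, fz = rx / h - 0.5, ry / h - 0.5, rz / h - 0.5
    nx, ny, nz = fld.shape
    i0 = int(np.floor(fx))
    j0 = int(np.floor(fy))
    k0 = int(np.floor(fz))
    tx = fx - i0
    ty = fy - j0
    tz = fz - k0
    acc = 0.0
    for di in range(2):
        ii = min(max(i0 + di, 0), nx - 1)
        wx = tx if di == 1 else 1.0 - tx
        for dj in range(2):
            jj = min(max(j0 + dj, 0), ny - 1)
            wy = ty if dj == 1 else 1.0 - ty
            for dk in range(2):
                kk = min(max(k0 + dk, 0), nz - 1)
                wz = tz if dk == 1 else 1.0 - tz
                acc += wx * wy * wz * fld[ii, jj, kk]
    return acc


@njit(cache=True, fastmath=True)
def _cd_re(re):
    if re <= 0.1:
        return 24.0
    if re <= 1.0:
        return (3.690 + 22.73 / re + 0.0903 / (re * re)) * re
    if re <= 10.0:
        return (1.222 + 29.1667 / re - 3.8889 / (re * re)) * re
    if re <= 100.0:
        return (0.6167 + 46.50 / re - 116.67 / (re * re)) * re
    if re <= 1000.0:
        return (0.3644 + 98.33 / re - 2778.0 / (re * re)) * re
    return (0.357 + 148.62 / re - 47500.0 / (re * re)) * re


@njit(cache=True, fastmath=True)
def _traverse_scaffold(occ, x0, y0, z0, x1, y1, z1, ox, oy, oz, voxel):
    """First solid voxel hit along the segment; returns (hit, t, axis, sgn).

    ``t`` in [0,1] parametrizes the segment; ``axis``/``sgn`` give the face
    normal crossed (normal = -sgn * e_axis points against the motion).
    """
    nx, ny, nz = occ.shape
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    # segment in grid units
    gx0 = (x0 - ox) / voxel
    gy0 = (y0 - oy) / voxel
    gz0 = (z0 - oz) / voxel
    gx1 = (x1 - ox) / voxel
    gy1 = (y1 - oy) / voxel
    gz1 = (z1 - oz) / voxel
    gdx = gx1 - gx0
    gdy = gy1 - gy0
    gdz = gz1 - gz0
    # clip to grid box
    t0 = 0.0
    t1 = 1.0
    for a in range(3):
        if a == 0:
            p, d, n = gx0, gdx, nx
        elif a == 1:
            p, d, n = gy0, gdy, ny
        else:
            p, d, n = gz0, gdz, nz
        if abs(d) < 1e-300:
            if p < 0.0 or p > n:
                return False, 0.0, 0, 0
        else:
            ta = (0.0 - p) / d
            tb = (n - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 > t1:
        return False, 0.0, 0, 0
    # start point inside grid
    cx = gx0 + gdx * (t0 + 1e-12)
    cy = gy0 + gdy * (t0 + 1e-12)
    cz = gz0 + gdz * (t0 + 1e-12)
    i = int(np.floor(cx))
    j = int(np.floor(cy))
    k = int(np.floor(cz))
    if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
        return False, 0.0, 0, 0
    if occ[i, j, k] == 1:
        return True, t0, 0, 0  # started at/inside solid: immediate hit
    stepx = 1 if gdx > 0 else -1
    stepy = 1 if gdy > 0 else -1
    stepz = 1 if gdz > 0 else -1
    big = 1e300
    tdx = abs(1.0 / gdx) if gdx != 0.0 else big
    tdy = abs(1.0 / gdy) if gdy != 0.0 else big
    tdz = abs(1.0 / gdz) if gdz != 0.0 else big
    nxt_x = ((i + (1 if stepx > 0 else 0)) - gx0) / gdx if gdx != 0.0 else big
    nxt_y = ((j + (1 if stepy > 0 else 0)) - gy0) / gdy if gdy != 0.0 else big
    nxt_z = ((k + (1 if stepz > 0 else 0)) - gz0) / gdz if gdz != 0.0 else big
    t = t0
    while t <= t1:
        if nxt_x <= nxt_y and nxt_x <= nxt_z:
            t = nxt_x
            nxt_x += tdx
            i += stepx
            axis = 0
            sgn = stepx
        elif nxt_y <= nxt_z:
            t = nxt_y
            nxt_y += tdy
            j += stepy
            axis = 1
            sgn = stepy
        else:
            t = nxt_z
            nxt_z += tdz
            k += stepz
            axis = 2
            sgn = stepz
        if t > t1:
            break
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            break
        if occ[i, j, k] == 1:
            return True, t, axis, sgn
    return False, 0.0, 0, 0


@njit(cache=True, fastmath=True)
def _advance_particles(pos, vel, status, mass, attach_t, n,
                       u, v, w, alpha, g_origin, h,
                       occ, s_origin, voxel,
                       film_h, film_area, grid_ny, grid_nz,
                       dt, t_now,
                       rho_f, mu_f, g,
                       rho_c, d_c, sigma,
                       well_cx, well_cy, well_r, depth,
                       e_stick, e_splash, rebound_on, rest_n, rest_t,
                       eq9_literal, drw_rms, rng_state,
                       regime_counts, n_alive):
    mu_air = 1.8e-5
    rho_air = 1.2
    for ip in range(n):
        st = status[ip]
        if st != 0 and st != 3:
            continue
        px = pos[ip, 0]
        py = pos[ip, 1]
        pz = pos[ip, 2]
        rx = px - g_origin[0]
        ry = py - g_origin[1]
        rz = pz - g_origin[2]
        ux = _interp_face(u, rx, ry, rz, h, 0)
        uy = _interp_face(v, rx, ry, rz, h, 1)
        uz = _interp_face(w, rx, ry, rz, h, 2)
        al = _interp_face(alpha, rx, ry, rz, h, 3)
        if al < 0.0:
            al = 0.0
        elif al > 1.0:
            al = 1.0
        if drw_rms > 0.0:
            # Box-Muller fluctuations on the sampled fluid velocity
            u1 = _xorshift(rng_state)
            u2 = _xorshift(rng_state)
            u3 = _xorshift(rng_state)
            u4 = _xorshift(rng_state)
            r1 = np.sqrt(-2.0 * np.log(u1 + 1e-300))
            r2 = np.sqrt(-2.0 * np.log(u3 + 1e-300))
            ux += drw_rms * r1 * np.cos(2.0 * np.pi * u2)
            uy += drw_rms * r1 * np.sin(2.0 * np.pi * u2)
            uz += drw_rms * r2 * np.cos(2.0 * np.pi * u4)
        # alpha-blended carrier properties (liquid <-> air)
        mu_eff = al * mu_f + (1.0 - al) * mu_air
        rho_eff = al * rho_f + (1.0 - al) * rho_air
        vrelx = ux - vel[ip, 0]
        vrely = uy - vel[ip, 1]
        vrelz = uz - vel[ip, 2]
        vrel = np.sqrt(vrelx * vrelx + vrely * vrely + vrelz * vrelz)
        re = rho_eff * vrel * d_c / mu_eff
        cdre = _cd_re(re)
        tau = 4.0 * rho_c * d_c * d_c / (3.0 * mu_eff * cdre)
        geff = -g * (rho_c - rho_eff) / rho_c
        e = np.exp(-dt / tau)
        s = tau * (1.0 - e)
        nvx = ux + (vel[ip, 0] - ux) * e
        nvy = uy + (vel[ip, 1] - uy) * e
        nvz = uz + geff * tau + (vel[ip, 2] - uz - geff * tau) * e
        qx = px + ux * dt + (vel[ip, 0] - ux) * s
        qy = py + uy * dt + (vel[ip, 1] - uy) * s
        qz = pz + (uz + geff * tau) * dt + (vel[ip, 2] - uz - geff * tau) * s
        # scaffold collision along the sub-step segment
        hit, th, axis, sgn = _traverse_scaffold(
            occ, px, py, pz, qx, qy, qz, s_origin[0], s_origin[1], s_origin[2], voxel
        )
        if hit:
            hx = px + (qx - px) * th
            hy = py + (qy - py) * th
            hz = pz + (qz - pz) * th
            # inward surface normal (against the motion across the face)
            nxn = 0.0
            nyn = 0.0
            nzn = 0.0
            if axis == 0:
                nxn = -1.0 * sgn
            elif axis == 1:
                nyn = -1.0 * sgn
            else:
                nzn = -1.0 * sgn
            vdotn = nvx * nxn + nvy * nyn + nvz * nzn
            v_pn = -vdotn if vdotn < 0.0 else 0.0
            # film element on the flow grid
            ei = int((hx - g_origin[0]) / h)
            ej = int((hy - g_origin[1]) / h)
            ek = int((hz - g_origin[2]) / h)
            nyz = grid_ny * grid_nz
            flat = ei * nyz + ej * grid_nz + ek
            if flat < 0 or flat >= film_h.size:
                flat = 0
            h_o = film_h[flat]
            # impact energy
            re_n = rho_f * v_pn * d_c / mu_f
            E = 0.0
            if re_n > 0.0:
                dbl = d_c / np.sqrt(re_n)
                we = rho_f * v_pn * v_pn * d_c / sigma
                filmterm = h_o / d_c
                if filmterm > 1.0:
                    filmterm = 1.0
                blterm = dbl / d_c
                if eq9_literal:
                    inv = filmterm if filmterm > blterm else blterm
                    E = np.sqrt(we * (1.0 / inv + blterm))
                else:
                    E = np.sqrt(we / (filmterm + blterm))
            # regime
            if E > e_splash:
                # splash: parent dies on the wall, 6 equal fragments fly
                regime_counts[3] += 1
                status[ip] = 2
                pos[ip, 0] = hx
                pos[ip, 1] = hy
                pos[ip, 2] = hz
                vel[ip, 0] = 0.0
                vel[ip, 1] = 0.0
                vel[ip, 2] = 0.0
                fm = mass[ip] / 6.0
                mass[ip] = 0.0
                spd = 0.5 * v_pn if v_pn > 1e-9 else 1e-6
                for kf in range(6):
                    # reflected scatter into the half-space above the wall
                    a1 = 2.0 * _xorshift(rng_state) - 1.0
                    a2 = 2.0 * _xorshift(rng_state) - 1.0
                    a3 = _xorshift(rng_state)
                    dxn = a1 + nxn * (1.0 + a3)
                    dyn = a2 + nyn * (1.0 + a3)
                    dzn = nzn * (1.0 + a3)
                    nn = np.sqrt(dxn * dxn + dyn * dyn + dzn * dzn) + 1e-30
                    idx = n_alive[0]
                    if idx < status.size:
                        pos[idx, 0] = hx + 2.0 * voxel * nxn
                        pos[idx, 1] = hy + 2.0 * voxel * nyn
                        pos[idx, 2] = hz + 2.0 * voxel * nzn
                        vel[idx, 0] = spd * dxn / nn
                        vel[idx, 1] = spd * dyn / nn
                        vel[idx, 2] = spd * dzn / nn
                        status[idx] = 3
                        mass[idx] = fm
                        n_alive[0] = idx + 1
            elif rebound_on:
                regime_counts[1] += 1
                # specular with restitution; fragments rebounding stay dead
                vt_x = nvx - vdotn * nxn
                vt_y = nvy - vdotn * nyn
                vt_z = nvz - vdotn * nzn
                vel[ip, 0] = rest_t * vt_x - rest_n * vdotn * nxn
                vel[ip, 1] = rest_t * vt_y - rest_n * vdotn * nyn
                vel[ip, 2] = rest_t * vt_z - rest_n * vdotn * nzn
                pos[ip, 0] = hx + 1e-7 * nxn
                pos[ip, 1] = hy + 1e-7 * nyn
                pos[ip, 2] = hz + 1e-7 * nzn
            else:
                # stick (E < 16) or spread (16 <= E <= 57.7): trapped
                if E < e_stick:
                    regime_counts[0] += 1
                else:
                    regime_counts[2] += 1
                    if film_area[flat] > 0.0:
                        volp = mass[ip] / rho_c
                        film_h[flat] += volp / film_area[flat]
                status[ip] = 2 if st == 3 else 1  # fragments deposit dead
                pos[ip, 0] = hx + 0.5 * voxel * nxn
                pos[ip, 1] = hy + 0.5 * voxel * nyn
                pos[ip, 2] = hz + 0.5 * voxel * nzn
                vel[ip, 0] = 0.0
                vel[ip, 1] = 0.0
                vel[ip, 2] = 0.0
                attach_t[ip] = t_now
            continue
        # no scaffold hit: well-wall reflections (specular, never trapping)
        if qz < 0.0:
            qz = -qz
            nvz = -nvz
        if qz > depth:
            qz = 2.0 * depth - qz
            nvz = -nvz
        ddx = qx - well_cx
        ddy = qy - well_cy
        rr = np.sqrt(ddx * ddx + ddy * ddy)
        if rr > well_r and rr > 0.0:
            nrx = ddx / rr
            nry = ddy / rr
            qx = well_cx + (2.0 * well_r - rr) * nrx
            qy = well_cy + (2.0 * well_r - rr) * nry
            vn = nvx * nrx + nvy * nry
            nvx -= 2.0 * vn * nrx
            nvy -= 2.0 * vn * nry
        pos[ip, 0] = qx
        pos[ip, 1] = qy
        pos[ip, 2] = qz
        vel[ip, 0] = nvx
        vel[ip, 1] = nvy
        vel[ip, 2] = nvz
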