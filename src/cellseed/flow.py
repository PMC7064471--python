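"""Laminar incompressible filling flow in the culture well.

A desk-scale replacement for the commercial VOF solver: the medium is
treated as a laminar, incompressible continuous fluid (continuity
``div u = 0`` plus Navier–Stokes with gravity and viscosity) on a uniform
staggered MAC grid over the cylindrical well, with a liquid volume
fraction ``alpha`` advected conservatively to track the filling front.

Simplifications relative to a full two-phase solver (documented in the
methods note):

* one-fluid approximation — uniform density and viscosity in the momentum
  equation; gravity enters as an ``alpha``-weighted body force so liquid
  sinks through the passive air phase, whose own dynamics are damped;
* no interface surface-tension (CSF) force at this resolution — the
  solution's sigma is used only by the impingement energy;
* scaffold handling is resolution dependent: pores spanning >= 3 grid
  cells are resolved by the no-slip mask, finer lattices become an
  isotropic Darcy drag region with Kozeny–Carman permeability;
* a velocity regularisation clamp bounds the time step of the falling
  injection stream; liquid volume bookkeeping is conservative regardless.

Units are SI (m, s, kg) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "FluidProperties",
    "WellDomain",
    "FlowState",
    "init_flow",
    "advance_flow",
    "inlet_flow",
    "sample_velocity",
    "kozeny_carman_permeability",
    "SolverError",
]

FLUID, SOLID, POROUS = 0, 1, 2


class SolverError(RuntimeError):
    """Pressure solver failed to reach the requested residual."""


@dataclass(frozen=True)
class FluidProperties:
    """Culture-medium properties (defaults: aqueous solution at 37 C)."""

    rho_fluid: float = 1.0e3  # kg/m^3
    mu: float = 1.0e-3  # Pa s
    sigma_solution: float = 0.07  # N/m, used by the impingement energy only
    g: float = 9.81  # m/s^2, acts in -z

    def __post_init__(self):
        for name in ("rho_fluid", "mu", "sigma_solution", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho_fluid


@dataclass
class WellDomain:
    """Cylindrical culture well with the scaffold registered at its bottom.

    The well is ``depth`` deep (z up, bottom at z=0) and ``diameter`` wide;
    medium is injected horizontally through a disk on the side wall at
    ``inlet_height`` (default mid-height). The scaffold occupancy grid
    (fine voxels, solid=True) is centered laterally and sits on the bottom.
    """

    depth: float = 15e-3
    diameter: float = 11e-3
    scaffold_occupancy: Optional[np.ndarray] = None
    scaffold_voxel: float = 25e-6
    inlet_height: Optional[float] = None  # default depth/2
    inlet_diameter: float = 2e-3
    darcy_mode: str = "auto"  # auto | resolved | darcy
    pore_size: Optional[float] = None  # m; used by auto mode
    permeability: Optional[float] = None  # m^2; required in darcy mode

    def __post_init__(self):
        if self.inlet_height is None:
            self.inlet_height = self.depth / 2.0
        if self.scaffold_occupancy is not None:
            ext = np.array(self.scaffold_occupancy.shape) * self.scaffold_voxel
            if ext[0] > self.diameter or ext[1] > self.diameter or ext[2] > self.depth:
                raise ValueError("scaffold does not fit inside the well")

    @property
    def scaffold_origin(self) -> np.ndarray:
        """Lower corner of the scaffold grid in well coordinates (m)."""
        if self.scaffold_occupancy is None:
            return np.zeros(3)
        ext = np.array(self.scaffold_occupancy.shape) * self.scaffold_voxel
        c = self.diameter / 2.0
        return np.array([c - ext[0] / 2.0, c - ext[1] / 2.0, 0.0])


def kozeny_carman_permeability(porosity_fraction: float, specific_surface: float,
                               kozeny_constant: float = 5.0) -> float:
    """Kozeny–Carman permeability (m^2) of a porous lattice.

    ``specific_surface`` is wetted surface per unit *solid* volume (m^-1),
    i.e. the scaffold's SA:V converted to SI.
    """
    eps = porosity_fraction
    if not 0.0 < eps < 1.0:
        raise ValueError("porosity fraction must lie in (0, 1)")
    return eps**3 / (kozeny_constant * (1.0 - eps) ** 2 * specific_surface**2)


@dataclass
class FlowState:
    """Staggered velocity/pressure/volume-fraction fields on the well grid."""

    h: float  # grid spacing (m), uniform
    origin: np.ndarray  # lower corner of the grid (m)
    cell_type: np.ndarray  # (nx,ny,nz) int8: FLUID/SOLID/POROUS
    u: np.ndarray  # (nx+1,ny,nz)
    v: np.ndarray  # (nx,ny+1,nz)
    w: np.ndarray  # (nx,ny,nz+1)
    p: np.ndarray  # (nx,ny,nz)
    alpha: np.ndarray  # (nx,ny,nz)
    t: float = 0.0
    top_open: bool = True
    lid_u: float = 0.0  # +x lid speed when top is closed (validation runs)
    props: FluidProperties = field(default_factory=FluidProperties)
    # inlet: prescribed-velocity faces on the u-grid
    inlet_faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), np.int64))
    inlet_rate: float = 0.0  # m^3/s while t < inlet_duration
    inlet_duration: float = 0.0
    darcy_coeff: float = 0.0  # nu/K (1/s) in POROUS cells
    injected_volume: float = 0.0
    # numerical regularisation / solver knobs
    u_clamp: float = 0.25  # m/s
    air_damping: float = 50.0  # 1/s linear drag in alpha≈0 cells
    cfl: float = 0.6
    poisson_rtol: float = 1.0e-6
    poisson_maxiter: int = 2000
    last_div_inf: float = 0.0
    last_cg_iters: int = 0

    @property
    def shape(self):
        return self.cell_type.shape

    @property
    def liquid_volume(self) -> float:
        """Total liquid volume (m^3) currently on the grid."""
        mask = self.cell_type != SOLID
        return float(self.alpha[mask].sum()) * self.h**3

    @property
    def inlet_area(self) -> float:
        return len(self.inlet_faces) * self.h**2


# ----------------------------------------------------------------------------
# Construction
# ----------------------------------------------------------------------------

def init_flow(domain: WellDomain, props: FluidProperties, grid_n: int = 64) -> FlowState:
    """Build the initial (quiescent, empty) flow state.

    ``grid_n`` cells span the well depth; the lateral extent uses the same
    spacing. Initially ``u = 0``, ``alpha = 0`` (air), ``p = 0``; solid
    cells (well wall and, in resolved mode, scaffold struts) are no-slip.
    """
    h = domain.depth / grid_n
    # +2: one guaranteed solid ring outside the cylinder on each side
    nx = ny = int(np.ceil(domain.diameter / h)) + 2
    nz = grid_n
    origin = np.array([
        domain.diameter / 2.0 - nx * h / 2.0,
        domain.diameter / 2.0 - ny * h / 2.0,
        0.0,
    ])

    xc = origin[0] + (np.arange(nx) + 0.5) * h
    yc = origin[1] + (np.arange(ny) + 0.5) * h
    zc = (np.arange(nz) + 0.5) * h
    cxy = domain.diameter / 2.0
    rr = (xc[:, None] - cxy) ** 2 + (yc[None, :] - cxy) ** 2
    inside = rr <= (domain.diameter / 2.0) ** 2
    cell_type = np.where(inside[:, :, None], FLUID, SOLID).astype(np.int8)
    cell_type = np.ascontiguousarray(np.broadcast_to(cell_type, (nx, ny, nz)).copy())

    darcy_coeff = 0.0
    if domain.scaffold_occupancy is not None:
        occ = domain.scaffold_occupancy
        mode = domain.darcy_mode
        if mode == "auto":
            pore = domain.pore_size
            if pore is None:
                # crude estimate: largest void gap along x at mid-height
                pore = _estimate_pore(occ, domain.scaffold_voxel)
            mode = "resolved" if pore / h >= 3.0 else "darcy"
        frac = _solid_fraction_on_grid(
            occ, domain.scaffold_voxel, domain.scaffold_origin, origin, h, (nx, ny, nz)
        )
        if mode == "resolved":
            cell_type[(frac > 0.5) & (cell_type == FLUID)] = SOLID
        else:
            if domain.permeability is None:
                raise ValueError("darcy mode requires domain.permeability")
            cell_type[(frac > 0.02) & (cell_type == FLUID)] = POROUS
            darcy_coeff = props.nu / domain.permeability

    state = FlowState(
        h=h,
        origin=origin,
        cell_type=cell_type,
        u=np.zeros((nx + 1, ny, nz)),
        v=np.zeros((nx, ny + 1, nz)),
        w=np.zeros((nx, ny, nz + 1)),
        p=np.zeros((nx, ny, nz)),
        alpha=np.zeros((nx, ny, nz)),
        props=props,
        darcy_coeff=darcy_coeff,
    )
    state.inlet_faces = _find_inlet_faces(state, domain)
    return state


def _estimate_pore(occ: np.ndarray, voxel: float) -> float:
    mid = occ[:, :, occ.shape[2] // 2]
    # longest run of void voxels along x, median over y
    runs = []
    for j in range(0, mid.shape[1], max(1, mid.shape[1] // 32)):
        col = mid[:, j]
        best = run = 0
        for s in col:
            run = 0 if s else run + 1
            best = max(best, run)
        if best:
            runs.append(best)
    return float(np.median(runs)) * voxel if runs else 0.0


def _solid_fraction_on_grid(occ, voxel, s_origin, g_origin, h, shape):
    """Average fine-voxel occupancy onto the coarse flow grid."""
    nx, ny, nz = shape
    n = occ.shape
    # index of the coarse cell containing each fine voxel center
    ix = ((s_origin[0] - g_origin[0] + (np.arange(n[0]) + 0.5) * voxel) / h).astype(int)
    iy = ((s_origin[1] - g_origin[1] + (np.arange(n[1]) + 0.5) * voxel) / h).astype(int)
    iz = ((s_origin[2] - g_origin[2] + (np.arange(n[2]) + 0.5) * voxel) / h).astype(int)
    ok_x = (ix >= 0) & (ix < nx)
    ok_y = (iy >= 0) & (iy < ny)
    ok_z = (iz >= 0) & (iz < nz)
    occ_f = occ[ok_x][:, ok_y][:, :, ok_z].astype(np.float64)
    # accumulate with bincount over flattened coarse indices
    flat = (
        ix[ok_x][:, None, None] * ny * nz
        + iy[ok_y][None, :, None] * nz
        + iz[ok_z][None, None, :]
    ).ravel()
    frac_flat = np.bincount(flat, weights=occ_f.ravel(), minlength=nx * ny * nz)
    cnt_flat = np.bincount(flat, minlength=nx * ny * nz)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = frac_flat / np.maximum(cnt_flat, 1)
    return out.reshape(nx, ny, nz)


def _find_inlet_faces(state: FlowState, domain: WellDomain) -> np.ndarray:
    """u-faces on the -x side wall within the inlet disk, pointing into fluid."""
    nx, ny, nz = state.shape
    h = state.h
    cy = domain.diameter / 2.0
    cz = domain.inlet_height
    r = domain.inlet_diameter / 2.0
    faces = []
    for j in range(ny):
        y = state.origin[1] + (j + 0.5) * h
        for k in range(nz):
            z = (k + 0.5) * h
            if (y - cy) ** 2 + (z - cz) ** 2 > r**2:
                continue
            # first fluid cell from the -x side in this (j,k) column
            for i in range(nx):
                if state.cell_type[i, j, k] != SOLID:
                    faces.append((i, j, k))  # u-face at index i (wall side)
                    break
    if not faces:
        raise ValueError("inlet disk does not intersect the fluid domain")
    return np.array(faces, dtype=np.int64)


def inlet_flow(state: FlowState, rate: float, duration: float) -> FlowState:
    """Prescribe a uniform inflow on the inlet disk.

    The normal face velocity is set so the volumetric rate matches exactly:
    ``u_in = rate / (n_faces * h^2)``. After ``duration`` (measured from
    t=0) the inlet closes.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    state.inlet_rate = float(rate)
    state.inlet_duration = float(duration)
    return state


# ----------------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _face_masks(cell_type):
    nx, ny, nz = cell_type.shape
    uo = np.zeros((nx + 1, ny, nz), np.bool_)
    vo = np.zeros((nx, ny + 1, nz), np.bool_)
    wo = np.zeros((nx, ny, nz + 1), np.bool_)
    for i in range(1, nx):
        for j in range(ny):
            for k in range(nz):
                uo[i, j, k] = cell_type[i - 1, j, k] != 1 and cell_type[i, j, k] != 1
    for i in range(nx):
        for j in range(1, ny):
            for k in range(nz):
                vo[i, j, k] = cell_type[i, j - 1, k] != 1 and cell_type[i, j, k] != 1
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                wo[i, j, k] = cell_type[i, j, k - 1] != 1 and cell_type[i, j, k] != 1
    return uo, vo, wo


@njit(cache=True, fastmath=True)
def _predict(u, v, w, un, vn, wn, uo, vo, wo, alpha, cell_type, h, dt, nu, g,
             air_damp, darcy, top_open, lid_u):
    nx, ny, nz = cell_type.shape
    ih = 1.0 / h
    ih2 = ih * ih
    # --- u component ---
    for i in range(1, nx):
        for j in range(ny):
            for k in range(nz):
                if not uo[i, j, k]:
                    un[i, j, k] = 0.0
                    continue
                uc = u[i, j, k]
                # neighbours along x (same component)
                uxm = u[i - 1, j, k]
                uxp = u[i + 1, j, k]
                # y neighbours with tangential wall ghosts
                if j > 0 and uo[i, j - 1, k]:
                    uym = u[i, j - 1, k]
                else:
                    uym = -uc
                if j < ny - 1 and uo[i, j + 1, k]:
                    uyp = u[i, j + 1, k]
                else:
                    uyp = -uc
                if k > 0 and uo[i, j, k - 1]:
                    uzm = u[i, j, k - 1]
                else:
                    uzm = -uc
                if k < nz - 1 and uo[i, j, k + 1]:
                    uzp = u[i, j, k + 1]
                else:
                    uzp = uc if top_open else (2.0 * lid_u - uc)
                vbar = 0.25 * (v[i - 1, j, k] + v[i, j, k] + v[i - 1, j + 1, k] + v[i, j + 1, k])
                wbar = 0.25 * (w[i - 1, j, k] + w[i, j, k] + w[i - 1, j, k + 1] + w[i, j, k + 1])
                adv = uc * ((uc - uxm) * ih if uc > 0.0 else (uxp - uc) * ih)
                adv += vbar * ((uc - uym) * ih if vbar > 0.0 else (uyp - uc) * ih)
                adv += wbar * ((uc - uzm) * ih if wbar > 0.0 else (uzp - uc) * ih)
                visc = nu * (uxm + uxp + uym + uyp + uzm + uzp - 6.0 * uc) * ih2
                af = 0.5 * (alpha[i - 1, j, k] + alpha[i, j, k])
                val = uc + dt * (-adv + visc - air_damp * (1.0 - af) * uc)
                if darcy > 0.0 and (cell_type[i - 1, j, k] == 2 or cell_type[i, j, k] == 2):
                    val /= 1.0 + dt * darcy
                un[i, j, k] = val
    # --- v component ---
    for i in range(nx):
        for j in range(1, ny):
            for k in range(nz):
                if not vo[i, j, k]:
                    vn[i, j, k] = 0.0
                    continue
                vc = v[i, j, k]
                vym = v[i, j - 1, k]
                vyp = v[i, j + 1, k]
                if i > 0 and vo[i - 1, j, k]:
                    vxm = v[i - 1, j, k]
                else:
                    vxm = -vc
                if i < nx - 1 and vo[i + 1, j, k]:
                    vxp = v[i + 1, j, k]
                else:
                    vxp = -vc
                if k > 0 and vo[i, j, k - 1]:
                    vzm = v[i, j, k - 1]
                else:
                    vzm = -vc
                if k < nz - 1 and vo[i, j, k + 1]:
                    vzp = v[i, j, k + 1]
                else:
                    vzp = vc if top_open else -vc
                ubar = 0.25 * (u[i, j - 1, k] + u[i + 1, j - 1, k] + u[i, j, k] + u[i + 1, j, k])
                wbar = 0.25 * (w[i, j - 1, k] + w[i, j - 1, k + 1] + w[i, j, k] + w[i, j, k + 1])
                adv = ubar * ((vc - vxm) * ih if ubar > 0.0 else (vxp - vc) * ih)
                adv += vc * ((vc - vym) * ih if vc > 0.0 else (vyp - vc) * ih)
                adv += wbar * ((vc - vzm) * ih if wbar > 0.0 else (vzp - vc) * ih)
                visc = nu * (vxm + vxp + vym + vyp + vzm + vzp - 6.0 * vc) * ih2
                af = 0.5 * (alpha[i, j - 1, k] + alpha[i, j, k])
                val = vc + dt * (-adv + visc - air_damp * (1.0 - af) * vc)
                if darcy > 0.0 and (cell_type[i, j - 1, k] == 2 or cell_type[i, j, k] == 2):
                    val /= 1.0 + dt * darcy
                vn[i, j, k] = val
    # --- w component ---
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                if not wo[i, j, k]:
                    wn[i, j, k] = 0.0
                    continue
                wc = w[i, j, k]
                wzm = w[i, j, k - 1]
                wzp = w[i, j, k + 1]
                if i > 0 and wo[i - 1, j, k]:
                    wxm = w[i - 1, j, k]
                else:
                    wxm = -wc
                if i < nx - 1 and wo[i + 1, j, k]:
                    wxp = w[i + 1, j, k]
                else:
                    wxp = -wc
                if j > 0 and wo[i, j - 1, k]:
                    wym = w[i, j - 1, k]
                else:
                    wym = -wc
                if j < ny - 1 and wo[i, j + 1, k]:
                    wyp = w[i, j + 1, k]
                else:
                    wyp = -wc
                ubar = 0.25 * (u[i, j, k - 1] + u[i + 1, j, k - 1] + u[i, j, k] + u[i + 1, j, k])
                vbar = 0.25 * (v[i, j, k - 1] + v[i, j + 1, k - 1] + v[i, j, k] + v[i, j + 1, k])
                adv = ubar * ((wc - wxm) * ih if ubar > 0.0 else (wxp - wc) * ih)
                adv += vbar * ((wc - wym) * ih if vbar > 0.0 else (wyp - wc) * ih)
                adv += wc * ((wc - wzm) * ih if wc > 0.0 else (wzp - wc) * ih)
                visc = nu * (wxm + wxp + wym + wyp + wzm + wzp - 6.0 * wc) * ih2
                af = 0.5 * (alpha[i, j, k - 1] + alpha[i, j, k])
                val = wc + dt * (-adv + visc - g * af - air_damp * (1.0 - af) * wc)
                if darcy > 0.0 and (cell_type[i, j, k - 1] == 2 or cell_type[i, j, k] == 2):
                    val /= 1.0 + dt * darcy
                wn[i, j, k] = val


@njit(cache=True, fastmath=True)
def _clamp(u, vmax):
    n = u.size
    f = u.ravel()
    for i in range(n):
        if f[i] > vmax:
            f[i] = vmax
        elif f[i] < -vmax:
            f[i] = -vmax


@njit(cache=True, fastmath=True)
def _divergence(u, v, w, cell_type, h, out):
    nx, ny, nz = cell_type.shape
    ih = 1.0 / h
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type[i, j, k] == 1:
                    out[i, j, k] = 0.0
                else:
                    out[i, j, k] = (
                        (u[i + 1, j, k] - u[i, j, k])
                        + (v[i, j + 1, k] - v[i, j, k])
                        + (w[i, j, k + 1] - w[i, j, k])
                    ) * ih


@njit(cache=True, fastmath=True)
def _apply_laplacian(phi, cell_type, pu, pv, pw, top_open, h, out):
    """out = -div(grad phi) over non-solid cells (SPD with this sign)."""
    nx, ny, nz = cell_type.shape
    ih2 = 1.0 / (h * h)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type[i, j, k] == 1:
                    out[i, j, k] = 0.0
                    continue
                acc = 0.0
                pc = phi[i, j, k]
                if pu[i, j, k]:
                    acc += pc - phi[i - 1, j, k]
                if pu[i + 1, j, k]:
                    acc += pc - phi[i + 1, j, k]
                if pv[i, j, k]:
                    acc += pc - phi[i, j - 1, k]
                if pv[i, j + 1, k]:
                    acc += pc - phi[i, j + 1, k]
                if pw[i, j, k]:
                    acc += pc - phi[i, j, k - 1]
                if pw[i, j, k + 1]:
                    acc += pc - phi[i, j, k + 1]
                if top_open and k == nz - 1:
                    acc += pc  # ghost p = 0 above the open top
                out[i, j, k] = acc * ih2


@njit(cache=True, fastmath=True)
def _build_diag(cell_type, pu, pv, pw, top_open, h):
    """Diagonal of the (negated) pressure Laplacian; 1.0 in solid cells."""
    nx, ny, nz = cell_type.shape
    ih2 = 1.0 / (h * h)
    diag = np.ones((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type[i, j, k] == 1:
                    continue
                c = 0.0
                if pu[i, j, k]:
                    c += 1.0
                if pu[i + 1, j, k]:
                    c += 1.0
                if pv[i, j, k]:
                    c += 1.0
                if pv[i, j + 1, k]:
                    c += 1.0
                if pw[i, j, k]:
                    c += 1.0
                if pw[i, j, k + 1]:
                    c += 1.0
                if top_open and k == nz - 1:
                    c += 1.0
                diag[i, j, k] = c * ih2 if c > 0.0 else 1.0
    return diag


@njit(cache=True, fastmath=True)
def _gs_sweep(z, r, cell_type, pu, pv, pw, diag, h, color):
    """One Gauss-Seidel sweep over cells of parity ``color`` (in place)."""
    nx, ny, nz = cell_type.shape
    ih2 = 1.0 / (h * h)
    for i in range(nx):
        for j in range(ny):
            kstart = (color - (i + j)) % 2
            for k in range(kstart, nz, 2):
                if cell_type[i, j, k] == 1:
                    continue
                acc = r[i, j, k]
                if pu[i, j, k]:
                    acc += ih2 * z[i - 1, j, k]
                if pu[i + 1, j, k]:
                    acc += ih2 * z[i + 1, j, k]
                if pv[i, j, k]:
                    acc += ih2 * z[i, j - 1, k]
                if pv[i, j + 1, k]:
                    acc += ih2 * z[i, j + 1, k]
                if pw[i, j, k]:
                    acc += ih2 * z[i, j, k - 1]
                if pw[i, j, k + 1]:
                    acc += ih2 * z[i, j, k + 1]
                z[i, j, k] = acc / diag[i, j, k]


@njit(cache=True, fastmath=True)
def _masked_dot(a, b, cell_type):
    nx, ny, nz = cell_type.shape
    s = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type[i, j, k] != 1:
                    s += a[i, j, k] * b[i, j, k]
    return s


@njit(cache=True, fastmath=True)
def _coarsen_cell_type(ct):
    """Coarse cell is solid only if every fine child is solid (keeps
    channels open at coarse levels; the scaffold fades from the coarse
    operators, which is fine for a preconditioner)."""
    nx, ny, nz = ct.shape
    cx, cy, cz = (nx + 1) // 2, (ny + 1) // 2, (nz + 1) // 2
    out = np.empty((cx, cy, cz), np.int8)
    for i in range(cx):
        for j in range(cy):
            for k in range(cz):
                all_solid = True
                for di in range(2):
                    for dj in range(2):
                        for dk in range(2):
                            fi = min(2 * i + di, nx - 1)
                            fj = min(2 * j + dj, ny - 1)
                            fk = min(2 * k + dk, nz - 1)
                            if ct[fi, fj, fk] != 1:
                                all_solid = False
                out[i, j, k] = 1 if all_solid else 0
    return out


@njit(cache=True, fastmath=True)
def _restrict_avg(fine, coarse):
    """coarse = average of the 2x2x2 fine children (adjoint of injection)."""
    cx, cy, cz = coarse.shape
    nx, ny, nz = fine.shape
    for i in range(cx):
        for j in range(cy):
            for k in range(cz):
                acc = 0.0
                for di in range(2):
                    for dj in range(2):
                        for dk in range(2):
                            fi = min(2 * i + di, nx - 1)
                            fj = min(2 * j + dj, ny - 1)
                            fk = min(2 * k + dk, nz - 1)
                            acc += fine[fi, fj, fk]
                coarse[i, j, k] = acc * 0.125


@njit(cache=True, fastmath=True)
def _prolong_add(fine, coarse, cell_type_f):
    nx, ny, nz = fine.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type_f[i, j, k] != 1:
                    fine[i, j, k] += coarse[i // 2, j // 2, k // 2]


class _Multigrid:
    """Geometric multigrid V-cycle preconditioner for the masked pressure
    Poisson operator (symmetric: injection/average transfer pair with
    colour-reversed pre/post smoothing)."""

    def __init__(self, cell_type, pu, pv, pw, top_open, h, max_levels=6):
        self.top_open = top_open
        self.levels = []
        ct, hh = cell_type, h
        masks = (pu, pv, pw)
        while True:
            diag = _build_diag(ct, masks[0], masks[1], masks[2], top_open, hh)
            self.levels.append({
                "ct": ct, "pu": masks[0], "pv": masks[1], "pw": masks[2],
                "diag": diag, "h": hh,
                "z": np.zeros(ct.shape), "r": np.zeros(ct.shape),
                "q": np.zeros(ct.shape), "b": np.zeros(ct.shape),
            })
            if len(self.levels) >= max_levels or min(ct.shape) <= 4:
                break
            ct = _coarsen_cell_type(ct)
            hh *= 2.0
            masks = _face_masks(ct)

    def _smooth(self, lv, z, b, colors):
        for c in colors:
            _gs_sweep(z, b, lv["ct"], lv["pu"], lv["pv"], lv["pw"],
                      lv["diag"], lv["h"], c)

    def vcycle(self, b, lvl=0):
        lv = self.levels[lvl]
        z = lv["z"]
        z[:] = 0.0
        if lvl == len(self.levels) - 1:
            for _ in range(10):
                self._smooth(lv, z, b, (0, 1))
            return z
        self._smooth(lv, z, b, (0, 1))
        _apply_laplacian(z, lv["ct"], lv["pu"], lv["pv"], lv["pw"],
                         self.top_open, lv["h"], lv["q"])
        np.subtract(b, lv["q"], out=lv["r"])
        nxt = self.levels[lvl + 1]
        _restrict_avg(lv["r"], nxt["b"])
        zc = self.vcycle(nxt["b"], lvl + 1)
        _prolong_add(z, zc, lv["ct"])
        self._smooth(lv, z, b, (1, 0))
        return z


def _solve_pressure(state: "FlowState", b: np.ndarray) -> tuple:
    """PCG on -Lap(phi) = b with a multigrid V-cycle preconditioner.

    Warm-started from the previous pressure; returns (iters, rel_res).
    Solid-cell entries of all vectors are kept at zero throughout.
    """
    masks = state._masks
    _, _, _, pu, pv, pw, _diag = masks
    mg = getattr(state, "_mg", None)
    if mg is None:
        mg = _Multigrid(state.cell_type, pu, pv, pw, state.top_open, state.h)
        state._mg = mg
    ct = state.cell_type
    fluid = ct != 1
    nfluid = int(fluid.sum())
    phi = state.p
    q = np.zeros_like(b)
    _apply_laplacian(phi, ct, pu, pv, pw, state.top_open, state.h, q)
    r = np.where(fluid, b - q, 0.0)
    if not state.top_open:
        # all-Neumann: project out the constant nullspace component
        r[fluid] -= r[fluid].sum() / nfluid
    bnorm = float(np.linalg.norm(b)) or 1.0
    rnorm = float(np.linalg.norm(r))
    rtol = state.poisson_rtol
    if rnorm <= rtol * bnorm:
        return 0, rnorm / bnorm
    z = mg.vcycle(r).copy()
    if not state.top_open:
        z[fluid] -= z[fluid].sum() / nfluid
    d = z.copy()
    rz = float(np.vdot(r, z))
    it = 0
    while it < state.poisson_maxiter:
        _apply_laplacian(d, ct, pu, pv, pw, state.top_open, state.h, q)
        dq = float(np.vdot(d, q))
        if dq <= 0.0:
            break
        a = rz / dq
        phi += a * d
        r -= a * np.where(fluid, q, 0.0)
        it += 1
        rnorm = float(np.linalg.norm(r))
        if rnorm <= rtol * bnorm:
            break
        z = mg.vcycle(r).copy()
        if not state.top_open:
            z[fluid] -= z[fluid].sum() / nfluid
        rz_new = float(np.vdot(r, z))
        if rz == 0.0:
            break
        d = z + (rz_new / rz) * d
        rz = rz_new
    return it, rnorm / bnorm


@njit(cache=True, fastmath=True)
def _project(u, v, w, phi, pu, pv, pw, cell_type, top_open, h, dt):
    nx, ny, nz = cell_type.shape
    c = dt / h
    for i in range(1, nx):
        for j in range(ny):
            for k in range(nz):
                if pu[i, j, k]:
                    u[i, j, k] -= c * (phi[i, j, k] - phi[i - 1, j, k])
    for i in range(nx):
        for j in range(1, ny):
            for k in range(nz):
                if pv[i, j, k]:
                    v[i, j, k] -= c * (phi[i, j, k] - phi[i, j - 1, k])
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                if pw[i, j, k]:
                    w[i, j, k] -= c * (phi[i, j, k] - phi[i, j, k - 1])
    if top_open:
        for i in range(nx):
            for j in range(ny):
                if cell_type[i, j, nz - 1] != 1:
                    w[i, j, nz] -= c * (0.0 - phi[i, j, nz - 1])


@njit(cache=True, fastmath=True)
def _advect_alpha(alpha, u, v, w, cell_type, h, dt, top_open):
    """Conservative first-order upwind advection of the liquid fraction.

    Returns the liquid volume lost through the open top (normally zero) and
    the volume removed by the [0,1] clip (diagnostic).
    """
    nx, ny, nz = cell_type.shape
    flux = dt / h  # per unit face: alpha-volume change = flux * face_vel
    da = np.zeros((nx, ny, nz))
    # x faces
    for i in range(1, nx):
        for j in range(ny):
            for k in range(nz):
                uf = u[i, j, k]
                if uf == 0.0:
                    continue
                au = alpha[i - 1, j, k] if uf > 0.0 else alpha[i, j, k]
                f = uf * au * flux
                da[i - 1, j, k] -= f
                da[i, j, k] += f
    for i in range(nx):
        for j in range(1, ny):
            for k in range(nz):
                vf = v[i, j, k]
                if vf == 0.0:
                    continue
                av = alpha[i, j - 1, k] if vf > 0.0 else alpha[i, j, k]
                f = vf * av * flux
                da[i, j - 1, k] -= f
                da[i, j, k] += f
    lost_top = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                wf = w[i, j, k]
                if wf == 0.0:
                    continue
                aw = alpha[i, j, k - 1] if wf > 0.0 else alpha[i, j, k]
                f = wf * aw * flux
                da[i, j, k - 1] -= f
                da[i, j, k] += f
            if top_open:
                wf = w[i, j, nz]
                if wf > 0.0:
                    f = wf * alpha[i, j, nz - 1] * flux
                    da[i, j, nz - 1] -= f
                    lost_top += f
    clipped = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type[i, j, k] == 1:
                    continue
                a = alpha[i, j, k] + da[i, j, k]
                if a < 0.0:
                    clipped += a
                    a = 0.0
                elif a > 1.0:
                    clipped += a - 1.0
                    a = 1.0
                alpha[i, j, k] = a
    h3 = h * h * h
    return lost_top * h3, clipped * h3


@njit(cache=True, fastmath=True)
def _max_abs(u, v, w):
    m = 0.0
    uf = u.ravel()
    for i in range(uf.size):
        a = abs(uf[i])
        if a > m:
            m = a
    vf = v.ravel()
    for i in range(vf.size):
        a = abs(vf[i])
        if a > m:
            m = a
    wf = w.ravel()
    for i in range(wf.size):
        a = abs(wf[i])
        if a > m:
            m = a
    return m


# ----------------------------------------------------------------------------
# Time stepping
# ----------------------------------------------------------------------------

def _prepare_masks(state: FlowState):
    uo, vo, wo = _face_masks(state.cell_type)
    # pressure-correction faces = open faces minus prescribed inlet faces
    pu, pv, pw = uo.copy(), vo, wo
    for i, j, k in state.inlet_faces:
        pu[i, j, k] = False
    diag = _build_diag(state.cell_type, pu, pv, pw, state.top_open, state.h)
    return uo, vo, wo, pu, pv, pw, diag


def advance_flow_step(state: FlowState, dt_cap: float) -> float:
    """Take ONE stable sub-step of at most ``dt_cap``; returns the dt taken.

    Sub-step: upwind advection + explicit viscosity + alpha-weighted
    gravity (predictor), prescribed inlet faces, pressure projection
    enforcing the divergence-free constraint, then conservative advection
    of the liquid fraction. Exposed separately so particle tracking can be
    interleaved at the flow's own time resolution.
    """
    if dt_cap <= 0:
        raise ValueError("dt must be positive")
    masks = getattr(state, "_masks", None)
    if masks is None:
        masks = _prepare_masks(state)
        state._masks = masks
    uo, vo, wo, pu, pv, pw, diag = masks
    nu = state.props.nu
    h = state.h
    visc_dt = h * h / (6.0 * nu) if nu > 0 else np.inf
    injecting = state.inlet_rate > 0.0 and state.t < state.inlet_duration - 1e-12
    u_in = state.inlet_rate / state.inlet_area if injecting else 0.0
    vmax = max(_max_abs(state.u, state.v, state.w), abs(u_in), abs(state.lid_u), 1e-9)
    sub = min(dt_cap, state.cfl * h / vmax, 0.5 * visc_dt)
    if injecting:
        # do not step across the inlet shutoff
        sub = min(sub, state.inlet_duration - state.t)
    un = np.zeros_like(state.u)
    vn = np.zeros_like(state.v)
    wn = np.zeros_like(state.w)
    _predict(
        state.u, state.v, state.w, un, vn, wn, uo, vo, wo,
        state.alpha, state.cell_type, h, sub, nu, state.props.g,
        state.air_damping, state.darcy_coeff, state.top_open, state.lid_u,
    )
    for arr in (un, vn, wn):
        _clamp(arr, state.u_clamp)
    for i, j, k in state.inlet_faces:
        un[i, j, k] = u_in
    div = np.empty_like(state.p)
    _divergence(un, vn, wn, state.cell_type, h, div)
    b = -div / sub  # operator is -Laplacian (SPD)
    iters, rres = _solve_pressure(state, b)
    if rres > 100 * state.poisson_rtol and iters >= state.poisson_maxiter:
        raise SolverError(f"pressure CG stalled: rel residual {rres:.2e}")
    _project(un, vn, wn, state.p, pu, pv, pw, state.cell_type, state.top_open, h, sub)
    state.u, state.v, state.w = un, vn, wn
    _divergence(state.u, state.v, state.w, state.cell_type, h, div)
    if injecting:
        # inlet cells legitimately carry the prescribed influx
        for i, j, k in state.inlet_faces:
            div[i, j, k] = 0.0
    state.last_div_inf = float(np.max(np.abs(div)))
    state.last_cg_iters = iters
    # ghost liquid behind the inlet faces: the conservative advection
    # then carries exactly rate*dt of alpha=1 liquid through the inlet
    for i, j, k in state.inlet_faces:
        if i > 0:
            state.alpha[i - 1, j, k] = 1.0 if injecting else 0.0
    lost, _clip = _advect_alpha(
        state.alpha, state.u, state.v, state.w, state.cell_type, h, sub, state.top_open
    )
    if injecting:
        state.injected_volume += u_in * state.inlet_area * sub
    state.t += sub
    return sub


def advance_flow(state: FlowState, dt: float) -> FlowState:
    """Advance the flow by ``dt`` with automatic CFL sub-stepping."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    remaining = dt
    while remaining > 1e-12:
        remaining -= advance_flow_step(state, remaining)
    return state


def sample_velocity(state: FlowState, position) -> np.ndarray:
    """Trilinearly interpolated fluid velocity at a point (m)."""
    pos = np.asarray(position, dtype=float)
    nx, ny, nz = state.shape
    h = state.h
    rel = pos - state.origin
    if np.any(rel < -1e-12) or rel[0] > nx * h or rel[1] > ny * h or rel[2] > nz * h:
        raise ValueError(f"position {pos} outside the flow domain")
    ci = np.clip((rel / h).astype(int), 0, [nx - 1, ny - 1, nz - 1])
    if state.cell_type[ci[0], ci[1], ci[2]] == SOLID:
        return np.zeros(3)
    out = np.empty(3)
    out[0] = _interp_component(state.u, rel, h, 0)
    out[1] = _interp_component(state.v, rel, h, 1)
    out[2] = _interp_component(state.w, rel, h, 2)
    return out


@njit(cache=True, fastmath=True)
def _interp_component(fld, rel, h, axis):
    # staggered: component `axis` lives on faces -> integer coordinate along
    # axis, cell-centered (+0.5) along the other two
    x = rel[0] / h
    y = rel[1] / h
    z = rel[2] / h
    if axis == 0:
        fx, fy, fz = x, y - 0.5, z - 0.5
    elif axis == 1:
        fx, fy, fz = x - 0.5, y, z - 0.5
    else:
        fx, fy, fz = x - 0.5, y - 0.5, z
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


# ----------------------------------------------------------------------------
# Validation helper: closed box (lid-driven cavity etc.)
# ----------------------------------------------------------------------------

def box_state(n: int, size: float, props: FluidProperties, lid_u: float = 0.0,
              liquid: bool = True) -> FlowState:
    """A closed cubic box of side ``size`` with an optional moving top lid.

    Used by validation runs (e.g. the lid-driven cavity); gravity is
    typically disabled by passing props with a tiny ``g`` and uniform
    ``alpha`` so the body force is hydrostatic.
    """
    h = size / n
    cell_type = np.zeros((n, n, n), dtype=np.int8)
    state = FlowState(
        h=h,
        origin=np.zeros(3),
        cell_type=cell_type,
        u=np.zeros((n + 1, n, n)),
        v=np.zeros((n, n + 1, n)),
        w=np.zeros((n, n, n + 1)),
        p=np.zeros((n, n, n)),
        alpha=np.ones((n, n, n)) if liquid else np.zeros((n, n, n)),
        top_open=False,
        lid_u=lid_u,
        props=props,
        air_damping=0.0,
    )
    return state
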