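# Methods

`cellseed` simulates the first hours-equivalent seconds of cell seeding on
3D-printed lattice scaffolds: medium carrying suspended cells is injected
into a culture well holding the scaffold, and every cell–scaffold impact is
classified by spray-impingement physics to decide whether the cell attaches.
This note records the model, its assumptions, the parameter choices, and
what the desk-scale implementation does and does not capture.

## Scaffold geometry

Two unit cells are built parametrically as implicit signed fields, sampled
on a voxel grid (default edge 25 um) and meshed with marching cubes:

* **Cubic cross-link** — three orthogonal families of cylindrical struts
  (diameter 0.5 mm) on a cubic lattice; the open square window between
  struts is the pore (side 1000 um, diagonal `side*sqrt(2)` = 1414 um).
  Lattice period = pore side + strut diameter = 1.5 mm.
* **Truncated octahedron (TO)** — the space-filling 14-faced cell (8
  hexagons, 6 squares) realised as thin shared walls on the faces of a
  body-centered-cubic TO honeycomb, each face pierced by a centered hole.
  The face edge is taken as pore side + 2 x wall margin (240 um + 2 x
  0.1 mm = 0.44 mm), which makes the square holes exactly 240 um and the
  hexagonal holes 240 um per side (long diagonal 480 um). The wall
  thickness is not a published parameter; the default (0.098 mm) is the
  value at which the full 7.9 x 7.9 x 6 mm scaffold reproduces the
  reported structural volume of 60.54 mm^3.

Both scaffolds are tiled into a 7.9 x 7.9 x 6 mm envelope. The cubic
pattern uses a pore-centered phase (strut planes not on the envelope
boundary): this reproduces the reported structural volume within ~1.5%,
whereas a strut-on-boundary phase is ~20% heavier. Metrics:

* porosity = (1 − V_structure/V_overall) x 100%,
* SA:V = S / V_structure,

with V_structure from signed-tetrahedron summation over the watertight
marching-cubes mesh (voxel counting kept as a cross-check) and S the mesh
area, including the flat clip faces at the envelope (switchable).

**Known limitation.** Measured smooth-surface areas land ~10% below the
reported table values for *both* designs while volumes agree within ~2%.
The reported cubic SA:V (8.24 mm^-1) exceeds the theoretical bound for
merged 0.5-mm cylinders (2/r = 8 mm^-1 before node losses), so no merged
cylinder lattice can reach it; the area convention behind the reported
values (possibly a faceted CAD export) is not recoverable. Volumes are
therefore the primary reconstruction target; areas carry this caveat.

## Filling flow

The medium (rho = 1.0e3 kg/m^3, mu = 0.001 Pa s) is treated as a laminar,
incompressible continuous fluid; a liquid volume fraction `alpha` tracks
the filling front (volume-of-fluid style). The solver is a staggered-grid
(MAC) projection method: first-order upwind advection and explicit
viscosity in the predictor, then a pressure Poisson solve (matrix-free
conjugate gradients, relative residual 1e-6, warm-started) enforcing the
divergence-free constraint. The well is a closed cylinder (15 mm deep,
11 mm diameter) with an open top; medium enters through a 2-mm disk on the
side wall at mid-height (the inlet diameter is not published; 2 mm is a
plausible syringe-tip scale). The default grid puts 64 cells across the
well depth (cell ~0.23 mm).

Desk-scale simplifications, all deliberate:

* **One-fluid approximation.** Density and viscosity are uniform in the
  momentum equation; gravity enters as an alpha-weighted body force, so
  liquid sinks through passive air, and pure-air cells are linearly damped
  (50 s^-1). A velocity regularisation clamp (0.25 m/s, roughly the free-
  fall speed over the half-well) bounds the time step of the falling
  injection stream. `alpha` is advected conservatively, so the liquid
  volume on the grid equals the injected volume to well under 1%
  regardless of these regularisations.
* **No interface surface tension (CSF).** At ~0.23-mm cells a curvature
  force is noise-dominated; sigma of the solution (0.07 N/m) is retained
  only where the impingement energy needs it. First-order upwind smears
  the filling front over a few cells; the front position is correct in the
  volume-integral sense.
* **No turbulence model.** The filling flow's Reynolds number is small;
  the laminar equations are solved as stated.
* **Scaffold coupling by resolution.** Pores spanning >= 3 grid cells
  (cubic: 1 mm / 0.23 mm ~ 4.3) are resolved through the no-slip voxel
  mask. Finer lattices (TO: 240-um pores, ~1 cell) become an isotropic
  Darcy drag region with Kozeny–Carman permeability
  `K = eps^3 / (5 (1-eps)^2 S0^2)` computed from the measured porosity and
  specific surface. Particle–strut collisions always use the fine
  (25-um) voxel grid, independent of the flow-side treatment.

Fluid and cell injections last 5 s by default. (The experimental protocol
injects 0.5 ml in 3 s; the simulated injection window is 5 s. Both
durations are independent config values, defaulting to the simulated
setup, so either protocol can be reproduced.)

## Cell transport

Cells are non-rotating spheres (d = 15 um, rho = 1.0e3 kg/m^3 — the rat
MSC assumption) tracked in the Lagrangian frame:

    du_p/dt = (u_f − u_p)/tau_r + g (rho_p − rho_f)/rho_p + F,
    tau_r   = 4 rho_p d^2 / (3 mu C_D Re),  Re = rho_f |u_f − u_p| d / mu,

with the Morsi–Alexander piecewise drag bands for `C_D` (Stokes band
(0, 24, 0) below Re = 0.1, so `C_D Re -> 24` and
`tau_r -> rho_p d^2/(18 mu)` ~ 1.25e-5 s). Because tau_r is orders of
magnitude below any stable flow step, the drag term is integrated with its
exact exponential solution (stable for dt >> tau_r); cells are then
effectively passive tracers with an analytic settling correction. Carrier
properties are blended between liquid and air by the local alpha so that
cells above the front fall at their (fast) air terminal velocity instead
of hanging on spurious water drag. The dispersion term F (discrete random
walk) defaults to off — the laminar field carries no turbulent kinetic
energy to set the fluctuation RMS — and is user-settable.

Cells enter on the inlet disk at the fluid injection point, at the local
fluid velocity, at a mass flow of 8.18e-10 kg/s for 5 s: 2314 whole cells
(the fractional remainder is carried between steps so the count is exact).
Two-way momentum coupling is neglected (the cell phase volume fraction is
tiny).

## Impingement (cell impingement model)

Each particle path segment is traced through the scaffold's 25-um voxel
grid (Amanatides–Woo traversal); on entering a solid voxel the impact is
classified by the dimensionless energy

    E^2 = (rho V_pn^2 d / sigma) / (min(h_o/d, 1) + delta_bl/d),
    delta_bl = d / sqrt(Re_n),  Re_n = rho V_pn d / mu,

with V_pn the wall-normal impact speed, h_o the local wall-film height and
sigma the cell phase's surface tension (0.03 N/m; the impinging entity is
the cell — switchable to the solution's 0.07 N/m). The printed form of the
energy denominator is typographically ambiguous; the standard
spray-impingement reading above is the default and the literal alternative
is kept behind a flag for sensitivity checks.

Regimes: **stick** (E < 16; cell attaches, takes the wall's zero
velocity), **spread** (16 <= E <= 57.7; attaches and feeds the wall film,
raising h_o by cell volume / element area on flow-grid surface elements),
**rebound** (E < 57.7 *and* wall temperature above the critical transition
temperature T_c = Tc* x T_s, Tc* = 1; restitution 0.9 normal / 1.0
tangential, non-lethal by assumption), **splash** (E > 57.7; the cell
separates into six equal droplets, all counted dead). At culture
conditions (37 C wall, T_c = 100 C) the rebound branch cannot fire, and at
the gentle injection speeds of this protocol E stays orders of magnitude
below 16 — every scaffold impact sticks, and no splash occurs, matching
the qualitative behaviour reported for these seeding conditions. Spread cells
are counted live (the reported attached counts make no distinction).

Elements already passed by the filling front (alpha > 0.5) carry a 1-um
pre-wetting film; with E << 16 this choice is inconsequential and is
exposed as a sensitivity flag.

Well walls and the well bottom reflect cells specularly (restitution 1)
and never trap; only the scaffold traps.

## Outputs

Seeding efficiency Phi(t) = 100 N_a(t)/N_i(t) over live attached cells;
attached-mass time series; lateral distribution of attached cells in six
1.3-mm bins from the injection-side scaffold face (half-open intervals),
live and dead separately; Welch's t test for replicate bin comparisons;
plateau detection on Phi(t) (slope < 1 %/s over a 0.2-s trailing window).

## Confocal counting stage

The live/dead image workflow mirrors the experimental analysis: channel
split (Calcein-AM green / PI red), per-channel Otsu threshold (the
experimental threshold is unpublished), erosion (2 px) to etch specks and
adhesion bridges, dilation (3 px) to restore cell bodies, connected-
component labelling, and per-row counting from the inlet side. The
synthetic generator places Gaussian spots of known position/status with
additive noise; because its ground truth is exact, pipeline recovery is
testable without microscope data. Real confocal projections differ in ways
the generator does not emulate — non-uniform background, out-of-focus
haze, intensity variation between cells — so exact-recovery results bound
pipeline errors only for well-separated, well-stained cells.

## Problem sizes and numerical choices

Default runs use the 64-cell-deep grid, 6 s of simulated time and ~2314
cells, matching the reference seeding protocol; unit tests exercise the same code on
coarser grids (24–32 cells, 50–100-um scaffold voxels, shorter horizons)
chosen to probe invariants rather than headline numbers. The pressure
solver runs to relative residual 1e-6; marching-cubes metrics use 25-um
voxels, at which an analytic 0.5-mm cylinder's volume and area are
recovered within 2%. All randomness (injection positions, any dispersion
kicks) flows from a single integer seed; runs are bit-reproducible.

## Known limitations

* The one-fluid filling flow cannot produce sharp jets, droplet pinch-off
  or free-surface waves; attachment totals inherit some dependence on the
  smeared front.
* Wall-film physics is bookkeeping only: no film transport or stripping
  by shear (stripping is likewise absent from the reference workflow).
* The TO construction (wall thickness, hole geometry) is a calibrated
  reconstruction of an under-specified CAD model; surface areas carry the
  ~10% convention gap described above.
* Simulated seconds map to experimental hours only qualitatively; no
  operation attempts that mapping.
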