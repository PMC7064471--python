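"""Output writers: legacy-VTK field snapshots and CSV result tables."""

from __future__ import annotations

import csv

from .analysis import SeedingResult
from .flow import FlowState

__all__ = ["write_vtk_snapshot", "write_results_csv", "write_bins_csv",
           "write_particles_csv"]


def write_vtk_snapshot(state: FlowState, path) -> None:
    """Write u, p, alpha as a legacy ASCII VTK structured-points file.

    Velocity components are averaged from faces to cell centers for
    visualization.
    """
    nx, ny, nz = state.shape
    uc = 0.5 * (state.u[:-1] + state.u[1:])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    wc = 0.5 * (state.w[:, :, :-1] + state.w[:, :, 1:])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cellseed flow snapshot t={state.t:.6f}\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {state.origin[0]} {state.origin[1]} {state.origin[2]}\n")
        fh.write(f"SPACING {state.h} {state.h} {state.h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        for k in range(nz):
            for j in range(ny):
                fh.write(" ".join(f"{state.p[i, j, k]:.6g}" for i in range(nx)) + "\n")
        fh.write("SCALARS alpha double 1\nLOOKUP_TABLE default\n")
        for k in range(nz):
            for j in range(ny):
                fh.write(" ".join(f"{state.alpha[i, j, k]:.6g}" for i in range(nx)) + "\n")
        fh.write("VECTORS velocity double\n")
        for k in range(nz):
            for j in range(ny):
                fh.write(" ".join(
                    f"{uc[i, j, k]:.6g} {vc[i, j, k]:.6g} {wc[i, j, k]:.6g}"
                    for i in range(nx)) + "\n")


def write_results_csv(result: SeedingResult, path) -> None:
    """Time series: t, N_i, N_a, Phi_pct, dead."""
    result.to_frame().to_csv(path, index=False)


def write_bins_csv(result: SeedingResult, path) -> None:
    """Lateral distribution: bin_lo_mm, bin_hi_mm, live, dead."""
    result.bins_frame().to_csv(path, index=False)


def write_particles_csv(result: SeedingResult, path) -> None:
    """Final particle snapshot: id, x, y, z, status."""
    pos = getattr(result, "particle_positions", None)
    status = getattr(result, "particle_status", None)
    if pos is None:
        raise ValueError("result carries no particle snapshot")
    names = {0: "suspended", 1: "attached", 2: "dead_attached", 3: "fragment"}
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "x", "y", "z", "status"])
        for i, (p, s) in enumerate(zip(pos, status)):
            wr.writerow([i, f"{p[0]:.8g}", f"{p[1]:.8g}", f"{p[2]:.8g}", names[int(s)]])
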