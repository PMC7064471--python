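"""Parametric lattice scaffold geometry.

Builds the two scaffold architectures under comparison — a cubic
cross-link lattice of cylindrical struts and a truncated-octahedron (TO)
shell lattice with pierced faces — as implicit signed fields, voxelizes
them, extracts watertight surface meshes, and computes the standard
scaffold metrics:

    porosity = (1 - V_structure / V_overall) * 100%
    SA:V     = S / V_structure          (units mm^-1)

All lengths in this module are millimetres unless a name says otherwise.
The dual representation (boolean voxel occupancy for simulation masking,
triangle mesh for surface area / volume / export) is deliberate: volumes
are computed by signed-tetrahedron summation on the mesh, with voxel
counting retained as a cross-check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
import trimesh
from numba import njit
from skimage import measure as _skmeasure

__all__ = [
    "Design",
    "UnitCellSpec",
    "ScaffoldModel",
    "GeometryMetrics",
    "build_cubic_cell",
    "build_to_cell",
    "build_scaffold",
    "tile_scaffold",
    "measure_geometry",
    "pore_diagonal",
    "export_mesh",
    "import_mesh",
    "write_metrics_csv",
    "InvalidSpecError",
    "MeshIOError",
    "SCAFFOLD_BOX_MM",
]

#: Overall scaffold envelope of the printed parts: length x width x height (mm).
SCAFFOLD_BOX_MM = (7.9, 7.9, 6.0)

#: Default voxel edge (mm); 25 um resolves 0.5-mm struts and ~90-um TO walls.
DEFAULT_VOXEL_MM = 0.025


class InvalidSpecError(ValueError):
    """Raised when a unit-cell specification is geometrically inconsistent."""


class MeshIOError(IOError):
    """Raised for malformed mesh files; carries a byte offset when known."""

    def __init__(self, message: str, byte_offset: Optional[int] = None):
        self.byte_offset = byte_offset
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)


class Design(str, Enum):
    CUBIC = "cubic"
    TRUNCATED_OCTAHEDRON = "truncated_octahedron"


@dataclass(frozen=True)
class UnitCellSpec:
    """Parameters of one lattice unit cell.

    Parameters
    ----------
    design
        ``cubic`` (orthogonal cylindrical struts) or ``truncated_octahedron``
        (shell cell with a centered hole in each of the 14 faces).
    strut_diameter
        Cylinder diameter of the cubic cross-link struts (mm). Default 0.5.
    pore_side_um
        Side length of the open pore (um): the square window of the cubic
        lattice (1000) or the hole side of the TO faces (240).
    wall_offset
        TO only: margin between each hole side and the face edges (mm);
        the face side is ``pore_side + 2 * wall_offset``. Default 0.1.
    wall_thickness
        TO only: full thickness of the face walls (mm). The source design
        does not state it; the default reproduces the reported structural
        volume of the TO scaffold (60.54 mm^3 over a 7.9 x 7.9 x 6 mm box).
    """

    design: Design
    strut_diameter: float = 0.5
    pore_side_um: float = 1000.0
    wall_offset: float = 0.1
    wall_thickness: float = 0.098

    def __post_init__(self):
        object.__setattr__(self, "design", Design(self.design))
        for name in ("strut_diameter", "pore_side_um", "wall_offset", "wall_thickness"):
            if getattr(self, name) <= 0.0:
                raise InvalidSpecError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.design is Design.TRUNCATED_OCTAHEDRON:
            # Hex hole apothem must stay strictly inside the face apothem.
            a = self.face_side
            if np.sqrt(3.0) / 2.0 * self.pore_side_mm >= np.sqrt(3.0) / 2.0 * a:
                raise InvalidSpecError("wall_offset leaves no wall: hole degenerates")

    @property
    def pore_side_mm(self) -> float:
        return self.pore_side_um * 1e-3

    @property
    def face_side(self) -> float:
        """TO face edge length (mm): pore side plus a wall margin on each side."""
        return self.pore_side_mm + 2.0 * self.wall_offset

    @property
    def pitch(self) -> float:
        """Lattice period (mm).

        Cubic: pore side + strut diameter. TO: distance across opposite
        square faces, ``2 * sqrt(2) * face_side`` (the TO honeycomb is
        body-centered cubic with this cube period).
        """
        if self.design is Design.CUBIC:
            return self.pore_side_mm + self.strut_diameter
        return 2.0 * np.sqrt(2.0) * self.face_side


@dataclass
class GeometryMetrics:
    design: str
    V_structure: float  # mm^3
    V_overall: float  # mm^3
    S: float  # mm^2
    porosity_pct: float
    sa_to_v: float  # mm^-1
    max_pore_side_um: float
    max_pore_diagonal_um: float

    def as_row(self) -> dict:
        return {
            "design": self.design,
            "V_mm3": self.V_structure,
            "S_mm2": self.S,
            "porosity_pct": self.porosity_pct,
            "sa_to_v_per_mm": self.sa_to_v,
            "pore_side_um": self.max_pore_side_um,
            "pore_diag_um": self.max_pore_diagonal_um,
        }


@dataclass
class ScaffoldModel:
    """Voxel occupancy + surface mesh of a (possibly clipped) lattice block.

    ``occupancy[i, j, k]`` is True where the material is solid; index order
    is (x, y, z) with voxel centers at ``origin + (index + 0.5) * voxel``.
    ``sdf`` is the generating implicit field (negative inside the solid),
    retained so the model can be re-tiled into a different bounding box.
    """

    occupancy: np.ndarray
    voxel: float
    origin: np.ndarray
    mesh: trimesh.Trimesh
    bounding_box: tuple
    spec: Optional[UnitCellSpec] = None
    sdf: Optional[Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]] = None

    @property
    def solid_volume_voxels(self) -> float:
        """Voxel-count volume estimate (mm^3); cross-check for the mesh volume."""
        return float(self.occupancy.sum()) * self.voxel**3


# ----------------------------------------------------------------------------
# Implicit fields
# ----------------------------------------------------------------------------

def _cubic_field(spec: UnitCellSpec):
    """Signed distance to the cubic cross-link lattice (exact for cylinders).

    Struts of radius r run along all three axes on the lattice lines of a
    cubic grid of period ``pitch``; the open window between parallel struts
    has side ``pitch - 2r = pore_side``.
    """
    pitch = spec.pitch
    r = spec.strut_diameter / 2.0

    def wrap(c):
        u = np.mod(c, pitch)
        return np.minimum(u, pitch - u)

    def f(x, y, z):
        dx, dy, dz = wrap(x), wrap(y), wrap(z)
        d_xstrut = np.hypot(dy, dz)
        d_ystrut = np.hypot(dx, dz)
        d_zstrut = np.hypot(dx, dy)
        return np.minimum(np.minimum(d_xstrut, d_ystrut), d_zstrut) - r

    return f


# In-plane edge normals of the hexagonal hole for the (1,1,1) face; other
# orientations follow by sign flips of the third coordinate pattern.
_HEX_M = np.array([[1.0, 1.0, -2.0], [1.0, -2.0, 1.0], [-2.0, 1.0, 1.0]]) / np.sqrt(6.0)
_HEX_SIGNS = np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1]], dtype=float)


def _to_local_fields(spec: UnitCellSpec):
    """Wall and hole-cut fields of one TO cell centered at the origin."""
    a = spec.face_side
    s = a / np.sqrt(2.0)
    th = spec.wall_thickness / 2.0  # half thickness: shared faces add up to full
    sq_hole_side = spec.face_side - 2.0 * spec.wall_offset  # == pore side
    diamond = sq_hole_side / np.sqrt(2.0)  # |y|+|z| <= diamond inside the hole
    ap_hex = np.sqrt(3.0) / 2.0 * spec.pore_side_mm

    def wall(x, y, z):
        ax, ay, az = np.abs(x), np.abs(y), np.abs(z)
        square = np.maximum(np.maximum(ax, ay), az) - 2.0 * s
        hexa = (ax + ay + az - 3.0 * s) / np.sqrt(3.0)
        sdf_to = np.maximum(square, hexa)
        return np.abs(sdf_to) - th

    def cut(x, y, z):
        # squares: prisms along each axis with diamond cross-section
        ax, ay, az = np.abs(x), np.abs(y), np.abs(z)
        c = np.minimum(np.minimum(ay + az, ax + az), ax + ay) - diamond
        # hexes: 4 prism axes (+-1,+-1,+-1)/sqrt(3) up to sign
        for sgn in _HEX_SIGNS:
            m = _HEX_M * sgn  # flips keep m orthogonal to the flipped axis
            h = np.maximum(
                np.maximum(np.abs(m[0, 0] * x + m[0, 1] * y + m[0, 2] * z),
                           np.abs(m[1, 0] * x + m[1, 1] * y + m[1, 2] * z)),
                np.abs(m[2, 0] * x + m[2, 1] * y + m[2, 2] * z),
            ) - ap_hex
            c = np.minimum(c, h)
        return c

    return wall, cut


def _to_field(spec: UnitCellSpec):
    """Signed field of the space-filling TO shell lattice (BCC sites)."""
    pitch = spec.pitch
    wall, cut = _to_local_fields(spec)

    def one_site(x, y, z, off):
        qx = x - off - pitch * np.round((x - off) / pitch)
        qy = y - off - pitch * np.round((y - off) / pitch)
        qz = z - off - pitch * np.round((z - off) / pitch)
        return np.maximum(wall(qx, qy, qz), -cut(qx, qy, qz))

    def f(x, y, z):
        # corner sites at multiples of pitch, body centers at half offsets
        return np.minimum(one_site(x, y, z, 0.0), one_site(x, y, z, pitch / 2.0))

    return f


def _clip_to_box(f, box, center):
    cx, cy, cz = center
    lx, ly, lz = box

    def g(x, y, z):
        d = np.maximum(
            np.maximum(np.abs(x - cx) - lx / 2.0, np.abs(y - cy) - ly / 2.0),
            np.abs(z - cz) - lz / 2.0,
        )
        return np.maximum(f(x, y, z), d)

    return g


# ----------------------------------------------------------------------------
# Voxelization and meshing
# ----------------------------------------------------------------------------

def _discretize(f, box, voxel: float, spec=None, periodic_sdf=None) -> ScaffoldModel:
    """Sample a signed field over ``box`` (origin at 0) and mesh its 0-level."""
    nx, ny, nz = (max(1, int(round(b / voxel))) for b in box)
    # one-voxel positive padding so marching cubes closes the surface
    xs = (np.arange(-1, nx + 1) + 0.5) * voxel
    ys = (np.arange(-1, ny + 1) + 0.5) * voxel
    zs = (np.arange(-1, nz + 1) + 0.5) * voxel
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    F = f(X, Y, Z).astype(np.float32)
    occupancy = F[1:-1, 1:-1, 1:-1] < 0.0
    if not occupancy.any():
        raise InvalidSpecError("empty intersection of lattice with bounding box")
    verts, faces, _, _ = _skmeasure.marching_cubes(F, level=0.0, spacing=(voxel,) * 3)
    verts = verts + (np.array([-1.0, -1.0, -1.0]) + 0.5) * voxel  # cell-center origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return ScaffoldModel(
        occupancy=occupancy,
        voxel=voxel,
        origin=np.zeros(3),
        mesh=mesh,
        bounding_box=tuple(box),
        spec=spec,
        sdf=periodic_sdf if periodic_sdf is not None else f,
    )


def build_cubic_cell(spec: UnitCellSpec, voxel: float = DEFAULT_VOXEL_MM) -> ScaffoldModel:
    """One cubic cross-link unit cell: three orthogonal strut families.

    The cell spans ``[0, pitch]^3`` with struts along its edges, so the open
    square window between struts has side ``pore_side``.
    """
    if Design(spec.design) is not Design.CUBIC:
        raise InvalidSpecError("build_cubic_cell requires design='cubic'")
    pitch = spec.pitch
    base = _cubic_field(spec)
    f = _clip_to_box(base, (pitch,) * 3, (pitch / 2.0,) * 3)
    return _discretize(f, (pitch,) * 3, voxel, spec, periodic_sdf=base)


def build_to_cell(spec: UnitCellSpec, voxel: float = DEFAULT_VOXEL_MM) -> ScaffoldModel:
    """One truncated-octahedron shell unit cell.

    A cube of side ``pitch`` holding one body-centered TO (plus the corner
    fractions of its neighbours): 14 walls, each pierced by a centered hole
    inset ``wall_offset`` from the face edges — 8 hexagonal holes of side
    ``pore_side`` and 6 square holes.
    """
    if Design(spec.design) is not Design.TRUNCATED_OCTAHEDRON:
        raise InvalidSpecError("build_to_cell requires design='truncated_octahedron'")
    pitch = spec.pitch
    lattice = _to_field(spec)
    # center the body TO in the cell
    half = pitch / 2.0

    def shifted(x, y, z):
        return lattice(x - half, y - half, z - half)

    f = _clip_to_box(shifted, (pitch,) * 3, (half,) * 3)
    return _discretize(f, (pitch,) * 3, voxel, spec, periodic_sdf=shifted)


def build_scaffold(
    spec: UnitCellSpec,
    bounding_box: Sequence[float] = SCAFFOLD_BOX_MM,
    voxel: float = DEFAULT_VOXEL_MM,
) -> ScaffoldModel:
    """Tile the unit cell periodically into ``bounding_box`` and clip.

    The lateral pattern is centered in the box; the pattern starts flush at
    the bottom (z = 0).
    """
    box = tuple(float(b) for b in bounding_box)
    pitch = spec.pitch
    if Design(spec.design) is Design.CUBIC:
        base = _cubic_field(spec)
        # pore-centered phase: strut planes at off + k*pitch, symmetric in the
        # box and not lying on the box boundary (reproduces the printed
        # structural volume; a strut-on-boundary phase is ~20% heavier)
        off = np.array([(b % pitch) / 2.0 + pitch / 2.0 for b in box])
    else:
        lattice = _to_field(spec)
        base = lattice
        # one TO site at the box center, pattern symmetric in all axes
        off = np.array([b / 2.0 for b in box])

    def f(x, y, z):
        return base(x - off[0], y - off[1], z - off[2])

    g = _clip_to_box(f, box, tuple(b / 2.0 for b in box))
    return _discretize(g, box, voxel, spec, periodic_sdf=f)


def tile_scaffold(cell: ScaffoldModel, bounding_box: Sequence[float]) -> ScaffoldModel:
    """Periodic tiling of a unit cell, clipped to ``bounding_box``.

    Models built by this package carry their implicit field, which is
    periodic by construction; tiling re-evaluates it over the target box so
    overlapping struts at cell borders merge exactly (boolean union).
    Imported meshes (no field) are tiled on the voxel grid instead.
    """
    box = tuple(float(b) for b in bounding_box)
    if any(b <= 0 for b in box):
        raise InvalidSpecError("bounding box must be positive")
    if cell.sdf is not None:
        # the stored field is periodic in the cell's own phase, so 1x1x1
        # tiling returns the clipped unit cell unchanged
        g = _clip_to_box(cell.sdf, box, tuple(b / 2.0 for b in box))
        return _discretize(g, box, cell.voxel, cell.spec, periodic_sdf=cell.sdf)
    # voxel-grid tiling fallback
    reps = [int(np.ceil(b / (n * cell.voxel))) for b, n in zip(box, cell.occupancy.shape)]
    tiled = np.tile(cell.occupancy, reps)
    counts = [max(1, int(round(b / cell.voxel))) for b in box]
    tiled = tiled[: counts[0], : counts[1], : counts[2]]
    if not tiled.any():
        raise InvalidSpecError("empty intersection of lattice with bounding box")
    F = np.where(tiled, -1.0, 1.0).astype(np.float32)
    Fp = np.pad(F, 1, constant_values=1.0)
    verts, faces, _, _ = _skmeasure.marching_cubes(Fp, level=0.0, spacing=(cell.voxel,) * 3)
    verts -= cell.voxel * 0.5
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return ScaffoldModel(tiled, cell.voxel, np.zeros(3), mesh, box, None, None)


# ----------------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------------

def porosity_pct(v_structure: float, v_overall: float) -> float:
    """Void fraction of the envelope, in percent."""
    if v_structure <= 0 or v_overall <= 0:
        raise ValueError("volumes must be positive")
    return (1.0 - v_structure / v_overall) * 100.0


def sa_to_v(surface: float, v_structure: float) -> float:
    """Specific surface area S / V (mm^-1)."""
    if v_structure <= 0:
        raise ValueError("structural volume must be positive")
    return surface / v_structure


def pore_diagonal(shape: str, side: float) -> float:
    """Longest diagonal of a pore polygon of the given side length.

    square -> side * sqrt(2); regular hexagon -> 2 * side.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if shape == "square":
        return side * np.sqrt(2.0)
    if shape == "hexagon":
        return 2.0 * side
    raise ValueError(f"unknown pore shape {shape!r}")


def measure_geometry(
    model: ScaffoldModel,
    include_clip_faces: bool = True,
    clip_tol: Optional[float] = None,
) -> GeometryMetrics:
    """Volume, surface, porosity and SA:V of a scaffold model.

    Volume is the signed-tetrahedron volume of the watertight surface mesh;
    surface is the mesh area. By default the flat faces created by clipping
    the lattice at the bounding box count toward S, as they would on the
    printed part; ``include_clip_faces=False`` subtracts triangles lying on
    the box planes.
    """
    if not model.occupancy.any():
        raise ValueError("empty occupancy")
    v_struct = float(abs(model.mesh.volume))
    if v_struct <= 0:
        raise ValueError("zero structural volume")
    area = float(model.mesh.area)
    if not include_clip_faces:
        tol = clip_tol if clip_tol is not None else 1.01 * model.voxel
        tri = model.mesh.triangles
        keep = np.zeros(len(tri), dtype=bool)
        box = np.asarray(model.bounding_box)
        for axis in range(3):
            for plane in (0.0, box[axis]):
                on = np.all(np.abs(tri[:, :, axis] - plane) < tol, axis=1)
                keep |= on
        area -= float(model.mesh.area_faces[keep].sum())
    v_overall = float(np.prod(model.bounding_box))
    if model.spec is not None:
        if Design(model.spec.design) is Design.CUBIC:
            shape, side = "square", model.spec.pore_side_um
        else:
            shape, side = "hexagon", model.spec.pore_side_um
        diag = pore_diagonal(shape, side)
        design = Design(model.spec.design).value
    else:
        side, diag, design = float("nan"), float("nan"), "unknown"
    return GeometryMetrics(
        design=design,
        V_structure=v_struct,
        V_overall=v_overall,
        S=area,
        porosity_pct=porosity_pct(v_struct, v_overall),
        sa_to_v=sa_to_v(area, v_struct),
        max_pore_side_um=side,
        max_pore_diagonal_um=diag,
    )


def write_metrics_csv(path, metrics: Sequence[GeometryMetrics]) -> None:
    rows = [m.as_row() for m in metrics]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


# ----------------------------------------------------------------------------
# STL I/O
# ----------------------------------------------------------------------------

def _validate_stl(path) -> None:
    with open(path, "rb") as fh:
        head = fh.read(84)
        if head[:5] == b"solid" and b"facet" in (head + fh.read(512)):
            return  # ASCII dialect; leave detailed parsing to the loader
        if len(head) < 84:
            raise MeshIOError("truncated STL header", byte_offset=len(head))
        n = int.from_bytes(head[80:84], "little")
        fh.seek(0, 2)
        size = fh.tell()
        expected = 84 + 50 * n
        if size < expected:
            raise MeshIOError(
                f"binary STL declares {n} triangles but file is short", byte_offset=size
            )


def export_mesh(model: ScaffoldModel, path) -> None:
    """Write the surface mesh as binary STL."""
    model.mesh.export(path, file_type="stl")


@njit(cache=True)
def _voxelize_watertight(verts, faces, voxel, nx, ny, nz):
    """Occupancy by z-column ray parity against the triangle soup.

    Column rays pass through voxel centers; crossings below a voxel center
    are counted per triangle (odd count = inside). Adequate for watertight
    meshes whose vertices are in generic position relative to the grid.
    """
    max_hits = 128
    occ = np.zeros((nx, ny, nz), np.bool_)
    hits = np.zeros((nx, max_hits))
    nhits = np.zeros(nx, np.int32)
    # tiny ray offsets break exact vertex/edge-on-column degeneracies
    ex, ey = 1.1e-9 * voxel * nx, 2.3e-9 * voxel * ny
    for j in range(ny):
        nhits[:] = 0
        y = (j + 0.5) * voxel + ey
        for t in range(faces.shape[0]):
            ia, ib, ic = faces[t, 0], faces[t, 1], faces[t, 2]
            ax, ay, az = verts[ia, 0], verts[ia, 1], verts[ia, 2]
            bx, by, bz = verts[ib, 0], verts[ib, 1], verts[ib, 2]
            cx, cy, cz = verts[ic, 0], verts[ic, 1], verts[ic, 2]
            ymin = min(ay, min(by, cy))
            ymax = max(ay, max(by, cy))
            if y < ymin or y > ymax:
                continue
            xmin = min(ax, min(bx, cx))
            xmax = max(ax, max(bx, cx))
            i0 = max(0, int(np.floor(xmin / voxel - 0.5)))
            i1 = min(nx - 1, int(np.ceil(xmax / voxel - 0.5)))
            for i in range(i0, i1 + 1):
                x = (i + 0.5) * voxel + ex
                # barycentric in the xy-projection
                d = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
                if d == 0.0:
                    continue
                l1 = ((by - cy) * (x - cx) + (cx - bx) * (y - cy)) / d
                l2 = ((cy - ay) * (x - cx) + (ax - cx) * (y - cy)) / d
                l3 = 1.0 - l1 - l2
                if l1 < 0.0 or l2 < 0.0 or l3 < 0.0:
                    continue
                z = l1 * az + l2 * bz + l3 * cz
                if nhits[i] < max_hits:
                    hits[i, nhits[i]] = z
                    nhits[i] += 1
        for i in range(nx):
            m = nhits[i]
            if m == 0:
                continue
            zs = np.sort(hits[i, :m])
            for k in range(nz):
                zc = (k + 0.5) * voxel
                below = 0
                for q in range(m):
                    if zs[q] < zc:
                        below += 1
                if below % 2 == 1:
                    occ[i, j, k] = True
    return occ


def import_mesh(path, voxel: float = DEFAULT_VOXEL_MM) -> ScaffoldModel:
    """Load an STL surface (binary or ASCII) and voxelize it.

    The occupancy grid is rebuilt at ``voxel`` resolution from the mesh so
    that imported and parametric scaffolds expose the same dual
    representation.
    """
    _validate_stl(path)
    try:
        mesh = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - loader-specific messages
        raise MeshIOError(f"failed to parse STL: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshIOError("STL contains no triangles")
    mesh.merge_vertices()  # STL stores unwelded triangles
    lo, hi = mesh.bounds
    box = tuple(float(b) for b in (hi - lo))
    shifted = mesh.copy()
    shifted.apply_translation(-lo)
    nx, ny, nz = (max(1, int(round(b / voxel))) for b in box)
    occupancy = _voxelize_watertight(
        np.ascontiguousarray(shifted.vertices, dtype=np.float64),
        np.ascontiguousarray(shifted.faces, dtype=np.int64),
        voxel, nx, ny, nz)
    return ScaffoldModel(
        occupancy=occupancy,
        voxel=voxel,
        origin=np.zeros(3),
        mesh=shifted,
        bounding_box=box,
        spec=None,
        sdf=None,
    )


def table_metrics(design: Design | str, voxel: float = DEFAULT_VOXEL_MM) -> GeometryMetrics:
    """Metrics of the full 7.9 x 7.9 x 6 mm scaffold for a named design."""
    spec = default_spec(design)
    model = build_scaffold(spec, SCAFFOLD_BOX_MM, voxel)
    return measure_geometry(model)


def default_spec(design: Design | str) -> UnitCellSpec:
    """The study's unit-cell parameters for each design."""
    design = Design(design)
    if design is Design.CUBIC:
        return UnitCellSpec(design=Design.CUBIC, strut_diameter=0.5, pore_side_um=1000.0)
    return UnitCellSpec(
        design=Design.TRUNCATED_OCTAHEDRON, pore_side_um=240.0, wall_offset=0.1
    )
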