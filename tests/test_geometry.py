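"""Scaffold geometry: unit cells, tiling, metrics, STL round trips."""

import numpy as np
import pytest

from cellseed import geometry as geo
from cellseed.geometry import (InvalidSpecError, UnitCellSpec,
                               build_cubic_cell, build_scaffold, build_to_cell,
                               export_mesh, import_mesh, measure_geometry,
                               pore_diagonal, porosity_pct, sa_to_v,
                               tile_scaffold)


class TestPoreDiagonal:
    @pytest.mark.parametrize("shape,side,expected", [
        ("square", 1000.0, 1414.2),  # cubic window: side * sqrt(2)
        ("hexagon", 240.0, 480.0),   # hex hole: 2 * side
        ("square", 1.0, np.sqrt(2.0)),
    ])
    def test_values(self, shape, side, expected):
        assert pore_diagonal(shape, side) == pytest.approx(expected, rel=1e-3)

    def test_rejects_unknown_shape_and_bad_side(self):
        with pytest.raises(ValueError):
            pore_diagonal("triangle", 1.0)
        with pytest.raises(ValueError):
            pore_diagonal("square", -1.0)


class TestEquationArithmetic:
    def test_porosity_formula(self):
        # full box -> 0% porosity; half box -> 50%
        assert porosity_pct(374.46, 374.46) == pytest.approx(0.0)
        assert porosity_pct(1.0, 2.0) == pytest.approx(50.0)

    def test_sa_to_v_is_ratio(self):
        assert sa_to_v(598.40, 72.65) == pytest.approx(8.236, abs=1e-3)


class TestCubicCell:
    def test_pitch_is_pore_plus_strut(self, cubic_spec):
        assert cubic_spec.pitch == pytest.approx(1.5)

    def test_window_side_measured_on_voxel_grid(self, cubic_cell):
        """The open square window between struts has side = pore side."""
        occ = cubic_cell.occupancy
        vox = cubic_cell.voxel
        # row along x at mid y, on the bottom strut plane: solid bands at the
        # two bounding struts, void run between them = window side
        row = occ[:, occ.shape[1] // 2, 0]
        # longest void run (in mm)
        best = run = 0
        for s in row:
            run = 0 if s else run + 1
            best = max(best, run)
        assert best * vox == pytest.approx(1.0, abs=3 * vox)

    def test_strut_cross_section_area(self, cubic_cell):
        """Cross-section of a single strut is ~pi r^2 (voxel tolerance)."""
        occ = cubic_cell.occupancy
        vox = cubic_cell.voxel
        # plane normal to x through the cell interior cuts only the four
        # x-direction edge struts: 4 quarter-sections = one full pi r^2
        i = occ.shape[0] // 2
        area = occ[i].sum() * vox**2
        assert area == pytest.approx(np.pi * 0.25**2, rel=0.1)

    def test_unit_cell_porosity_strictly_inside_0_100(self, cubic_cell):
        m = measure_geometry(cubic_cell)
        assert 0.0 < m.porosity_pct < 100.0

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(InvalidSpecError):
            UnitCellSpec(design="cubic", strut_diameter=-0.5)
        with pytest.raises(InvalidSpecError):
            build_to_cell(UnitCellSpec(design="cubic"))


class TestToCell:
    def test_fourteen_pierced_faces(self, to_spec):
        """Every one of the 14 faces carries a centred hole: the field is
        void at each face centre, solid between hole and face edge."""
        from cellseed.geometry import _to_local_fields

        wall, cut = _to_local_fields(to_spec)
        a = to_spec.face_side
        s = a / np.sqrt(2.0)
        centers = []
        for ax in range(3):  # 6 square faces
            for sgn in (-1.0, 1.0):
                c = np.zeros(3)
                c[ax] = sgn * 2.0 * s
                centers.append(c)
        for sx in (-1.0, 1.0):  # 8 hex faces
            for sy in (-1.0, 1.0):
                for sz in (-1.0, 1.0):
                    centers.append(np.array([sx * s, sy * s, sz * s]))
        assert len(centers) == 14
        for c in centers:
            w = wall(c[0], c[1], c[2])
            d = cut(c[0], c[1], c[2])
            assert w <= 0.0  # on the wall surface band
            assert d < 0.0   # inside the hole cut -> pierced

    def test_hole_degenerates_with_large_offset(self):
        with pytest.raises(InvalidSpecError):
            UnitCellSpec(design="truncated_octahedron", pore_side_um=240.0,
                         wall_offset=-0.1)

    def test_cell_porosity_and_watertight(self, to_cell):
        m = measure_geometry(to_cell)
        assert 0.0 < m.porosity_pct < 100.0
        assert to_cell.mesh.is_watertight


class TestMeasureGeometry:
    def test_full_box_porosity_zero(self):
        """A solid filling its whole bounding box has ~0% porosity."""
        from cellseed.geometry import _discretize

        def solid_box(x, y, z):
            return np.maximum(np.maximum(np.abs(x - 0.5) - 0.5,
                                         np.abs(y - 0.5) - 0.5),
                              np.abs(z - 0.5) - 0.5)

        m = measure_geometry(_discretize(solid_box, (1.0, 1.0, 1.0), 0.05))
        assert m.porosity_pct == pytest.approx(0.0, abs=1.0)

    def test_voxel_count_cross_checks_mesh_volume(self, cubic_cell):
        m = measure_geometry(cubic_cell)
        assert cubic_cell.solid_volume_voxels == pytest.approx(
            m.V_structure, rel=0.05)

    def test_scaling_invariance(self):
        """Scaling by k: V x k^3, S x k^2, SA:V / k."""
        base = UnitCellSpec(design="cubic", strut_diameter=0.5, pore_side_um=1000.0)
        k = 2.0
        scaled = UnitCellSpec(design="cubic", strut_diameter=0.5 * k,
                              pore_side_um=1000.0 * k)
        m1 = measure_geometry(build_cubic_cell(base, voxel=0.05))
        m2 = measure_geometry(build_cubic_cell(scaled, voxel=0.05 * k))
        assert m2.V_structure == pytest.approx(k**3 * m1.V_structure, rel=0.01)
        assert m2.S == pytest.approx(k**2 * m1.S, rel=0.01)
        assert m2.sa_to_v == pytest.approx(m1.sa_to_v / k, rel=0.01)

    def test_cylinder_voxel_convergence(self):
        """Analytic cylinder d=0.5 mm: V and S within 2% at 25-um voxels."""
        r, L = 0.25, 2.0

        def f(x, y, z):
            d_side = np.hypot(x - 1.0, y - 1.0) - r
            return np.maximum(d_side, np.maximum(z - L, -z))

        from cellseed.geometry import _discretize
        model = _discretize(f, (2.0, 2.0, L), 0.025)
        m = measure_geometry(model)
        v_true = np.pi * r**2 * L
        s_true = 2 * np.pi * r * L + 2 * np.pi * r**2
        assert m.V_structure == pytest.approx(v_true, rel=0.02)
        assert m.S == pytest.approx(s_true, rel=0.02)


class TestTiling:
    def test_identity_tiling(self, cubic_spec, cubic_cell):
        tiled = tile_scaffold(cubic_cell, (cubic_spec.pitch,) * 3)
        assert tiled.occupancy.shape == cubic_cell.occupancy.shape
        assert (tiled.occupancy == cubic_cell.occupancy).mean() > 0.999

    def test_periodic_block_preserves_porosity(self, cubic_spec, cubic_cell):
        p = cubic_spec.pitch
        m1 = measure_geometry(build_scaffold(cubic_spec, (2 * p, 2 * p, 2 * p),
                                             voxel=0.05))
        m2 = measure_geometry(build_scaffold(cubic_spec, (3 * p, 3 * p, 3 * p),
                                             voxel=0.05))
        assert m1.porosity_pct == pytest.approx(m2.porosity_pct, abs=0.5)

    def test_scaffold_width_holds_five_full_cells(self, cubic_spec):
        """floor(7.9 / 1.5) = 5 windows across a mid-height section."""
        model = build_scaffold(cubic_spec, voxel=0.05)
        occ = model.occupancy
        k = int(1.5 / 0.05)  # z mid-way between strut planes (0.75, 2.25)
        row = occ[:, occ.shape[1] // 2, k]
        # count distinct void runs longer than half a pore
        runs, run = [], 0
        for s in row:
            if s:
                if run:
                    runs.append(run)
                run = 0
            else:
                run += 1
        if run:
            runs.append(run)
        big = [r for r in runs if r * 0.05 > 0.5]
        assert len(big) == 6  # 5 interior windows + clipped edge pores

    def test_empty_intersection_raises(self, cubic_spec):
        cell = build_cubic_cell(cubic_spec, voxel=0.1)
        with pytest.raises(InvalidSpecError):
            tile_scaffold(cell, (0.0, 1.0, 1.0))


class TestStlIO(object):
    def test_round_trip_triangle_count_and_metrics(self, tmp_path, cubic_spec):
        model = build_cubic_cell(cubic_spec, voxel=0.1)
        path = tmp_path / "cell.stl"
        export_mesh(model, path)
        back = import_mesh(path, voxel=0.1)
        assert len(back.mesh.faces) == len(model.mesh.faces)
        assert back.mesh.is_watertight == model.mesh.is_watertight
        np.testing.assert_allclose(
            np.sort(back.mesh.area_faces)[-10:],
            np.sort(model.mesh.area_faces)[-10:], rtol=1e-6)

    def test_unit_cube_round_trip(self, tmp_path):
        import trimesh
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        cube.apply_translation([0.5, 0.5, 0.5])
        p = tmp_path / "cube.stl"
        cube.export(p, file_type="stl")
        back = import_mesh(p, voxel=0.05)
        assert abs(back.mesh.volume) == pytest.approx(1.0, rel=1e-6)
        assert back.mesh.area == pytest.approx(6.0, rel=1e-6)

    def test_malformed_stl_reports_offset(self, tmp_path):
        from cellseed.geometry import MeshIOError
        p = tmp_path / "bad.stl"
        # binary header declaring many triangles, truncated body
        p.write_bytes(b"\x00" * 80 + (1000).to_bytes(4, "little") + b"\x00" * 10)
        with pytest.raises(MeshIOError) as err:
            import_mesh(p)
        assert err.value.byte_offset is not None
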