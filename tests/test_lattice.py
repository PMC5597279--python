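"""Tri-cylinder pore cell geometry: analytic porosity, voxel oracle, inversion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stiffmatch.lattice import (
    PlateSolid,
    UnitCell,
    adequate_resolution,
    connected_components,
    interior_porosity,
    max_porosity,
    plate_indicator,
    porosity_analytic,
    porosity_sweep_table,
    porosity_voxel,
    solve_cell_for_porosity,
    solve_diameter_for_porosity,
    voxel_indicator,
    voxelize_unit_cell,
)


class TestAnalyticPorosity:
    def test_no_channels_no_porosity(self):
        assert porosity_analytic(UnitCell(d=0.0, a=1.0)) == 0.0

    def test_full_diameter_steinmetz_value(self):
        # inclusion-exclusion with bicylinder 16 r^3/3 and tricylinder
        # 8 (2 - sqrt 2) r^3 at d = a = 1:
        # 3 pi/4 - 2 + (2 - sqrt 2) = 0.941981
        assert porosity_analytic(UnitCell(d=1.0, a=1.0)) == pytest.approx(
            0.9419809278, abs=1e-9
        )
        assert max_porosity() == pytest.approx(0.9419809278, abs=1e-9)

    def test_protruding_cylinders_rejected(self):
        with pytest.raises(ValueError, match="protrude"):
            UnitCell(d=1.2, a=1.0)

    def test_strut_convention_flag_complements(self):
        void = UnitCell(d=0.8, a=1.0, cylinders_are_voids=True)
        strut = UnitCell(d=0.8, a=1.0, cylinders_are_voids=False)
        assert porosity_analytic(void) + porosity_analytic(strut) == pytest.approx(1.0)

    @given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_strictly_increasing_in_diameter(self, r1, r2):
        lo, hi = sorted((r1, r2))
        if hi - lo < 1e-6:
            return
        a = 1.3
        assert porosity_analytic(UnitCell(d=hi * a, a=a)) > porosity_analytic(
            UnitCell(d=lo * a, a=a)
        )

    @given(st.floats(1.0, 5.0), st.floats(1.05, 5.0))
    def test_strictly_decreasing_in_cell_edge(self, a1, a2):
        lo, hi = sorted((a1, a2))
        if hi - lo < 1e-6:
            return
        assert porosity_analytic(UnitCell(d=1.0, a=hi)) < porosity_analytic(
            UnitCell(d=1.0, a=lo)
        )


class TestInversion:
    def test_bone_matched_cell_edge(self):
        # 1 mm channels at 45.7% void fraction need a ~1.87 mm cell
        cell = solve_cell_for_porosity(1.0, 0.457)
        assert cell.a == pytest.approx(1.8714, abs=2e-3)
        assert porosity_analytic(cell) == pytest.approx(0.457, abs=1e-9)

    def test_zero_target_degenerate(self):
        cell = solve_cell_for_porosity(1.0, 0.0)
        assert cell.d == 0.0

    def test_unattainable_target(self):
        with pytest.raises(ValueError, match="porosity"):
            solve_cell_for_porosity(1.0, 0.99)

    @given(st.floats(0.01, 0.94))
    def test_round_trip(self, target):
        cell = solve_cell_for_porosity(1.0, target)
        assert porosity_analytic(cell) == pytest.approx(target, abs=1e-6)
        dual = solve_diameter_for_porosity(cell.a, target)
        assert dual.d == pytest.approx(cell.d, rel=1e-6)


class TestVoxelization:
    def test_voxel_oracle_matches_analytic(self):
        # discretization oracle: < 0.5% absolute at 64 voxels per edge
        for target in (0.457, 0.783, 0.9420):
            cell = solve_cell_for_porosity(1.0, target) if target < 0.94 else UnitCell(1.0, 1.0)
            assert abs(porosity_voxel(cell, 64) - porosity_analytic(cell)) < 0.005

    def test_convergence_with_resolution(self):
        cell = solve_cell_for_porosity(1.0, 0.457)
        errs = [
            abs(porosity_voxel(cell, r) - porosity_analytic(cell))
            for r in (16, 32, 64, 128)
        ]
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.003

    def test_resolution_floor(self):
        with pytest.raises(ValueError, match="resolution"):
            porosity_voxel(UnitCell(), 4)

    def test_mirror_symmetry(self):
        solid = voxel_indicator(solve_cell_for_porosity(1.0, 0.457), 32)
        for ax in range(3):
            assert np.array_equal(solid, np.flip(solid, axis=ax))

    def test_dense_cell_all_solid(self):
        mesh = voxelize_unit_cell(UnitCell(d=0.0, a=1.0), 8)
        assert mesh.n_elems == 8**3

    def test_solid_fraction_of_bone_matched_cell(self):
        mesh = voxelize_unit_cell(solve_cell_for_porosity(1.0, 0.457), 48)
        assert mesh.n_elems / 48**3 == pytest.approx(1 - 0.457, abs=0.01)

    def test_under_resolved_signal(self):
        cell = solve_cell_for_porosity(1.0, 0.783)  # 0.25 mm struts
        with pytest.raises(ValueError, match="under-resolved"):
            voxelize_unit_cell(cell, 12)

    def test_adequate_resolution_rule(self):
        cell = solve_cell_for_porosity(1.0, 0.457)
        res = adequate_resolution(cell)
        h = cell.a / res
        assert (cell.a - cell.d) / h >= 4.0
        assert res >= 12

    def test_voxel_cell_connected(self):
        solid = voxel_indicator(solve_cell_for_porosity(1.0, 0.7), 32)
        assert connected_components(solid) == 1


class TestPlate:
    def test_inferior_plate_shell_is_dense(self):
        # 78 x 4 x 1.5 mm plate; 0.2 mm shell must close every boundary layer
        plate = PlateSolid(size=(78.0, 4.0, 1.5), cell=UnitCell(d=1.0, a=1.87), shell=0.2)
        solid = plate_indicator(plate, h=0.1)
        for ax in range(3):
            assert np.all(np.take(solid, 0, axis=ax))
            assert np.all(np.take(solid, -1, axis=ax))
        assert np.all(np.take(solid, 1, axis=2))  # 0.2 mm = 2 voxel layers

    def test_interior_porosity_near_cell_porosity(self):
        cell = solve_cell_for_porosity(1.0, 0.457)
        plate = PlateSolid(size=(20.0, 8.0, 8.0), cell=cell, shell=0.2)
        interior, whole = interior_porosity(plate, h=0.05)
        assert interior == pytest.approx(0.457, abs=0.03)
        assert whole < interior  # the dense shell lowers the total porosity

    def test_screw_holes_removed(self):
        cell = solve_cell_for_porosity(1.0, 0.457)
        base = PlateSolid(size=(18.0, 2.8, 6.0), cell=cell, shell=0.2)
        holed = PlateSolid(
            size=(18.0, 2.8, 6.0), cell=cell, shell=0.2,
            screw_holes=((9.0, 3.0),), screw_axis=1,
        )
        s0 = plate_indicator(base, h=0.1)
        s1 = plate_indicator(holed, h=0.1)
        assert s1.sum() < s0.sum()
        assert np.all(s0[~s1 & s0])  # holes only remove material

    def test_thin_plate_rejected(self):
        with pytest.raises(ValueError, match="shell"):
            PlateSolid(size=(10.0, 4.0, 0.3), shell=0.2)


def test_sweep_table_monotone():
    t = porosity_sweep_table(d=1.0, n=20)
    p = t["porosity"].to_numpy()
    assert np.all(np.diff(p) > 0)
    assert p[0] == 0.0 and p[-1] == pytest.approx(max_porosity())
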