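"""Voxel FE solver: patch test, equilibrium, interfaces, superelastic stepping."""

import numpy as np
import pytest

from conftest import make_compression_load
from stiffmatch.fe import (
    Interface,
    LoadCase,
    VoxelMesh,
    assemble_and_solve_linear,
    solve_incremental_sma,
    tie_and_contact_interface,
    von_mises,
)
from stiffmatch.lattice import solve_cell_for_porosity, voxelize_unit_cell
from stiffmatch.materials import LinearElastic


def solid_mesh(n, spacing=1.0):
    return VoxelMesh(np.zeros((n, n, n), dtype=np.int32), spacing=spacing)


def affine_load(mesh, F):
    """Prescribe an affine displacement u = F x on every boundary node."""
    c = mesh.coords
    lo, hi = c.min(axis=0), c.max(axis=0)
    on_bound = np.any((np.abs(c - lo) < 1e-9) | (np.abs(c - hi) < 1e-9), axis=1)
    nodes = np.nonzero(on_bound)[0]
    u = c[nodes] @ np.asarray(F).T
    # one single-node set per node and component
    dirichlet = [
        (np.array([nid]), comp, float(val))
        for nid, row in zip(nodes, u)
        for comp, val in enumerate(row)
    ]
    return LoadCase(dirichlet=dirichlet)


class TestLinear:
    def test_patch_test_uniform_strain_exact(self, ti):
        # affine boundary displacements on a fully solid mesh must reproduce
        # the uniform strain state to machine precision (direct solver)
        mesh = solid_mesh(4, spacing=0.5)
        F = np.array([[1e-3, 2e-4, 0.0], [2e-4, -3e-4, 1e-4], [0.0, 1e-4, 5e-4]])
        res = assemble_and_solve_linear(mesh, {0: LinearElastic(E=ti.E, nu=0.3)}, affine_load(mesh, F))
        vm = res.vm
        assert np.ptp(vm) / vm.mean() < 1e-10
        # sym(F) in engineering Voigt [xx, yy, zz, yz, xz, xy]
        eps_exact = np.array([1e-3, -3e-4, 5e-4, 2e-4, 0.0, 4e-4])
        assert np.allclose(res.strain, eps_exact, rtol=1e-10, atol=1e-14)

    def test_single_voxel_uniaxial_titanium(self, ti):
        mesh = solid_mesh(1)
        load = make_compression_load(mesh, 1.0, -1e-3)  # tension 0.1%
        res = assemble_and_solve_linear(mesh, {0: ti}, load)
        # frictionless platens on one voxel give the exact uniaxial stress state
        assert res.stress[0, 2] == pytest.approx(112000 * 1e-3, rel=1e-9)
        assert np.allclose(res.stress[0, :2], 0, atol=1e-6)

    def test_equilibrium_of_reactions(self, ti):
        mesh = solid_mesh(6)
        bottom = mesh.face_nodes(2, 0)
        top = mesh.face_nodes(2, 1)
        load = LoadCase(
            dirichlet=[(bottom, c, 0.0) for c in range(3)],
            forces=[(top, 2, -500.0)],
        )
        res = assemble_and_solve_linear(mesh, {0: ti}, load)
        assert res.reactions[2] == pytest.approx(500.0, rel=1e-6)

    def test_energy_balance(self, ti):
        mesh = solid_mesh(5)
        load = make_compression_load(mesh, 5.0, 0.01)
        res = assemble_and_solve_linear(mesh, {0: ti}, load)
        assert res.external_work == pytest.approx(res.strain_energy, rel=0.01)

    def test_axis_permutation_symmetry(self, niti):
        # loading the symmetric porous cell along z or x gives the same
        # spectrum of element stresses
        cell = solve_cell_for_porosity(1.0, 0.457)
        mesh = voxelize_unit_cell(cell, 12)
        lin = LinearElastic(E=niti.E_A_mpa, nu=niti.nu)
        vms = []
        for ax in (2, 0):
            lo = mesh.face_nodes(ax, 0)
            hi = mesh.face_nodes(ax, 1)
            others = [i for i in range(3) if i != ax]
            pins = [
                (lo[:1], others[0], 0.0),
                (lo[:1], others[1], 0.0),
                (lo[-1:], others[1], 0.0),
            ]
            load = LoadCase(
                dirichlet=[(hi, ax, -0.01 * cell.a), (lo, ax, 0.0)] + pins
            )
            res = assemble_and_solve_linear(mesh, {0: lin}, load)
            vms.append(np.sort(res.vm))
        assert np.allclose(vms[0], vms[1], rtol=1e-6)

    def test_mesh_refinement_stability(self, niti):
        # equivalent modulus of the porous cell changes < 2% under 2x refinement
        from stiffmatch.homogenize import equivalent_modulus_gpa

        cell = solve_cell_for_porosity(1.0, 0.457)
        e1 = equivalent_modulus_gpa(cell, niti, resolution=12)
        e2 = equivalent_modulus_gpa(cell, niti, resolution=24)
        assert e1 == pytest.approx(e2, rel=0.02)

    def test_under_constrained_signal(self, ti):
        mesh = solid_mesh(3)
        with pytest.raises(ValueError, match="constrained"):
            assemble_and_solve_linear(
                mesh, {0: ti}, LoadCase(dirichlet=[(np.array([0]), 0, 0.0)])
            )

    def test_disconnected_mesh_rejected(self):
        mat = -np.ones((5, 3, 3), dtype=np.int32)
        mat[0] = 0
        mat[4] = 0  # two islands
        with pytest.raises(ValueError, match="disconnected"):
            VoxelMesh(mat)


class TestInterfaces:
    def two_blocks(self, split=True):
        mat = np.zeros((4, 8, 4), dtype=np.int32)
        mesh = VoxelMesh(mat)
        itf = tie_and_contact_interface(mesh, axis=1, plane=4, mode="tie") if split else None
        return mesh, itf

    def end_load(self, mesh, value):
        lo = mesh.face_nodes(1, 0)
        hi = mesh.face_nodes(1, 1)
        dirichlet = [(lo, c, 0.0) for c in range(3)]
        dirichlet += [(hi, 1, value), (hi, 0, 0.0), (hi, 2, 0.0)]
        return LoadCase(dirichlet=dirichlet)

    def test_tied_blocks_match_monolith(self, ti):
        mesh1, _ = self.two_blocks(split=False)
        res1 = assemble_and_solve_linear(mesh1, {0: ti}, self.end_load(mesh1, -0.02))
        mesh2, itf = self.two_blocks(split=True)
        res2 = assemble_and_solve_linear(
            mesh2, {0: ti}, self.end_load(mesh2, -0.02), interfaces=[itf]
        )
        assert res2.reactions[3] == pytest.approx(res1.reactions[3], rel=2e-3)

    def test_contact_opens_under_tension(self, ti):
        mesh, itf = self.two_blocks(split=True)
        itf.mode = "contact"
        res = assemble_and_solve_linear(
            mesh, {0: ti}, self.end_load(mesh, +0.02), interfaces=[itf]
        )
        # no tensile traction transmitted; the pulled block stretches freely
        assert res.interface_tractions[0] == pytest.approx(0.0, abs=1e-9)
        gap = res.u[itf.pairs[:, 1], 1] - res.u[itf.pairs[:, 0], 1]
        assert np.all(gap > 0)

    def test_contact_transmits_compression(self, ti):
        mesh, itf = self.two_blocks(split=True)
        itf.mode = "contact"
        res = assemble_and_solve_linear(
            mesh, {0: ti}, self.end_load(mesh, -0.02), interfaces=[itf]
        )
        assert res.interface_tractions[0] > 0  # compressive (positive)

    def test_interior_plane_required(self, ti):
        mesh, _ = self.two_blocks(split=False)
        with pytest.raises(ValueError, match="interior"):
            tie_and_contact_interface(mesh, axis=1, plane=8)


class TestSuperelasticFE:
    def test_elastic_branch_matches_linear_solver(self, niti):
        mesh = solid_mesh(3, spacing=1.0 / 3)
        load = make_compression_load(mesh, 1.0, 0.005, n_increments=4)  # below plateau
        res_sma = solve_incremental_sma(mesh, {0: niti}, load)
        lin = LinearElastic(E=niti.E_A_mpa, nu=niti.nu)
        res_lin = assemble_and_solve_linear(mesh, {0: lin}, load)
        assert res_sma.reactions[0] == pytest.approx(res_lin.reactions[0], rel=1e-6)
        assert res_sma.xi.max() == 0.0

    def test_macroscopic_loop_closes(self, niti):
        mesh = solid_mesh(3, spacing=1.0 / 3)
        load = make_compression_load(mesh, 1.0, 0.02)  # through the plateau
        sched = list(np.linspace(0.125, 1.0, 8)) + list(np.linspace(0.875, 0.0, 8))
        res = solve_incremental_sma(mesh, {0: niti}, load, schedule=sched)
        assert max(i["xi_max"] for i in res.increments) > 0.1
        assert abs(res.reactions[0]) < 1e-6  # stress-free after unloading
        assert res.increments[-1]["xi_max"] < 1e-3
        assert res.external_work > 0  # dissipation of the closed loop

    def test_path_consistency_increment_halving(self, niti):
        mesh = solid_mesh(3, spacing=1.0 / 3)

        def final_reaction(n):
            load = make_compression_load(mesh, 1.0, 0.02, n_increments=n)
            return solve_incremental_sma(mesh, {0: niti}, load).reactions[0]

        r1, r2 = final_reaction(5), final_reaction(10)
        assert r1 == pytest.approx(r2, rel=0.01)

    def test_no_sma_material_rejected(self, ti):
        mesh = solid_mesh(2)
        load = make_compression_load(mesh, 2.0, 0.01)
        with pytest.raises(ValueError, match="superelastic"):
            solve_incremental_sma(mesh, {0: ti}, load)


def test_von_mises_of_uniaxial_and_shear():
    assert von_mises(np.array([100.0, 0, 0, 0, 0, 0])) == pytest.approx(100.0)
    assert von_mises(np.array([0.0, 0, 0, 50.0, 0, 0])) == pytest.approx(50 * np.sqrt(3))
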