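"""FE core verification: element stiffness, closed-form solutions, field
post-processing and the comparative-regime harness."""

import numpy as np
import pytest

from paleofract.fe import (
    LoadCase,
    StaticSolver,
    TetMesh,
    canonical_load_cases,
    compare_het_hom,
    distribute_force,
    element_stiffness,
    mean_vm_strain,
    principal_stresses,
    solve_linear_static,
    von_mises,
    von_mises_strain,
    voigt_to_tensor,
)
from paleofract.phantoms import box_tet_mesh

TET = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])


class TestElementStiffness:
    def test_symmetry(self):
        K = element_stiffness(TET, 1000.0, 0.3)
        assert np.abs(K - K.T).max() <= 1e-9 * np.abs(K).max()

    def test_rigid_modes_are_zero_energy(self):
        K = element_stiffness(TET, 1000.0, 0.3)
        for t in np.eye(3):
            u = np.tile(t, 4)
            assert np.abs(K @ u).max() < 1e-9 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w) < 1e-8 * w.max()).sum() == 6  # exactly six rigid modes

    def test_scales_linearly_with_size(self):
        K1 = element_stiffness(TET, 1000.0, 0.3)
        K2 = element_stiffness(2 * TET, 1000.0, 0.3)
        assert np.allclose(K2, 2 * K1)

    def test_degenerate_tet_rejected(self):
        flat = TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="degenerate|inverted"):
            element_stiffness(flat, 1000.0, 0.3)


class TestClosedFormSolutions:
    def test_patch_test_uniform_strain(self):
        """Linear boundary displacements reproduce the uniform strain field in
        every interior element: the completeness requirement."""
        mesh = box_tet_mesh(3, 3, 3, 1.0)
        A = np.array(
            [[1e-3, 1.5e-4, 1e-4], [1.5e-4, -2e-4, -5e-5], [1e-4, -5e-5, 5e-4]]
        )
        surf = mesh.surface_nodes()
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[surf] = True
        prescribed = mesh.nodes @ A.T
        res = solve_linear_static(
            mesh, 1000.0, 0.3,
            LoadCase(fixed, np.zeros((mesh.n_nodes, 3)), prescribed=prescribed),
        )
        expect = np.array(
            [A[0, 0], A[1, 1], A[2, 2], 2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]]
        )
        assert np.abs(res.strain - expect).max() < 1e-8

    def test_uniaxial_bar_stress_and_strain(self):
        """Axial traction P over area A: sigma = P/A, eps = P/(AE), exactly."""
        nx = ny = 4
        nz = 16
        mesh = box_tet_mesh(nx, ny, nz, 1.0)
        E, P, area = 5000.0, 80.0, float(nx * ny)
        top = np.where(np.abs(mesh.nodes[:, 2] - nz) < 1e-9)[0]
        bot = np.where(np.abs(mesh.nodes[:, 2]) < 1e-9)[0]
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[bot] = True
        res = solve_linear_static(
            mesh, E, 0.0, LoadCase(fixed, distribute_force(mesh, top, [0, 0, P]))
        )
        assert np.abs(res.stress[:, 2] - P / area).max() < 1e-6 * P / area
        assert np.abs(res.strain[:, 2] - P / (area * E)).max() < 1e-6 * P / (area * E)
        assert res.equilibrium_residual <= 1e-6
        # von Mises strain equals vm stress / E in a uniaxial state
        assert np.allclose(res.vm_strain_ue * 1e-6, res.vm_stress / E)

    def test_displacement_linear_in_load(self):
        mesh = box_tet_mesh(2, 2, 6, 1.0)
        bot = np.where(np.abs(mesh.nodes[:, 2]) < 1e-9)[0]
        top = np.where(np.abs(mesh.nodes[:, 2] - 6) < 1e-9)[0]
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[bot] = True
        solver = StaticSolver(mesh, 2000.0, 0.25)
        f1 = distribute_force(mesh, top, [1.0, 0, 3.0])
        r1 = solver.solve(LoadCase(fixed, f1))
        r2 = solver.solve(LoadCase(fixed, 2.5 * f1))
        assert np.allclose(r2.displacements, 2.5 * r1.displacements)

    def test_insufficient_restraints_detected(self):
        mesh = box_tet_mesh(2, 2, 2, 1.0)
        fixed = np.zeros((mesh.n_nodes, 3), bool)  # nothing fixed
        with pytest.raises(ValueError, match="restraint"):
            solve_linear_static(
                mesh, 1000.0, 0.3, LoadCase(fixed, np.zeros((mesh.n_nodes, 3)))
            )


def test_refinement_convergence_monotone():
    """Cantilever tip-deflection error decreases under uniform refinement."""
    E, nu, L, d, P = 10000.0, 0.3, 8.0, 1.0, 1.0
    w_eb = P * L**3 / (3 * E * d**4 / 12)
    errors = []
    for nd in (2, 4, 8):
        mesh = box_tet_mesh(nd, nd, 8 * nd, np.array([d / nd, d / nd, L / (8 * nd)]))
        tip = np.where(np.abs(mesh.nodes[:, 2] - L) < 1e-9)[0]
        base = np.where(np.abs(mesh.nodes[:, 2]) < 1e-9)[0]
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[base] = True
        res = solve_linear_static(
            mesh, E, nu, LoadCase(fixed, distribute_force(mesh, tip, [P, 0, 0]))
        )
        errors.append(abs(res.displacements[tip, 0].mean() - w_eb) / w_eb)
    assert errors[0] > errors[1] > errors[2]


def test_mirror_symmetry():
    """Mirrored mesh + mirrored load gives the mirrored displacement field."""
    mesh = box_tet_mesh(3, 3, 9, 1.0)
    mirror = mesh.nodes.copy()
    mirror[:, 0] *= -1.0
    elems = mesh.elements[:, [0, 1, 3, 2]]  # restore positive orientation
    mesh_m = TetMesh(nodes=mirror, elements=elems)
    base = np.abs(mesh.nodes[:, 2]) < 1e-9
    top = np.abs(mesh.nodes[:, 2] - 9) < 1e-9
    fixed = np.zeros((mesh.n_nodes, 3), bool)
    fixed[base] = True
    f = np.zeros((mesh.n_nodes, 3))
    f[top] = [0.5, 0.2, -1.0]
    fm = f.copy()
    fm[:, 0] *= -1.0
    r = solve_linear_static(mesh, 3000.0, 0.3, LoadCase(fixed, f))
    rm = solve_linear_static(mesh_m, 3000.0, 0.3, LoadCase(fixed, fm))
    expect = r.displacements.copy()
    expect[:, 0] *= -1.0
    assert np.abs(rm.displacements - expect).max() <= 1e-8


class TestFieldMeasures:
    def test_von_mises_trivials(self):
        assert von_mises(np.array([5.0, 5.0, 5.0, 0, 0, 0])) == pytest.approx(0.0)
        assert von_mises(np.array([7.0, 0, 0, 0, 0, 0])) == pytest.approx(7.0)
        assert von_mises(np.array([0, 0, 0, 2.0, 0, 0])) == pytest.approx(
            np.sqrt(3) * 2.0
        )

    def test_von_mises_strain_uniaxial_convention(self):
        nu, E, sigma = 0.3, 1000.0, 10.0
        eps = sigma / E
        voigt = np.array([eps, -nu * eps, -nu * eps, 0, 0, 0])
        assert von_mises_strain(voigt, nu) == pytest.approx(eps)

    def test_principal_sorted_and_invariant(self, rng):
        t = np.diag([3.0, 1.0, 2.0])
        vals, dirs = principal_stresses(t[None])
        assert np.allclose(vals[0], [3.0, 2.0, 1.0])
        assert np.allclose(np.abs(dirs[0, 0]), [1, 0, 0])
        s = rng.normal(size=(3, 3))
        s = s + s.T
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        v1, _ = principal_stresses(s[None])
        v2, _ = principal_stresses((q @ s @ q.T)[None])
        assert np.allclose(v1, v2)

    def test_principal_characteristic_polynomial(self, rng):
        s = rng.normal(size=(10, 3, 3))
        s = s + np.swapaxes(s, 1, 2)
        vals, dirs = principal_stresses(s)
        for k in range(10):
            for i in range(3):
                resid = (s[k] - vals[k, i] * np.eye(3)) @ dirs[k, i]
                assert np.abs(resid).max() < 1e-9 * max(1.0, np.abs(vals[k]).max())

    def test_voigt_round_trip(self):
        v = np.array([1.0, 2, 3, 4, 5, 6])
        t = voigt_to_tensor(v)
        assert t[0, 1] == 4 and t[1, 2] == 5 and t[0, 2] == 6
        assert np.allclose(t, t.T)


class TestCanonicalCases:
    def test_case_structure(self, phantom_mesh):
        spec, mesh, density = phantom_mesh
        cases = canonical_load_cases(mesh, magnitude=50.0)
        assert [c.description for c in cases] == [
            "uniaxial compression",
            "uniaxial tension",
            "uniaxial torsion",
            "anteroposterior bending",
            "mediolateral bending",
        ]
        comp, tens, tors = cases[0], cases[1], cases[2]
        assert np.allclose(comp.forces.sum(axis=0), -tens.forces.sum(axis=0))
        # torsion: zero net force, nonzero moment about the long axis
        assert np.abs(tors.forces.sum(axis=0)).max() < 1e-9
        c = mesh.nodes.mean(axis=0)
        moment = np.cross(mesh.nodes - c, tors.forces).sum(axis=0)
        assert abs(moment[2]) > 1.0

    def test_all_five_solvable(self, phantom_mesh, het_card):
        spec, mesh, density = phantom_mesh
        _, E, nu = het_card.arrays(mesh.element_class)
        solver = StaticSolver(mesh, E, nu)
        for case in canonical_load_cases(mesh):
            res = solver.solve(case)
            assert res.equilibrium_residual <= 1e-6
            assert np.isfinite(res.vm_strain_ue).all()


class TestMeanStrainAndComparison:
    def test_uniform_field_has_zero_sd(self):
        mesh = box_tet_mesh(2, 2, 2, 1.0)
        A = 1e-3 * np.eye(3)
        surf = mesh.surface_nodes()
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[surf] = True
        res = solve_linear_static(
            mesh, 1000.0, 0.0,
            LoadCase(fixed, np.zeros((mesh.n_nodes, 3)), prescribed=mesh.nodes @ A.T),
        )
        stats = mean_vm_strain(res, mesh.element_volumes())
        assert stats["sd_ue"] == pytest.approx(0.0, abs=1e-6)
        assert stats["mean_ue_volweighted"] == pytest.approx(stats["mean_ue"])

    def test_mean_scales_with_load(self):
        mesh = box_tet_mesh(2, 2, 6, 1.0)
        bot = np.abs(mesh.nodes[:, 2]) < 1e-9
        top = np.where(np.abs(mesh.nodes[:, 2] - 6) < 1e-9)[0]
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[bot] = True
        solver = StaticSolver(mesh, 2000.0, 0.25)
        f = distribute_force(mesh, top, [1.0, 0, 2.0])
        m1 = mean_vm_strain(solver.solve(LoadCase(fixed, f)))["mean_ue"]
        m2 = mean_vm_strain(solver.solve(LoadCase(fixed, 2 * f)))["mean_ue"]
        assert m2 == pytest.approx(2 * m1)

    def test_identical_cards_give_zero_difference(self, phantom_mesh, het_card):
        spec, mesh, density = phantom_mesh
        rows = compare_het_hom(mesh, het_card, het_card)
        assert len(rows) == 5
        for r in rows:
            assert r["difference_pct"] == pytest.approx(0.0, abs=1e-9)
            assert set(r) >= {
                "regime", "het_mean_ue", "het_sd_ue", "hom_mean_ue",
                "hom_sd_ue", "difference_pct",
            }
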