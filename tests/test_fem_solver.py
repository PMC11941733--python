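import numpy as np
import pytest

from aneufem.fem_solver import (
    MMHG_TO_PA,
    LoadCase,
    MaterialModel,
    SolverError,
    assemble,
    dirichlet_dofs,
    element_stiffness,
    elasticity_matrix,
    pressure_loads,
    solve_constrained,
    solve_static,
)
from aneufem.wall_mesher import WallMesh, boundary_nodes
from conftest import make_cylinder_mesh, uv_sphere

UNIT_TET_MM = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])

# V * B^T D B of the unit reference tet at E=1, nu=0 (SI coordinates),
# computed once symbolically; entries are integers / 12.
K_UNIT_REF = np.array([
    [4, 1, 1, -2, -1, -1, -1, 0, 0, -1, 0, 0],
    [1, 4, 1, 0, -1, 0, -1, -2, -1, 0, -1, 0],
    [1, 1, 4, 0, 0, -1, 0, 0, -1, -1, -1, -2],
    [-2, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0],
    [-1, -1, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0],
    [-1, 0, -1, 0, 0, 1, 0, 0, 0, 1, 0, 0],
    [-1, -1, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0],
    [0, -2, 0, 0, 0, 0, 0, 2, 0, 0, 0, 0],
    [0, -1, -1, 0, 0, 0, 0, 0, 1, 0, 1, 0],
    [-1, 0, -1, 0, 0, 1, 0, 0, 0, 1, 0, 0],
    [0, -1, -1, 0, 0, 0, 0, 0, 1, 0, 1, 0],
    [0, 0, -2, 0, 0, 0, 0, 0, 0, 0, 0, 2],
]) / 12.0


class TestElasticityMatrix:
    def test_shear_modulus_at_defaults(self):
        d = elasticity_matrix(MaterialModel())  # E = 0.7 MPa, nu = 0.45
        assert d[3, 3] == pytest.approx(0.7e6 / 2.9, rel=1e-12)

    def test_nu_zero_diagonal(self):
        d = elasticity_matrix(MaterialModel(young_modulus=1.0, poisson_ratio=0.0))
        assert d[0, 0] == pytest.approx(1.0)
        assert np.allclose(d[:3, :3], np.eye(3))

    def test_uniaxial_strain_probe(self):
        mat = MaterialModel(young_modulus=2.3e6, poisson_ratio=0.31)
        d = elasticity_matrix(mat)
        sigma = d @ np.array([1.0, 0, 0, 0, 0, 0])
        assert sigma[0] == pytest.approx(mat.lame_lambda + 2 * mat.lame_mu, rel=1e-12)

    def test_symmetric_positive_definite(self):
        d = elasticity_matrix(MaterialModel())
        assert np.allclose(d, d.T)
        assert np.all(np.linalg.eigvalsh(d) > 0)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            MaterialModel(poisson_ratio=0.5)


class TestElementStiffness:
    def test_matches_symbolic_oracle(self):
        mat = MaterialModel(young_modulus=1.0, poisson_ratio=0.0)
        # mm coords scale to metres by 1e-3; K scales linearly with length
        ke = element_stiffness(UNIT_TET_MM, mat)
        assert np.allclose(ke, K_UNIT_REF * 1e-3, atol=1e-15)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        tet = rng.normal(size=(4, 3)) * 10
        if np.linalg.det(tet[1:] - tet[0]) < 0:
            tet[[1, 2]] = tet[[2, 1]]
        ke = element_stiffness(tet, MaterialModel())
        assert np.allclose(ke, ke.T, atol=1e-9 * np.abs(ke).max())

    def test_rigid_translation_in_nullspace(self):
        ke = element_stiffness(UNIT_TET_MM * 3.0, MaterialModel())
        for axis in range(3):
            u = np.zeros(12)
            u[axis::3] = 1.0
            assert np.abs(ke @ u).max() < 1e-12 * np.abs(ke).max()

    def test_six_rigid_modes(self):
        ke = element_stiffness(UNIT_TET_MM, MaterialModel())
        w = np.linalg.eigvalsh(ke)
        assert np.sum(np.abs(w) < 1e-12 * w.max()) == 6

    def test_degenerate_tet_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(SolverError):
            element_stiffness(flat, MaterialModel())


class TestAssemble:
    @staticmethod
    def two_tet_mesh():
        nodes = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 10.0]]
        )
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        return WallMesh(nodes=nodes, tets=tets)

    def test_matches_dense_oracle(self):
        mesh = self.two_tet_mesh()
        mat = MaterialModel()
        k = assemble(mesh, mat).toarray()
        dense = np.zeros_like(k)
        for tet in mesh.tets:
            ke = element_stiffness(mesh.nodes[tet], mat)
            dof = (3 * tet[:, None] + np.arange(3)).ravel()
            dense[np.ix_(dof, dof)] += ke
        assert np.allclose(k, dense, atol=1e-12 * np.abs(dense).max())

    def test_translation_nullspace(self):
        k = assemble(self.two_tet_mesh(), MaterialModel())
        u = np.tile([1.0, 0.0, 0.0], 5)
        assert np.abs(k @ u).max() < 1e-10 * np.abs(k.data).max()

    def test_nullspace_dimension_six(self):
        k = assemble(self.two_tet_mesh(), MaterialModel()).toarray()
        w = np.linalg.eigvalsh(k)
        assert np.sum(np.abs(w) < 1e-10 * w.max()) == 6

    def test_permutation_invariance(self):
        mesh, _ = make_cylinder_mesh(n_circ=12, n_ax=9, n_layers=1)
        mat = MaterialModel()
        load = LoadCase(n_steps=1)
        u_ref = solve_static(mesh, mat, load).displacements[-1]

        rng = np.random.default_rng(3)
        perm = rng.permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        permuted = WallMesh(
            nodes=mesh.nodes[perm],
            tets=inv[mesh.tets],
            inlet_nodes=inv[mesh.inlet_nodes],
            outlet_nodes=inv[mesh.outlet_nodes],
            lumen_faces=inv[mesh.lumen_faces],
        )
        u_perm = solve_static(permuted, mat, load).displacements[-1]
        assert np.allclose(u_perm[inv], u_ref, atol=1e-10)


class TestPressureLoads:
    def test_closed_sphere_equilibrium(self):
        sphere = uv_sphere(radius=20.0, n_theta=24, n_phi=48)
        wall = WallMesh(
            nodes=sphere.vertices,
            tets=np.zeros((0, 4), dtype=np.int64),
            lumen_faces=sphere.triangles[:, [0, 2, 1]],  # inward orientation
        )
        f = pressure_loads(wall, 1e4).reshape(-1, 3)
        net = f.sum(axis=0)
        total = np.linalg.norm(f, axis=1).sum()
        assert np.linalg.norm(net) < 1e-9 * total

    def test_open_cylinder_projected_area(self):
        mesh, surf = make_cylinder_mesh(radius=12.0, length=100.0, n_circ=64, n_ax=51)
        p = 1e4
        f = pressure_loads(mesh, p).reshape(-1, 3)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9 * np.linalg.norm(f, axis=1).sum()
        # +x half-barrel: x-resultant = p x projected area 2 r L
        nv = surf.n_vertices
        xpos = mesh.nodes[:nv, 0] > 1e-9
        fx = f[:nv][xpos, 0].sum()
        a_proj = 2 * 0.012 * 0.1  # SI
        assert fx == pytest.approx(p * a_proj, rel=0.02)

    def test_zero_pressure_zero_loads(self):
        mesh, _ = make_cylinder_mesh(n_circ=16, n_ax=9)
        assert np.all(pressure_loads(mesh, 0.0) == 0.0)

    def test_untagged_lumen_errors(self):
        mesh = WallMesh(nodes=np.zeros((4, 3)), tets=np.array([[0, 1, 2, 3]]))
        with pytest.raises(SolverError):
            pressure_loads(mesh, 1.0)


class TestSolveStatic:
    def test_step_linearity(self, solved_cylinder):
        _, _, _, load, sol = solved_cylinder
        dps = load.step_pressures_mmhg()
        u_final = sol.displacements[-1]
        scale_ref = np.linalg.norm(u_final)
        for k, dp in enumerate(dps[:-1]):
            expected = u_final * (dp / dps[-1])
            assert np.linalg.norm(sol.displacements[k] - expected) < 1e-8 * scale_ref

    def test_global_equilibrium(self, solved_cylinder):
        mesh, _, _, load, sol = solved_cylinder
        applied = pressure_loads(mesh, load.step_pressures_pa()[-1]).reshape(-1, 3)
        residual = sol.reactions[-1].sum(axis=0) + applied.sum(axis=0)
        assert np.linalg.norm(residual) < 1e-8 * np.linalg.norm(applied, axis=1).sum()

    def test_constrained_nodes_fixed(self, solved_cylinder):
        mesh, _, _, _, sol = solved_cylinder
        fixed = np.concatenate([mesh.inlet_nodes, mesh.outlet_nodes])
        assert np.abs(sol.displacements[:, fixed, :]).max() == 0.0

    def test_empty_constraints_error(self):
        mesh = WallMesh(nodes=np.zeros((4, 3)), tets=np.array([[0, 1, 2, 3]]))
        with pytest.raises(SolverError):
            dirichlet_dofs(mesh)

    def test_cg_matches_direct(self):
        mesh, _ = make_cylinder_mesh(n_circ=16, n_ax=11, n_layers=1)
        mat = MaterialModel(poisson_ratio=0.3)
        load = LoadCase(n_steps=1)
        u_d = solve_static(mesh, mat, load).displacements[-1]
        u_c = solve_static(mesh, mat, load, solver="cg", tol=1e-12).displacements[-1]
        assert np.allclose(u_c, u_d, atol=1e-6 * np.abs(u_d).max())

    def test_patch_uniform_strain_exact(self):
        # prescribe an affine displacement on every boundary node; CST
        # must reproduce the constant strain field exactly
        from aneufem.postproc import element_fields

        mesh, _ = make_cylinder_mesh(n_circ=12, n_ax=9, n_layers=2)
        mat = MaterialModel(poisson_ratio=0.3)
        grad = np.array([[2e-3, 1e-3, 0], [0, -1e-3, 5e-4], [1e-3, 0, 3e-3]])
        u_affine = mesh.nodes @ grad.T  # mm

        bn = boundary_nodes(mesh)
        fixed = (3 * bn[:, None] + np.arange(3)).ravel()
        k = assemble(mesh, mat)
        u_mm_si = u_affine * 1e-3
        u, _ = solve_constrained(
            k, np.zeros(3 * mesh.n_nodes), fixed, fixed_values=u_mm_si.ravel()[fixed]
        )
        u_mm = u.reshape(-1, 3) / 1e-3
        strain, _ = element_fields(mesh, mat, u_mm)
        sym = 0.5 * (grad + grad.T)
        expected = np.array([
            sym[0, 0], sym[1, 1], sym[2, 2],
            2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[2, 0],
        ])
        assert np.abs(strain - expected).max() < 1e-10


class TestLoadCase:
    def test_mmhg_conversion(self):
        assert 77.0 * MMHG_TO_PA == pytest.approx(10265.794)

    def test_step_schedule_endpoints(self):
        load = LoadCase()
        dps = load.step_pressures_mmhg()
        assert len(dps) == 10
        assert dps[0] == 50.0 and dps[-1] == 77.0
        assert np.allclose(np.diff(dps), 3.0)

    def test_single_step(self):
        assert LoadCase(n_steps=1).step_pressures_mmhg().tolist() == [77.0]

    def test_validation(self):
        with pytest.raises(ValueError):
            LoadCase(delta_p_first=80.0, delta_p_final=77.0)
        with pytest.raises(ValueError):
            LoadCase(n_steps=0)
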