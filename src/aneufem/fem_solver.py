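"""Linear isotropic elastostatics on tetrahedral wall meshes.

Constant-strain (4-node) tetrahedra, incremental lumen-pressure loading
with all displacement components fixed on the inlet and outlet node
sets. Internally everything is SI (m, Pa, N); millimetres and mmHg
appear only at the interface.

Voigt convention: (xx, yy, zz, xy, yz, zx) with engineering shear
strains (gamma = 2 * epsilon_shear).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu, cg

from .wall_mesher import WallMesh

#: Conversion constant used everywhere a pressure crosses the interface.
MMHG_TO_PA = 133.322

MM_TO_M = 1e-3


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear elastic wall material.

    Defaults: E = 0.7 MPa, nu = 0.45, density 1095 kg/m^3 (density is
    carried for completeness; statics does not use it).
    """

    young_modulus: float = 0.7e6  # Pa
    poisson_ratio: float = 0.45
    density: float = 1095.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in (-1, 0.5)")

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1 + nu) * (1 - 2 * nu))

    @property
    def lame_mu(self) -> float:
        return self.young_modulus / (2 * (1 + self.poisson_ratio))


@dataclass(frozen=True)
class LoadCase:
    """Incremental pressure-difference loading, all pressures in mmHg.

    Step k (1-based) applies
    dP_k = delta_p_first + (k-1)/(n_steps-1) * (delta_p_final - delta_p_first);
    a single step applies delta_p_final.
    """

    p_dias_low: float = 80.0
    p_sys_low: float = 130.0
    p_dias_high: float = 123.0
    p_sys_high: float = 230.0
    delta_p_first: float = 50.0
    delta_p_final: float = 77.0
    n_steps: int = 10

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.delta_p_first < self.delta_p_final:
            raise ValueError("delta_p_first must be < delta_p_final")

    def step_pressures_mmhg(self) -> np.ndarray:
        if self.n_steps == 1:
            return np.array([self.delta_p_final])
        k = np.arange(self.n_steps, dtype=float)
        return self.delta_p_first + k / (self.n_steps - 1) * (
            self.delta_p_final - self.delta_p_first
        )

    def step_pressures_pa(self) -> np.ndarray:
        return self.step_pressures_mmhg() * MMHG_TO_PA


@dataclass
class Solution:
    """Per-step nodal displacements (mm) and reactions (N) on constrained nodes."""

    displacements: np.ndarray  # (n_steps, n_nodes, 3), mm
    reactions: np.ndarray  # (n_steps, n_constrained, 3), N
    constrained_nodes: np.ndarray
    step_pressures_mmhg: np.ndarray

    @property
    def final_displacement(self) -> np.ndarray:
        return self.displacements[-1]

    def max_displacement(self, step: int = -1) -> float:
        """Largest nodal displacement magnitude at a load step, mm."""
        return float(np.linalg.norm(self.displacements[step], axis=1).max())


def elasticity_matrix(material: MaterialModel) -> np.ndarray:
    """6x6 isotropic stress-strain operator in Voigt form (SPD)."""
    lam, mu = material.lame_lambda, material.lame_mu
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.diag_indices(3)] += 2 * mu
    d[3, 3] = d[4, 4] = d[5, 5] = mu
    return d


def _tet_gradients(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Shape-function gradients (4, 3) and volume of one tet (coords in m)."""
    m = coords[1:] - coords[0]
    vol = np.linalg.det(m) / 6.0
    if vol <= 0:
        raise SolverError("degenerate or inverted tetrahedron")
    minv = np.linalg.inv(m)
    g = np.zeros((4, 3))
    g[1:] = minv.T
    g[0] = -g[1:].sum(axis=0)
    return g, vol


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 12) of the constant-strain tet."""
    b = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        b[0, c] = gx
        b[1, c + 1] = gy
        b[2, c + 2] = gz
        b[3, c] = gy
        b[3, c + 1] = gx
        b[4, c + 1] = gz
        b[4, c + 2] = gy
        b[5, c] = gz
        b[5, c + 2] = gx
    return b


def element_stiffness(tet_nodes: np.ndarray, material: MaterialModel) -> np.ndarray:
    """12x12 stiffness K_e = V B^T D B of one tet (node coords in mm)."""
    coords = np.asarray(tet_nodes, dtype=float) * MM_TO_M
    grads, vol = _tet_gradients(coords)
    b = _b_matrix(grads)
    d = elasticity_matrix(material)
    return vol * b.T @ d @ b


def _all_gradients(mesh: WallMesh) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised shape gradients (n_el, 4, 3) and volumes (m^3)."""
    p = mesh.nodes[mesh.tets] * MM_TO_M  # (n, 4, 3)
    m = p[:, 1:] - p[:, :1]  # (n, 3, 3)
    vol = np.linalg.det(m) / 6.0
    if np.any(vol <= 0):
        raise SolverError(
            f"{int((vol <= 0).sum())} degenerate/inverted tets in mesh"
        )
    minv = np.linalg.inv(m)
    g = np.empty((len(p), 4, 3))
    g[:, 1:] = np.transpose(minv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def assemble(mesh: WallMesh, material: MaterialModel) -> sparse.csr_matrix:
    """Global stiffness (3N x 3N, SI) by scatter-add of element matrices."""
    grads, vols = _all_gradients(mesh)
    d = elasticity_matrix(material)
    n_el = len(mesh.tets)

    # batched B matrices: (n_el, 6, 12)
    b = np.zeros((n_el, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        b[:, 0, c] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c] = gz
        b[:, 5, c + 2] = gx

    ke = np.einsum("eji,jk,ekl->eil", b, d, b, optimize=True)
    ke *= vols[:, None, None]

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(n_el, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    ndof = 3 * mesh.n_nodes
    k = sparse.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(ndof, ndof)
    ).tocsr()
    return k


def pressure_loads(mesh: WallMesh, pressure: float) -> np.ndarray:
    """Consistent nodal forces (N) from uniform pressure on the lumen faces.

    Each lumen triangle contributes p*A/3 to each of its nodes along the
    face normal directed from the lumen into the wall; normals are taken
    on the reference configuration (dead load).
    """
    if mesh.lumen_faces.size == 0:
        raise SolverError("mesh has no tagged lumen faces")
    v = mesh.nodes * MM_TO_M
    f = mesh.lumen_faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    # lumen faces are oriented with normals pointing into the lumen
    # (tag_boundaries convention); pressure pushes the opposite way.
    tri_force = -0.5 * pressure * cross  # p * A * n_into_wall
    loads = np.zeros((mesh.n_nodes, 3))
    for k in range(3):
        np.add.at(loads, f[:, k], tri_force / 3.0)
    return loads.ravel()


def dirichlet_dofs(mesh: WallMesh, components: tuple[int, ...] = (0, 1, 2)) -> np.ndarray:
    """Global dof indices fixed to zero on the inlet and outlet node sets."""
    nodes = np.concatenate([mesh.inlet_nodes, mesh.outlet_nodes])
    if nodes.size == 0:
        raise SolverError("no constrained nodes: tag inlet/outlet first")
    return np.unique(
        (3 * nodes[:, None] + np.array(components)[None, :]).ravel()
    )


def solve_constrained(
    k: sparse.csr_matrix,
    rhs: np.ndarray,
    fixed_dofs: np.ndarray,
    solver: str = "direct",
    tol: float = 1e-10,
    fixed_values: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve K u = rhs (possibly multiple RHS columns) with prescribed dofs.

    Fixed dofs take ``fixed_values`` (zero by default). Returns
    (u, reactions_on_fixed_dofs). ``rhs`` may be (ndof,) or (ndof, n_rhs).
    """
    ndof = k.shape[0]
    if fixed_dofs.size == 0:
        raise SolverError("empty constraint set: system is singular")
    free = np.setdiff1d(np.arange(ndof), fixed_dofs, assume_unique=False)
    rhs2 = rhs.reshape(ndof, -1).astype(float).copy()
    kff = k[free][:, free].tocsc()
    u = np.zeros_like(rhs2)
    if fixed_values is not None:
        uc = np.asarray(fixed_values, dtype=float).reshape(len(fixed_dofs), -1)
        u[fixed_dofs] = uc
        rhs2[free] -= k[free][:, fixed_dofs] @ uc
    if solver == "direct":
        lu = splu(kff)
        for j in range(rhs2.shape[1]):
            u[free, j] = lu.solve(rhs2[free, j])
    elif solver == "cg":
        precond = sparse.diags(1.0 / kff.diagonal())
        for j in range(rhs2.shape[1]):
            x, info = cg(kff, rhs2[free, j], rtol=tol, M=precond, maxiter=20000)
            if info != 0:
                res = np.linalg.norm(kff @ x - rhs2[free, j]) / max(
                    np.linalg.norm(rhs2[free, j]), 1e-300
                )
                raise SolverError(f"CG did not converge (info={info}, rel res={res:.2e})")
            u[free, j] = x
    else:
        raise ValueError(f"unknown solver '{solver}'")
    reactions = np.asarray(k[fixed_dofs] @ u) - rhs2[fixed_dofs]
    return u.reshape(rhs.shape), reactions


def solve_static(
    mesh: WallMesh,
    material: MaterialModel,
    load: LoadCase,
    solver: str = "direct",
    tol: float = 1e-10,
) -> Solution:
    """Incremental pressure solve with inlet/outlet fully fixed.

    One factorisation serves every load step; each step is an
    independent solve against its own pressure RHS (for this linear
    model the steps are exact rescalings of each other).
    """
    fixed = dirichlet_dofs(mesh)
    k = assemble(mesh, material)
    pressures = load.step_pressures_pa()
    rhs = np.column_stack([pressure_loads(mesh, p) for p in pressures])
    u, reac = solve_constrained(k, rhs, fixed, solver=solver, tol=tol)
    if not np.all(np.isfinite(u)):
        raise SolverError("non-finite displacements")
    n_steps = len(pressures)
    disp_mm = (u.T.reshape(n_steps, mesh.n_nodes, 3)) / MM_TO_M
    cn = np.unique(np.concatenate([mesh.inlet_nodes, mesh.outlet_nodes]))
    reac_nodes = reac.T.reshape(n_steps, len(cn), 3)
    return Solution(
        displacements=disp_mm,
        reactions=reac_nodes,
        constrained_nodes=cn,
        step_pressures_mmhg=load.step_pressures_mmhg(),
    )
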