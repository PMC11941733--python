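"""Stress/strain/displacement fields and per-case summary records.

Element strain is the symmetric displacement gradient (constant per
tet); stress follows from the isotropic operator. Scalar measures are
the von Mises stress and the deviatoric (von Mises) equivalent strain,
sqrt(2/3 * dev(eps):dev(eps)). Maxima are always taken on raw element
values — no nodal averaging — to avoid smoothing bias.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .fem_solver import (
    MaterialModel,
    Solution,
    _all_gradients,
    elasticity_matrix,
    MM_TO_M,
)
from .wall_mesher import WallMesh


@dataclass
class FieldResult:
    """Per-element tensors (Voigt, engineering shear) plus field maxima."""

    element_stress: np.ndarray  # (n_el, 6), MPa
    element_strain: np.ndarray  # (n_el, 6), dimensionless
    node_displacement: np.ndarray  # (n_nodes, 3), mm
    max_von_mises: float  # MPa
    max_equivalent_strain: float  # fraction
    max_displacement: float  # mm

    @property
    def max_equivalent_strain_percent(self) -> float:
        return 100.0 * self.max_equivalent_strain


@dataclass
class CaseRecord:
    """One row of a cohort summary table."""

    case_id: str
    diagnostic_diameter: float  # mm
    max_von_mises: float  # MPa
    max_equivalent_strain: float  # fraction
    max_displacement: float  # mm
    systolic_diameter: float  # mm, = diagnostic + max displacement
    systolic_diameter_section: float | None = None  # deformed-section measure

    def __post_init__(self) -> None:
        if self.systolic_diameter < self.diagnostic_diameter - 1e-9:
            raise ValueError("systolic diameter cannot shrink below diagnostic")

    def to_dict(self) -> dict:
        return asdict(self)


def strain_from_displacement(tet_nodes: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Small strain tensor (3x3) of one tet from nodal displacements.

    ``tet_nodes`` (4, 3) mm, ``u`` (4, 3) mm; strain is unitless so a
    shared length unit suffices.
    """
    from .fem_solver import _tet_gradients

    grads, _ = _tet_gradients(np.asarray(tet_nodes, dtype=float) * MM_TO_M)
    grad_u = (np.asarray(u, dtype=float) * MM_TO_M).T @ grads  # du_i/dx_j
    return 0.5 * (grad_u + grad_u.T)


def _to_voigt_stress(t: np.ndarray) -> np.ndarray:
    return np.array([t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[1, 2], t[2, 0]])


def von_mises(stress) -> float | np.ndarray:
    """Von Mises scalar from a (..., 6) Voigt or (3, 3) stress tensor."""
    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] == (3, 3):
        s = np.stack(
            [s[..., 0, 0], s[..., 1, 1], s[..., 2, 2],
             s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]],
            axis=-1,
        )
    sx, sy, sz, sxy, syz, szx = (s[..., i] for i in range(6))
    out = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
    return float(out) if out.ndim == 0 else out


def equivalent_strain(strain) -> float | np.ndarray:
    """Deviatoric equivalent strain sqrt(2/3 dev:dev).

    Accepts (..., 6) Voigt with ENGINEERING shears or a (3, 3) tensor.
    For the uniaxial deviatoric probe diag(e, -e/2, -e/2) it returns e.
    """
    e = np.asarray(strain, dtype=float)
    if e.shape[-2:] == (3, 3):
        e = np.stack(
            [e[..., 0, 0], e[..., 1, 1], e[..., 2, 2],
             2 * e[..., 0, 1], 2 * e[..., 1, 2], 2 * e[..., 2, 0]],
            axis=-1,
        )
    ex, ey, ez = e[..., 0], e[..., 1], e[..., 2]
    exy, eyz, ezx = e[..., 3] / 2.0, e[..., 4] / 2.0, e[..., 5] / 2.0
    tr = (ex + ey + ez) / 3.0
    dev2 = (
        (ex - tr) ** 2 + (ey - tr) ** 2 + (ez - tr) ** 2
        + 2.0 * (exy**2 + eyz**2 + ezx**2)
    )
    out = np.sqrt(2.0 / 3.0 * dev2)
    return float(out) if out.ndim == 0 else out


def element_fields(
    mesh: WallMesh, material: MaterialModel, displacement_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (strain, stress) in Voigt form for the whole mesh.

    Strain dimensionless; stress in Pa.
    """
    grads, _ = _all_gradients(mesh)  # (n_el, 4, 3)
    u = displacement_mm[mesh.tets] * MM_TO_M  # (n_el, 4, 3)
    grad_u = np.einsum("eai,eaj->eij", u, grads)  # du_i/dx_j
    eps = 0.5 * (grad_u + np.transpose(grad_u, (0, 2, 1)))
    strain = np.stack(
        [eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
         2 * eps[:, 0, 1], 2 * eps[:, 1, 2], 2 * eps[:, 2, 0]],
        axis=1,
    )
    stress = strain @ elasticity_matrix(material).T
    return strain, stress


def compute_fields(
    mesh: WallMesh,
    material: MaterialModel,
    solution: Solution,
    step: int = -1,
) -> FieldResult:
    """Assemble the FieldResult for one load step (default: final)."""
    disp = solution.displacements[step]
    strain, stress_pa = element_fields(mesh, material, disp)
    stress_mpa = stress_pa / 1e6
    vm = von_mises(stress_mpa)
    eq = equivalent_strain(strain)
    return FieldResult(
        element_stress=stress_mpa,
        element_strain=strain,
        node_displacement=disp,
        max_von_mises=float(vm.max()),
        max_equivalent_strain=float(eq.max()),
        max_displacement=float(np.linalg.norm(disp, axis=1).max()),
    )


def deformed_section_diameter(
    mesh: WallMesh, displacement_mm: np.ndarray, bin_width: float = 2.0
) -> float:
    """Alternative systolic diameter: widest deformed lumen cross-section.

    Bins the deformed inner-surface nodes by axial position and returns
    the largest 2*max-distance-from-centroid over bins.
    """
    from .surface import max_section_diameter

    lumen_nodes = np.unique(mesh.lumen_faces)
    pts = mesh.nodes[lumen_nodes] + displacement_mm[lumen_nodes]
    return max_section_diameter(pts, axis=2, bin_width=bin_width)


def case_summary(
    result: FieldResult,
    diagnostic_diameter: float,
    case_id: str = "",
    mesh: WallMesh | None = None,
) -> CaseRecord:
    """Summarise one solved case.

    The systolic diameter follows the one-sided bookkeeping convention
    Dsys = Ddias + max displacement. When the mesh is available a
    cross-section-based measurement of the deformed bulge is reported
    alongside (``systolic_diameter_section``).
    """
    section = None
    if mesh is not None:
        section = deformed_section_diameter(mesh, result.node_displacement)
    return CaseRecord(
        case_id=case_id,
        diagnostic_diameter=float(diagnostic_diameter),
        max_von_mises=result.max_von_mises,
        max_equivalent_strain=result.max_equivalent_strain,
        max_displacement=result.max_displacement,
        systolic_diameter=float(diagnostic_diameter) + result.max_displacement,
        systolic_diameter_section=section,
    )
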