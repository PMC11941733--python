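"""Closed-form validation benchmarks for the elasticity solver.

The pressurised thick-walled cylinder has the classical interior
solution (hoop stress at radius r for inner/outer radii a, b and inner
pressure p):

    sigma_theta(r) = p a^2 / (b^2 - a^2) * (1 + b^2 / r^2)

A long tube with fully fixed ends approaches this solution away from
the ends; the inner-wall value p (a^2 + b^2) / (b^2 - a^2) is the
reference for convergence checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem_solver import MMHG_TO_PA, LoadCase, MaterialModel, solve_static
from .postproc import element_fields
from .synthetic_anatomy import AnatomySpec, generate_lumen_surface
from .wall_mesher import extrude_wall, tag_boundaries


def lame_inner_hoop(a_mm: float, b_mm: float, p_pa: float) -> float:
    """Exact inner-wall hoop stress (Pa) of the thick-walled cylinder."""
    a2, b2 = a_mm**2, b_mm**2
    return p_pa * (a2 + b2) / (b2 - a2)


def lame_hoop_at(a_mm: float, b_mm: float, p_pa: float, r_mm) -> np.ndarray:
    a2, b2 = a_mm**2, b_mm**2
    return p_pa * a2 / (b2 - a2) * (1.0 + b2 / np.asarray(r_mm) ** 2)


@dataclass
class LameResult:
    computed_inner_hoop: float  # Pa
    exact_inner_hoop: float  # Pa
    relative_error: float
    n_elements: int
    max_displacement_mm: float


def lame_cylinder_benchmark(
    n_circ: int = 32,
    n_axial: int = 41,
    n_layers: int = 2,
    poisson_ratio: float = 0.3,
    a_mm: float = 24.0,
    thickness_mm: float = 2.0,
    length_mm: float = 120.0,
    pressure_pa: float = 10e3,
    young_modulus: float = 1e6,
) -> LameResult:
    """Solve the fixed-end tube and extrapolate mid-section hoop stress to r=a.

    Element hoop stresses in the mid-length band are averaged per radial
    layer; a two-parameter A + B/r^2 profile (the exact radial form) is
    fitted through the layer means and evaluated at the inner wall.
    """
    spec = AnatomySpec(
        neck_radius=a_mm, max_radius=a_mm, bulge_center=length_mm / 2,
        bulge_width=20.0, total_length=length_mm, wall_thickness=thickness_mm,
    )
    surf = generate_lumen_surface(spec, n_circumferential=n_circ, n_axial=n_axial)
    mesh = tag_boundaries(extrude_wall(surf, thickness_mm, n_layers), surf)
    material = MaterialModel(young_modulus=young_modulus, poisson_ratio=poisson_ratio)
    dp_mmhg = pressure_pa / MMHG_TO_PA
    load = LoadCase(delta_p_first=dp_mmhg / 2, delta_p_final=dp_mmhg, n_steps=2)
    sol = solve_static(mesh, material, load)

    _, stress = element_fields(mesh, material, sol.displacements[-1])
    cent = mesh.nodes[mesh.tets].mean(axis=1)
    r = np.hypot(cent[:, 0], cent[:, 1])
    band = np.abs(cent[:, 2] - length_mm / 2) < 0.1 * length_mm
    th = np.arctan2(cent[:, 1], cent[:, 0])
    c, s = np.cos(th), np.sin(th)
    hoop = s**2 * stress[:, 0] + c**2 * stress[:, 1] - 2 * s * c * stress[:, 3]

    rs, hs = r[band], hoop[band]
    edges = np.linspace(rs.min() - 1e-9, rs.max() + 1e-9, n_layers + 1)
    r_mean, h_mean = [], []
    for i in range(n_layers):
        sel = (rs >= edges[i]) & (rs < edges[i + 1])
        r_mean.append(rs[sel].mean())
        h_mean.append(hs[sel].mean())
    r_mean = np.asarray(r_mean)
    x = np.column_stack([np.ones(n_layers), 1.0 / r_mean**2])
    coef, *_ = np.linalg.lstsq(x, np.asarray(h_mean), rcond=None)
    b_mm = a_mm + thickness_mm
    inner = float(coef[0] + coef[1] / a_mm**2)
    exact = lame_inner_hoop(a_mm, b_mm, pressure_pa)
    return LameResult(
        computed_inner_hoop=inner,
        exact_inner_hoop=exact,
        relative_error=abs(inner / exact - 1.0),
        n_elements=mesh.n_elements,
        max_displacement_mm=sol.max_displacement(),
    )
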