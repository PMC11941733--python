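import numpy as np
import pytest

from aneufem.synthetic_anatomy import AnatomySpec, generate_lumen_surface
from aneufem.wall_mesher import extrude_wall, tag_boundaries
from aneufem.fem_solver import MaterialModel, LoadCase, solve_static


def make_cylinder_spec(radius=12.0, length=100.0, thickness=2.0):
    return AnatomySpec(
        neck_radius=radius,
        max_radius=radius,
        bulge_center=length / 2.0,
        bulge_width=20.0,
        total_length=length,
        wall_thickness=thickness,
    )


def make_cylinder_mesh(
    radius=12.0, length=100.0, thickness=2.0, n_circ=24, n_ax=21, n_layers=2
):
    spec = make_cylinder_spec(radius, length, thickness)
    surf = generate_lumen_surface(spec, n_circumferential=n_circ, n_axial=n_ax)
    return tag_boundaries(extrude_wall(surf, thickness, n_layers), surf), surf


def uv_sphere(radius=25.0, n_theta=32, n_phi=64, center=(0.0, 0.0, 0.0)):
    """Closed lat-long sphere with triangle fans at the poles, outward normals."""
    from aneufem.surface import SurfaceMesh

    thetas = np.linspace(0.0, np.pi, n_theta + 1)[1:-1]
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    verts = [np.array([0.0, 0.0, radius])]
    for th in thetas:
        for ph in phis:
            verts.append(
                radius
                * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
            )
    verts.append(np.array([0.0, 0.0, -radius]))
    verts = np.array(verts) + np.asarray(center)

    tris = []
    ring = lambda i, j: 1 + i * n_phi + (j % n_phi)
    for j in range(n_phi):  # north fan
        tris.append([0, ring(0, j), ring(0, j + 1)])
    for i in range(len(thetas) - 1):
        for j in range(n_phi):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            tris.append([a, c, d])
            tris.append([a, d, b])
    south = len(verts) - 1
    for j in range(n_phi):  # south fan
        tris.append([south, ring(len(thetas) - 1, j + 1), ring(len(thetas) - 1, j)])
    mesh = SurfaceMesh(verts, np.array(tris), provenance="uv-sphere")
    assert mesh.signed_volume() > 0
    return mesh


@pytest.fixture(scope="session")
def solved_cylinder():
    """Small pressurised cylinder solved once and shared across tests."""
    mesh, surf = make_cylinder_mesh(n_circ=24, n_ax=21, n_layers=2)
    material = MaterialModel(young_modulus=1e6, poisson_ratio=0.3)
    load = LoadCase(delta_p_first=38.5, delta_p_final=77.0, n_steps=4)
    solution = solve_static(mesh, material, load)
    return mesh, surf, material, load, solution
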