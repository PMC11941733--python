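"""Extrude a lumen surface into a conforming tetrahedral wall mesh.

The wall is built by offsetting every surface vertex outward along its
area-weighted normal in ``n_layers`` equal shells; each triangular prism
is split into three tetrahedra with an index-ordered diagonal rule so
that quad faces shared by neighbouring prisms receive matching
diagonals (the split is then globally conforming).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface import SurfaceMesh


class MeshingError(ValueError):
    pass


@dataclass
class WallMesh:
    """Tetrahedral wall volume with named boundary sets (coordinates mm)."""

    nodes: np.ndarray
    tets: np.ndarray
    inlet_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    outlet_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    lumen_faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.int64))
    element_size_target: float = 1.0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.inlet_nodes = np.asarray(self.inlet_nodes, dtype=np.int64)
        self.outlet_nodes = np.asarray(self.outlet_nodes, dtype=np.int64)
        self.lumen_faces = np.asarray(self.lumen_faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes, mm^3."""
        p = self.nodes[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())


def vertex_normals(surface: SurfaceMesh) -> np.ndarray:
    """Per-vertex unit normals: area-weighted mean of incident triangle normals."""
    cross = surface.triangle_cross()  # length = 2x area, direction = normal
    acc = np.zeros_like(surface.vertices)
    for k in range(3):
        np.add.at(acc, surface.triangles[:, k], cross)
    norms = np.linalg.norm(acc, axis=1)
    isolated = norms == 0
    if isolated.any():
        raise MeshingError(
            f"isolated or null-normal vertices: {np.flatnonzero(isolated)[:10]}"
        )
    return acc / norms[:, None]


def _split_prism(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split one triangular prism into 3 tets with index-ordered diagonals.

    ``bottom``/``top`` are matching global node triples. Each quad face
    (b[i], b[j], t[j], t[i]) is cut along the diagonal leaving from its
    smallest global node index, which is a symmetric rule: both prisms
    sharing the quad choose the same diagonal.
    """
    b, t = bottom, top
    # rotate so the smallest bottom index is first (canonical orientation)
    rot = int(np.argmin(b))
    idx = [(rot + k) % 3 for k in range(3)]
    v0, v1, v2 = (int(b[i]) for i in idx)
    v3, v4, v5 = (int(t[i]) for i in idx)
    # Diagonal choice on the two quads not touching v0's edge rule:
    # quad (v1,v2,v5,v4): diagonal from min(v1, v2, v4, v5) corner.
    if min(v1, v5) < min(v2, v4):
        tets = [(v0, v1, v2, v5), (v0, v1, v5, v4), (v0, v4, v5, v3)]
    else:
        tets = [(v0, v1, v2, v4), (v0, v4, v2, v5), (v0, v4, v5, v3)]
    return np.array(tets, dtype=np.int64)


def extrude_wall(surface: SurfaceMesh, thickness: float, n_layers: int = 2) -> WallMesh:
    """Offset the surface outward into a tet wall mesh of given thickness.

    Raises
    ------
    MeshingError
        If the offset self-intersects (non-positive tet volumes), with
        the offending vertex indices named.
    """
    if thickness <= 0:
        raise MeshingError("thickness must be positive")
    if n_layers < 1:
        raise MeshingError("n_layers must be >= 1")
    normals = vertex_normals(surface)
    nv = surface.n_vertices
    shells = [
        surface.vertices + normals * (thickness * l / n_layers)
        for l in range(n_layers + 1)
    ]
    nodes = np.vstack(shells)

    tets = []
    for l in range(n_layers):
        lo = l * nv
        hi = (l + 1) * nv
        for tri in surface.triangles:
            tets.append(_split_prism(tri + lo, tri + hi))
    tets = np.vstack(tets)

    mesh = WallMesh(nodes=nodes, tets=tets)
    vols = mesh.tet_volumes()
    # A valid extrusion has a single consistent sign determined by the
    # surface orientation: flip GLOBALLY if the majority is negative,
    # then any leftover non-positive volume is a genuine local inversion
    # (offset crossed itself), not an orientation artefact.
    if np.median(np.sign(vols)) < 0:
        mesh.tets = mesh.tets[:, [0, 2, 1, 3]]
        vols = -vols
    bad = vols <= 1e-12
    if bad.any():
        offenders = np.unique(mesh.tets[bad] % nv)[:20]
        raise MeshingError(
            "offset self-intersection (thickness too large for local "
            f"curvature); offending surface vertices: {offenders.tolist()}"
        )
    return mesh


def tag_boundaries(mesh: WallMesh, surface: SurfaceMesh) -> WallMesh:
    """Attach inlet/outlet node sets and the inner-surface (lumen) faces.

    Inlet gathers every through-thickness copy of the z-min boundary
    loop of the lumen surface, outlet likewise at z-max. Lumen faces are
    the original surface triangles (layer-0 node indices), oriented so
    their normals point into the lumen.
    """
    loops = surface.boundary_loops()
    if not loops:
        raise MeshingError("closed surface: no boundary loops to tag")
    if len(loops) != 2:
        raise MeshingError(f"expected 2 boundary loops, found {len(loops)}")
    zmean = [surface.vertices[lp][:, 2].mean() for lp in loops]
    lo_loop = loops[int(np.argmin(zmean))]
    hi_loop = loops[int(np.argmax(zmean))]

    nv = surface.n_vertices
    n_layers = mesh.n_nodes // nv - 1
    layers = np.arange(n_layers + 1) * nv
    inlet = np.concatenate([lo_loop + off for off in layers])
    outlet = np.concatenate([hi_loop + off for off in layers])

    # orient each lumen face so its normal points away from the wall,
    # i.e. opposite the offset direction of its vertices
    faces = surface.triangles.copy()
    v = mesh.nodes
    offset_dir = mesh.nodes[nv : 2 * nv] - mesh.nodes[:nv]  # into the wall
    fc = np.cross(
        v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]]
    )
    face_off = offset_dir[faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", fc, face_off) > 0
    faces[flip] = faces[flip][:, [0, 2, 1]]

    return WallMesh(
        nodes=mesh.nodes,
        tets=mesh.tets,
        inlet_nodes=np.unique(inlet),
        outlet_nodes=np.unique(outlet),
        lumen_faces=faces,
        element_size_target=mesh.element_size_target,
    )


def boundary_nodes(mesh: WallMesh) -> np.ndarray:
    """Nodes lying on the mesh boundary (on faces owned by a single tet)."""
    t = mesh.tets
    faces = np.vstack(
        [t[:, [0, 1, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 3]], t[:, [1, 2, 3]]]
    )
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def check_conforming(mesh: WallMesh) -> bool:
    """Every interior triangular face shared by exactly 2 tets, boundary by 1."""
    t = mesh.tets
    faces = np.vstack(
        [t[:, [0, 1, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 3]], t[:, [1, 2, 3]]]
    )
    faces = np.sort(faces, axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    return bool(np.all((counts == 1) | (counts == 2)))


def build_wall_mesh(
    spec,
    element_size: float = 1.0,
    n_layers: int = 2,
    thickness: float | None = None,
) -> WallMesh:
    """Convenience: synthetic lumen surface -> extruded, tagged wall mesh.

    Circumferential and axial vertex counts are chosen so element edges
    approach ``element_size`` at the widest section.
    """
    from .synthetic_anatomy import generate_lumen_surface

    if thickness is None:
        thickness = spec.wall_thickness
    n_circ = max(8, int(np.ceil(2 * np.pi * spec.max_radius / element_size)))
    n_ax = max(8, int(np.ceil(spec.total_length / element_size)) + 1)
    surface = generate_lumen_surface(spec, n_circumferential=n_circ, n_axial=n_ax)
    mesh = extrude_wall(surface, thickness=thickness, n_layers=n_layers)
    mesh.element_size_target = element_size
    return tag_boundaries(mesh, surface)
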