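"""Triangulated surface mesh type and basic geometric queries.

Coordinates are millimetres throughout. The mesh is a plain
vertex/triangle soup with consistent orientation; higher-level modules
(:mod:`aneufem.synthetic_anatomy`, :mod:`aneufem.reconstruct`) construct
instances and guarantee orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SurfaceValidationError(ValueError):
    """Raised when a surface mesh violates a structural invariant."""


@dataclass
class SurfaceMesh:
    """Open or closed triangulated surface in physical (mm) coordinates.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices, consistently oriented
    provenance : free-text note on how the surface was produced
    """

    vertices: np.ndarray
    triangles: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SurfaceValidationError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise SurfaceValidationError("triangles must be (m, 3)")
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise SurfaceValidationError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    # -- geometry ---------------------------------------------------------

    def triangle_cross(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_cross(), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def triangle_normals(self) -> np.ndarray:
        """Unit normals per triangle (right-hand rule on vertex order)."""
        c = self.triangle_cross()
        n = np.linalg.norm(c, axis=1, keepdims=True)
        if np.any(n == 0):
            raise SurfaceValidationError("degenerate (zero-area) triangle")
        return c / n

    def signed_volume(self) -> float:
        """Enclosed volume by the divergence theorem; meaningful when closed.

        Positive for outward-oriented closed surfaces.
        """
        v = self.vertices
        t = self.triangles
        return float(
            np.einsum("ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])).sum()
            / 6.0
        )

    def volume(self) -> float:
        return abs(self.signed_volume())

    # -- topology ---------------------------------------------------------

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and their incidence counts."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def euler_characteristic(self) -> int:
        uniq, _ = self.edges()
        used = np.unique(self.triangles)
        return int(len(used) - len(uniq) + len(self.triangles))

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edges()
        return uniq[counts == 1]

    def is_watertight(self) -> bool:
        """Closed 2-manifold: every edge shared by exactly two triangles."""
        _, counts = self.edges()
        return bool(len(counts)) and bool(np.all(counts == 2))

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of the surface boundary (open surfaces)."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        nxt: dict[int, list[int]] = {}
        for a, b in be:
            nxt.setdefault(int(a), []).append(int(b))
            nxt.setdefault(int(b), []).append(int(a))
        visited: set[int] = set()
        loops = []
        for start in sorted(nxt):
            if start in visited:
                continue
            loop = [start]
            visited.add(start)
            cur = start
            while True:
                cand = [v for v in nxt[cur] if v not in visited]
                if not cand:
                    break
                cur = cand[0]
                loop.append(cur)
                visited.add(cur)
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def drop_degenerate(self, min_area: float = 1e-12) -> "SurfaceMesh":
        keep = self.triangle_areas() > min_area
        return SurfaceMesh(self.vertices, self.triangles[keep], self.provenance)


def cap_ends(mesh: SurfaceMesh) -> SurfaceMesh:
    """Close each boundary loop with a triangle fan about its centroid.

    Fan orientation is chosen so the capped surface has positive signed
    volume when the input tube is outward-oriented.
    """
    loops = mesh.boundary_loops()
    if not loops:
        return mesh
    verts = [mesh.vertices]
    tris = [mesh.triangles]
    n = mesh.n_vertices
    for loop in loops:
        centroid = mesh.vertices[loop].mean(axis=0)
        verts.append(centroid[None, :])
        m = len(loop)
        fan = np.column_stack(
            [np.full(m, n), loop, np.roll(loop, -1)]
        )
        tris.append(fan)
        n += 1
    capped = SurfaceMesh(
        np.vstack(verts), np.vstack(tris), provenance=mesh.provenance + "+caps"
    )
    if capped.signed_volume() < 0:
        # flip only the fans, keeping original orientation
        t = capped.triangles.copy()
        fans = slice(mesh.n_triangles, None)
        trial = t.copy()
        trial[fans] = trial[fans][:, [0, 2, 1]]
        trial_mesh = SurfaceMesh(capped.vertices, trial, capped.provenance)
        if abs(trial_mesh.signed_volume()) >= abs(capped.signed_volume()):
            capped = trial_mesh
    return capped


def max_section_diameter(
    points: np.ndarray, axis: int = 2, bin_width: float = 2.0
) -> float:
    """Largest cross-sectional max chord of a point cloud along ``axis``.

    Points are binned along the axis; each bin's diameter is the maximum
    pairwise in-plane distance, taken over the bin's convex hull. Exact
    for (possibly offset) circular sections and, unlike a
    centroid-based radius, unbiased by uneven vertex density.
    """
    from scipy.spatial import ConvexHull, QhullError

    v = np.asarray(points, dtype=float)
    other = [i for i in range(3) if i != axis]
    z = v[:, axis]
    bins = np.floor((z - z.min()) / bin_width).astype(int)
    best = 0.0
    for b in np.unique(bins):
        pts = v[bins == b][:, other]
        if len(pts) < 3:
            continue
        if len(pts) > 4:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        best = max(best, float(np.sqrt(d2.max())))
    return best


def max_diameter(mesh: SurfaceMesh, axis: int = 2, bin_width: float = 2.0) -> float:
    """Largest cross-sectional diameter of the surface perpendicular to ``axis``."""
    return max_section_diameter(mesh.vertices, axis=axis, bin_width=bin_width)
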