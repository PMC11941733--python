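"""Parametric fusiform aneurysm geometries and noisy voxel phantoms.

The anatomy is a single unbranched tube of revolution whose radius
follows a Gaussian bulge:

    r(z) = r_neck + (r_max - r_neck) * exp(-((z - z_c) / w)^2)

An ``asymmetry`` parameter in [0, 1] shifts the bulge off-axis in +x by
``asymmetry * (r(z) - r_neck)`` so the cross-sections remain circles of
radius r(z). Phantoms voxelise the lumen with two intensity levels plus
seeded Gaussian noise, standing in for contrast CT volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .surface import SurfaceMesh

#: Intensity levels of the phantom (arbitrary units); thresholds are relative.
I_IN = 1.0
I_OUT = 0.0

#: Cohort diagnostic-diameter range, mm.
DIAMETER_RANGE = (48.0, 68.0)


class AnatomyValidationError(ValueError):
    """Raised for geometrically impossible anatomy parameters."""


@dataclass(frozen=True)
class AnatomySpec:
    """Parametric description of a fusiform aneurysm.

    All lengths in millimetres. ``2 * max_radius`` is the diagnostic
    diameter; the cohort generator keeps it in :data:`DIAMETER_RANGE`.
    """

    neck_radius: float = 11.0
    max_radius: float = 25.0
    bulge_center: float = 60.0
    bulge_width: float = 22.0
    total_length: float = 120.0
    wall_thickness: float = 2.0
    asymmetry: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.neck_radius > 0:
            raise AnatomyValidationError("neck_radius must be positive")
        if self.max_radius < self.neck_radius:
            raise AnatomyValidationError("max_radius must be >= neck_radius")
        if not 0 < self.bulge_center < self.total_length:
            raise AnatomyValidationError("bulge_center must lie inside the axis")
        if not self.bulge_width > 0:
            raise AnatomyValidationError("bulge_width must be positive")
        if not self.wall_thickness > 0:
            raise AnatomyValidationError("wall_thickness must be positive")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise AnatomyValidationError("asymmetry must be in [0, 1]")

    @property
    def diagnostic_diameter(self) -> float:
        return 2.0 * self.max_radius

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnatomySpec":
        return cls(**json.loads(text))


@dataclass
class VoxelVolume:
    """Scalar intensity grid with physical spacing and origin (mm)."""

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def radius_profile(spec: AnatomySpec, z) -> np.ndarray | float:
    """Lumen radius at axial position(s) ``z`` (mm).

    Raises
    ------
    AnatomyValidationError
        If any z lies outside [0, total_length].
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0) or np.any(z_arr > spec.total_length):
        raise AnatomyValidationError(
            f"z outside [0, {spec.total_length}] mm"
        )
    r = spec.neck_radius + (spec.max_radius - spec.neck_radius) * np.exp(
        -(((z_arr - spec.bulge_center) / spec.bulge_width) ** 2)
    )
    return r if r.ndim else float(r)


def axis_offset(spec: AnatomySpec, z) -> np.ndarray | float:
    """Off-axis (+x) shift of the section centre at ``z``; zero when symmetric."""
    z_arr = np.asarray(z, dtype=float)
    r = spec.neck_radius + (spec.max_radius - spec.neck_radius) * np.exp(
        -(((z_arr - spec.bulge_center) / spec.bulge_width) ** 2)
    )
    off = spec.asymmetry * (r - spec.neck_radius)
    return off if off.ndim else float(off)


def lumen_volume_analytic(spec: AnatomySpec, n_quad: int = 4001) -> float:
    """Analytic lumen volume: axial quadrature of pi * r(z)^2 dz (mm^3).

    Cross-sections are offset circles, so the off-axis shift does not
    change sectional area.
    """
    from scipy.integrate import simpson

    z = np.linspace(0.0, spec.total_length, n_quad)
    r = radius_profile(spec, z)
    return float(simpson(np.pi * np.asarray(r) ** 2, x=z))


def generate_lumen_surface(
    spec: AnatomySpec, n_circumferential: int = 64, n_axial: int = 96
) -> SurfaceMesh:
    """Open-ended, outward-oriented triangulated tube of revolution.

    Vertices are arranged in ``n_axial`` rings of ``n_circumferential``
    points; the two boundary loops sit at z = 0 and z = total_length.
    """
    if n_circumferential < 8 or n_axial < 8:
        raise AnatomyValidationError("need n_circumferential >= 8 and n_axial >= 8")
    nc, na = n_circumferential, n_axial
    z = np.linspace(0.0, spec.total_length, na)
    r = np.asarray(radius_profile(spec, z))
    cx = np.asarray(axis_offset(spec, z))
    theta = np.linspace(0.0, 2.0 * np.pi, nc, endpoint=False)

    verts = np.empty((na * nc, 3))
    verts[:, 0] = (np.outer(r, np.cos(theta)) + cx[:, None]).ravel()
    verts[:, 1] = np.outer(r, np.sin(theta)).ravel()
    verts[:, 2] = np.repeat(z, nc)

    # two triangles per quad; winding chosen so normals point outward
    j = np.arange(nc)
    jn = (j + 1) % nc
    tris = []
    for i in range(na - 1):
        a = i * nc + j
        b = i * nc + jn
        c = (i + 1) * nc + j
        d = (i + 1) * nc + jn
        tris.append(np.column_stack([a, b, d]))
        tris.append(np.column_stack([a, d, c]))
    mesh = SurfaceMesh(
        verts,
        np.vstack(tris),
        provenance=f"synthetic tube nc={nc} na={na}",
    )
    # orientation sanity: mean dot of triangle normal with radial direction
    normals = mesh.triangle_normals()
    cent = mesh.vertices[mesh.triangles].mean(axis=1)
    radial = cent.copy()
    radial[:, 2] = 0.0
    if np.mean(np.einsum("ij,ij->i", normals, radial)) < 0:
        mesh = SurfaceMesh(verts, mesh.triangles[:, [0, 2, 1]], mesh.provenance)
    return mesh


def generate_phantom_volume(
    spec: AnatomySpec,
    voxel_size: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin: float = 6.0,
) -> VoxelVolume:
    """Voxel phantom of the lumen: I_IN inside, I_OUT outside, plus noise.

    Deterministic for fixed ``(spec, voxel_size, noise_sd, seed)``.

    Raises
    ------
    AnatomyValidationError
        If ``voxel_size`` exceeds the neck radius (geometry unresolvable).
    """
    if voxel_size <= 0:
        raise AnatomyValidationError("voxel_size must be positive")
    if voxel_size > spec.neck_radius:
        raise AnatomyValidationError(
            f"voxel_size {voxel_size} mm cannot resolve neck radius "
            f"{spec.neck_radius} mm"
        )
    rmax = spec.max_radius * (1.0 + spec.asymmetry)
    x0 = -(rmax + margin)
    y0 = -(spec.max_radius + margin)
    z0 = -margin
    nx = int(np.ceil((2 * (rmax + margin)) / voxel_size)) + 1
    ny = int(np.ceil((2 * (spec.max_radius + margin)) / voxel_size)) + 1
    nz = int(np.ceil((spec.total_length + 2 * margin) / voxel_size)) + 1

    xs = x0 + voxel_size * np.arange(nx)
    ys = y0 + voxel_size * np.arange(ny)
    zs = z0 + voxel_size * np.arange(nz)

    inside = np.zeros((nx, ny, nz), dtype=bool)
    zmask = (zs >= 0.0) & (zs <= spec.total_length)
    zin = zs[zmask]
    r = np.asarray(radius_profile(spec, zin))
    cx = np.asarray(axis_offset(spec, zin))
    dx2 = (xs[:, None, None] - cx[None, None, :]) ** 2  # (nx, 1, nzin)
    dy2 = ys[None, :, None] ** 2  # (1, ny, 1)
    inside[:, :, zmask] = dx2 + dy2 <= (r**2)[None, None, :]

    intens = np.where(inside, I_IN, I_OUT).astype(np.float32)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd, intens.shape).astype(np.float32)
    return VoxelVolume(
        intensities=intens,
        spacing=np.full(3, voxel_size),
        origin=np.array([x0, y0, z0]),
    )


def sample_cohort(n: int, seed: int = 0) -> list[AnatomySpec]:
    """Draw ``n`` anatomy specs with diagnostic diameters ~ U(48, 68) mm."""
    if n < 1:
        raise AnatomyValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = DIAMETER_RANGE
    diameters = rng.uniform(lo, hi, n)
    widths = rng.uniform(18.0, 28.0, n)
    asym = rng.uniform(0.0, 0.3, n)
    specs = []
    for i in range(n):
        specs.append(
            AnatomySpec(
                neck_radius=11.0,
                max_radius=diameters[i] / 2.0,
                bulge_center=60.0,
                bulge_width=float(widths[i]),
                total_length=120.0,
                wall_thickness=2.0,
                asymmetry=float(asym[i]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def cohort_to_json(specs: list[AnatomySpec]) -> str:
    return json.dumps([asdict(s) for s in specs], indent=1)


def cohort_from_json(text: str) -> list[AnatomySpec]:
    return [AnatomySpec(**d) for d in json.loads(text)]
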