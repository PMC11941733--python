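"""Readers and writers for the pipeline's interchange formats.

STL (ASCII and binary) for surfaces, VTU (ASCII XML) for volume meshes
and fields, NIfTI and raw+JSON-header for voxel volumes, and a simple
documented plain-text node/element format for wall meshes.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .surface import SurfaceMesh
from .synthetic_anatomy import VoxelVolume


# ---------------------------------------------------------------- STL

def write_stl(mesh: SurfaceMesh, path: str | Path, binary: bool = True) -> None:
    path = Path(path)
    tris = mesh.vertices[mesh.triangles]  # (m, 3, 3)
    normals = mesh.triangle_normals()
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tris)))
            rec = np.zeros((len(tris), 12), dtype="<f4")
            rec[:, 0:3] = normals
            rec[:, 3:12] = tris.reshape(len(tris), 9)
            raw = np.zeros(
                len(tris),
                dtype=np.dtype([("data", "<f4", 12), ("attr", "<u2")]),
            )
            raw["data"] = rec
            fh.write(raw.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid aneufem\n")
            for n, t in zip(normals, tris):
                fh.write(f"facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write(" outer loop\n")
                for v in t:
                    fh.write(f"  vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid aneufem\n")


def read_stl(path: str | Path) -> SurfaceMesh:
    """Read ASCII or binary STL, merging exactly coincident vertices."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head == b"solid":
        # could still be binary with a 'solid' header; check parseability
        try:
            return _read_stl_ascii(path)
        except ValueError:
            pass
    return _read_stl_binary(path)


def _read_stl_ascii(path: Path) -> SurfaceMesh:
    pts = []
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            parts = line.split()
            if parts[:1] == ["vertex"]:
                pts.append([float(x) for x in parts[1:4]])
    if not pts or len(pts) % 3:
        raise ValueError("not a valid ASCII STL")
    return _soup_to_mesh(np.array(pts), str(path))


def _read_stl_binary(path: Path) -> SurfaceMesh:
    with open(path, "rb") as fh:
        fh.seek(80)
        (n,) = struct.unpack("<I", fh.read(4))
        raw = np.frombuffer(
            fh.read(n * 50),
            dtype=np.dtype([("data", "<f4", 12), ("attr", "<u2")]),
        )
    pts = raw["data"][:, 3:12].reshape(-1, 3).astype(float)
    return _soup_to_mesh(pts, str(path))


def _soup_to_mesh(pts: np.ndarray, provenance: str) -> SurfaceMesh:
    uniq, inverse = np.unique(pts.round(decimals=8), axis=0, return_inverse=True)
    tris = inverse.reshape(-1, 3)
    return SurfaceMesh(uniq, tris, provenance=f"stl:{provenance}")


# ---------------------------------------------------------------- VTU

_VTK_TET = 10
_VTK_TRI = 5


def write_vtu(
    path: str | Path,
    points: np.ndarray,
    cells: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """ASCII XML UnstructuredGrid with tet (4-node) or tri (3-node) cells."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    ctype = _VTK_TET if cells.shape[1] == 4 else _VTK_TRI
    npts, ncells = len(points), len(cells)

    def arr(a: np.ndarray) -> str:
        return " ".join(f"{x:.10g}" for x in np.asarray(a, dtype=float).ravel())

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        " <UnstructuredGrid>",
        f'  <Piece NumberOfPoints="{npts}" NumberOfCells="{ncells}">',
        "   <Points>",
        f'    <DataArray type="Float64" NumberOfComponents="3" format="ascii">'
        f"{arr(points)}</DataArray>",
        "   </Points>",
        "   <Cells>",
        f'    <DataArray type="Int64" Name="connectivity" format="ascii">'
        f'{" ".join(map(str, cells.ravel()))}</DataArray>',
        f'    <DataArray type="Int64" Name="offsets" format="ascii">'
        f'{" ".join(map(str, np.arange(1, ncells + 1) * cells.shape[1]))}</DataArray>',
        f'    <DataArray type="UInt8" Name="types" format="ascii">'
        f'{" ".join([str(ctype)] * ncells)}</DataArray>',
        "   </Cells>",
    ]
    for tag, data in (("PointData", point_data), ("CellData", cell_data)):
        if not data:
            continue
        lines.append(f"   <{tag}>")
        for name, a in data.items():
            a = np.asarray(a, dtype=float)
            ncomp = 1 if a.ndim == 1 else a.shape[1]
            lines.append(
                f'    <DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">{arr(a)}</DataArray>'
            )
        lines.append(f"   </{tag}>")
    lines += ["  </Piece>", " </UnstructuredGrid>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------- volumes

def write_nifti(volume: VoxelVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), str(path))


def read_nifti(path: str | Path) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    return VoxelVolume(
        intensities=np.asarray(img.dataobj, dtype=np.float32),
        spacing=spacing,
        origin=affine[:3, 3],
    )


def write_raw_volume(volume: VoxelVolume, stem: str | Path) -> None:
    """float32 little-endian .raw alongside a .json header."""
    stem = Path(stem)
    volume.intensities.astype("<f4").tofile(stem.with_suffix(".raw"))
    header = {
        "shape": list(volume.shape),
        "dtype": "<f4",
        "order": "C",
        "spacing_mm": list(map(float, volume.spacing)),
        "origin_mm": list(map(float, volume.origin)),
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_raw_volume(stem: str | Path) -> VoxelVolume:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".raw"), dtype=header["dtype"]).reshape(
        header["shape"]
    )
    return VoxelVolume(
        intensities=data,
        spacing=np.array(header["spacing_mm"]),
        origin=np.array(header["origin_mm"]),
    )


# ------------------------------------------------------- wall mesh text

def write_wall_mesh_text(mesh, path: str | Path) -> None:
    """Plain-text wall mesh: header JSON line, then nodes and tets.

    Format::

        #aneufem-wallmesh {json header}
        n <x> <y> <z>        # one per node, mm
        t <i> <j> <k> <l>    # one per tetrahedron
    """
    header = {
        "n_nodes": int(len(mesh.nodes)),
        "n_tets": int(len(mesh.tets)),
        "inlet_nodes": [int(i) for i in mesh.inlet_nodes],
        "outlet_nodes": [int(i) for i in mesh.outlet_nodes],
        "lumen_faces": [[int(j) for j in f] for f in mesh.lumen_faces],
        "element_size_target": float(mesh.element_size_target),
    }
    with open(path, "w") as fh:
        fh.write("#aneufem-wallmesh " + json.dumps(header) + "\n")
        for p in mesh.nodes:
            fh.write(f"n {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        for t in mesh.tets:
            fh.write(f"t {t[0]} {t[1]} {t[2]} {t[3]}\n")


def read_wall_mesh_text(path: str | Path):
    from .wall_mesher import WallMesh

    nodes, tets = [], []
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#aneufem-wallmesh"):
                header = json.loads(line.split(" ", 1)[1])
            elif line.startswith("n "):
                nodes.append([float(x) for x in line.split()[1:4]])
            elif line.startswith("t "):
                tets.append([int(x) for x in line.split()[1:5]])
    if header is None:
        raise ValueError("missing wall-mesh header line")
    return WallMesh(
        nodes=np.array(nodes),
        tets=np.array(tets, dtype=np.int64),
        inlet_nodes=np.array(header["inlet_nodes"], dtype=np.int64),
        outlet_nodes=np.array(header["outlet_nodes"], dtype=np.int64),
        lumen_faces=np.array(header["lumen_faces"], dtype=np.int64),
        element_size_target=header["element_size_target"],
    )
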