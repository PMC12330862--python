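"""Readers and writers for mesh and per-vertex map formats.

Surfaces: FreeSurfer binary, GIFTI, OFF, ASCII PLY; volumes: TetGen-style
.node/.ele pairs and legacy ASCII VTK unstructured grids.  Maps: GIFTI
func/shape, FreeSurfer curv, NIfTI volumes (with a voxel-to-vertex table),
and plain text (one value per line).  NaN on input becomes mask=False;
vertex order is preserved exactly.  Connectivity is 0-based everywhere in
memory; .node/.ele files keep their native 1-based indices on disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import SurfaceMap, TetMesh, TriangleMesh

__all__ = ["read_mesh", "write_mesh", "read_map", "write_map"]

_MESH_FORMATS = ("freesurfer-surface", "gifti", "off", "ply", "node-ele", "vtk")
_MAP_FORMATS = ("gifti", "curv", "nifti", "text")


class FormatError(ValueError):
    """Unparseable file; the message names the offending line."""


def _sniff_mesh_format(path: Path) -> str:
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".gii"):
        return "gifti"
    if suffix.endswith(".off"):
        return "off"
    if suffix.endswith(".ply"):
        return "ply"
    if suffix.endswith(".node") or suffix.endswith(".ele"):
        return "node-ele"
    if suffix.endswith(".vtk"):
        return "vtk"
    return "freesurfer-surface"


def read_mesh(path, format: str | None = None):
    """Read a triangle or tetrahedral mesh; format inferred from the suffix
    when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_mesh_format(path)
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_MESH_FORMATS}")
    return {
        "freesurfer-surface": _read_fs_surface,
        "gifti": _read_gifti_surface,
        "off": _read_off,
        "ply": _read_ply,
        "node-ele": _read_node_ele,
        "vtk": _read_vtk,
    }[fmt](path)


def write_mesh(mesh, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _sniff_mesh_format(path)
    if isinstance(mesh, TetMesh) and fmt not in ("node-ele", "vtk"):
        raise ValueError(f"tet meshes serialize to node-ele or vtk, not {fmt!r}")
    {
        "freesurfer-surface": _write_fs_surface,
        "gifti": _write_gifti_surface,
        "off": _write_off,
        "ply": _write_ply,
        "node-ele": _write_node_ele,
        "vtk": _write_vtk,
    }[fmt](mesh, path)


# -- FreeSurfer / GIFTI (via nibabel) ---------------------------------------

def _read_fs_surface(path: Path) -> TriangleMesh:
    import nibabel.freesurfer.io as fsio

    vertices, faces = fsio.read_geometry(str(path))
    return TriangleMesh(vertices, faces)


def _write_fs_surface(mesh: TriangleMesh, path: Path) -> None:
    import nibabel.freesurfer.io as fsio

    fsio.write_geometry(str(path), mesh.vertices, mesh.faces)


def _read_gifti_surface(path: Path) -> TriangleMesh:
    import nibabel as nib

    img = nib.load(str(path))
    pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
    if not pts or not tris:
        raise FormatError(f"{path}: GIFTI file lacks POINTSET/TRIANGLE arrays")
    return TriangleMesh(pts[0].data, tris[0].data)


def _write_gifti_surface(mesh: TriangleMesh, path: Path) -> None:
    import nibabel as nib

    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


# -- OFF --------------------------------------------------------------------

def _read_off(path: Path) -> TriangleMesh:
    lines = path.read_text().splitlines()
    tokens = []
    for ln, raw in enumerate(lines, start=1):
        body = raw.split("#", 1)[0].strip()
        if body:
            tokens.append((ln, body))
    if not tokens or tokens[0][1].split()[0].upper() != "OFF":
        raise FormatError(f"{path}:1: missing OFF header")
    head = tokens[0][1].split()
    cursor = 1
    if len(head) >= 4 and head[0].upper() == "OFF":
        counts = head[1:4]
    else:
        counts = tokens[1][1].split()
        cursor = 2
    try:
        nv, nf = int(counts[0]), int(counts[1])
    except (ValueError, IndexError):
        raise FormatError(f"{path}:{tokens[min(cursor-1,1)][0]}: bad count line")
    verts, faces = [], []
    for ln, body in tokens[cursor:cursor + nv]:
        parts = body.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: expected 3 coordinates")
        verts.append([float(x) for x in parts[:3]])
    for ln, body in tokens[cursor + nv:cursor + nv + nf]:
        parts = body.split()
        if len(parts) < 4 or int(parts[0]) != 3:
            raise FormatError(f"{path}:{ln}: only triangle faces supported")
        faces.append([int(x) for x in parts[1:4]])
    if len(verts) != nv or len(faces) != nf:
        raise FormatError(f"{path}: truncated file ({len(verts)}/{nv} vertices, {len(faces)}/{nf} faces)")
    return TriangleMesh(np.array(verts), np.array(faces))


def _write_off(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- PLY (ASCII) ------------------------------------------------------------

def _read_ply(path: Path) -> TriangleMesh:
    import trimesh

    m = trimesh.load(str(path), file_type="ply", process=False, maintain_order=True)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- TetGen-style node/ele --------------------------------------------------

def _companion(path: Path):
    if path.suffix == ".node":
        return path, path.with_suffix(".ele")
    if path.suffix == ".ele":
        return path.with_suffix(".node"), path
    raise FormatError(f"{path}: node-ele format expects a .node or .ele path")


def _data_lines(path: Path):
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        body = raw.split("#", 1)[0].strip()
        if body:
            yield ln, body.split()


def _read_node_ele(path: Path) -> TetMesh:
    node_path, ele_path = _companion(Path(path))
    for p in (node_path, ele_path):
        if not p.exists():
            raise FileNotFoundError(p)
    rows = list(_data_lines(node_path))
    n = int(rows[0][1][0])
    verts = np.empty((n, 3))
    ids = np.empty(n, dtype=np.int64)
    for i, (ln, parts) in enumerate(rows[1:n + 1]):
        if len(parts) < 4:
            raise FormatError(f"{node_path}:{ln}: expected index + 3 coordinates")
        ids[i] = int(parts[0])
        verts[i] = [float(x) for x in parts[1:4]]
    offset = ids.min()  # native files are 1-based; tolerate 0-based too
    rows = list(_data_lines(ele_path))
    t = int(rows[0][1][0])
    tets = np.empty((t, 4), dtype=np.int64)
    for i, (ln, parts) in enumerate(rows[1:t + 1]):
        if len(parts) < 5:
            raise FormatError(f"{ele_path}:{ln}: expected index + 4 corners")
        tets[i] = [int(x) - offset for x in parts[1:5]]
    return TetMesh(verts, tets)


def _write_node_ele(mesh: TetMesh, path: Path) -> None:
    node_path, ele_path = _companion(Path(path))
    with open(node_path, "w") as fh:
        fh.write(f"{mesh.n_vertices} 3 0 0\n")
        for i, v in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
    with open(ele_path, "w") as fh:
        fh.write(f"{len(mesh.tets)} 4 0\n")
        for i, t in enumerate(mesh.tets, start=1):
            fh.write(f"{i} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")


# -- legacy VTK unstructured grid (ASCII) -----------------------------------

def _read_vtk(path: Path):
    lines = path.read_text().splitlines()
    i = 0

    def expect(predicate, what):
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or not predicate(lines[i]):
            raise FormatError(f"{path}:{i + 1}: expected {what}")
        i += 1
        return lines[i - 1]

    expect(lambda s: s.startswith("# vtk DataFile"), "VTK header")
    i += 1  # title line
    expect(lambda s: s.strip().upper() == "ASCII", "ASCII marker")
    expect(lambda s: "UNSTRUCTURED_GRID" in s, "DATASET UNSTRUCTURED_GRID")
    pts_line = expect(lambda s: s.startswith("POINTS"), "POINTS")
    npts = int(pts_line.split()[1])
    flat = []
    while len(flat) < 3 * npts:
        flat.extend(float(x) for x in lines[i].split())
        i += 1
    verts = np.array(flat).reshape(npts, 3)
    cells_line = expect(lambda s: s.startswith("CELLS"), "CELLS")
    ncells = int(cells_line.split()[1])
    cells = []
    for _ in range(ncells):
        parts = [int(x) for x in lines[i].split()]
        if parts[0] not in (3, 4):
            raise FormatError(f"{path}:{i + 1}: only triangle/tetra cells supported")
        cells.append(parts[1:])
        i += 1
    types_line = expect(lambda s: s.startswith("CELL_TYPES"), "CELL_TYPES")
    ntypes = int(types_line.split()[1])
    types = []
    while len(types) < ntypes:
        types.extend(int(x) for x in lines[i].split())
        i += 1
    types = np.array(types)
    if np.all(types == 10):
        return TetMesh(verts, np.array(cells))
    if np.all(types == 5):
        return TriangleMesh(verts, np.array(cells))
    raise FormatError(f"{path}: mixed or unsupported cell types {np.unique(types).tolist()}")


def _write_vtk(mesh, path: Path) -> None:
    is_tet = isinstance(mesh, TetMesh)
    cells = mesh.tets if is_tet else mesh.faces
    k = 4 if is_tet else 3
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\neigenstrap mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
        for c in cells:
            fh.write(" ".join([str(k)] + [str(x) for x in c]) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.write("\n".join(["10" if is_tet else "5"] * len(cells)) + "\n")


# ---------------------------------------------------------------------------
# scalar maps

def _sniff_map_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gii"):
        return "gifti"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".curv") or ".curv" in name or name.startswith(("lh.", "rh.")):
        return "curv"
    return "text"


def read_map(path, format: str | None = None, n_vertices: int | None = None,
             vertex_voxels: np.ndarray | None = None) -> SurfaceMap:
    """Read a per-vertex scalar map.  NaNs become mask=False.

    NIfTI volumes need `vertex_voxels`, an (N, 3) integer voxel index per
    vertex, to define the voxel-to-vertex mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_map_format(path)
    if fmt not in _MAP_FORMATS:
        raise ValueError(f"unknown map format {fmt!r}; expected one of {_MAP_FORMATS}")
    if fmt == "gifti":
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=np.float64)
    elif fmt == "curv":
        import nibabel.freesurfer.io as fsio

        values = np.asarray(fsio.read_morph_data(str(path)), dtype=np.float64)
    elif fmt == "nifti":
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if vertex_voxels is None:
            values = vol.ravel()
        else:
            idx = np.asarray(vertex_voxels, dtype=np.int64)
            values = vol[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        values = np.loadtxt(path, ndmin=1)
    if n_vertices is not None and values.size != n_vertices:
        raise ValueError(f"map has {values.size} records but mesh has {n_vertices} vertices")
    return SurfaceMap(values)


def write_map(surface_map: SurfaceMap, path, format: str | None = None) -> None:
    """Write a map; masked vertices are stored as NaN.  Text keeps full
    precision; GIFTI and curv store 32-bit floats."""
    path = Path(path)
    fmt = format or _sniff_map_format(path)
    vals = surface_map.values.copy()
    vals[~surface_map.mask] = np.nan
    if fmt == "gifti":
        import nibabel as nib

        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(vals.astype(np.float32),
                                     intent="NIFTI_INTENT_NONE")])
        nib.save(img, str(path))
    elif fmt == "curv":
        import nibabel.freesurfer.io as fsio

        fsio.write_morph_data(str(path), vals)
    elif fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(vals.reshape(-1, 1, 1), np.eye(4)), str(path))
    else:
        np.savetxt(path, vals, fmt="%.17g")
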