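"""Readers and writers for the standard interchange formats.

Surfaces come in as OFF/PLY (via trimesh), GIFTI or FreeSurfer binary
surfaces (via nibabel).  Tetrahedral meshes round-trip through legacy-ASCII
VTK unstructured grids (written here directly — the format is a plain text
table) and ABAQUS-style ``*NODE``/``*ELEMENT`` decks.  Streamlines use the
TCK/TRK formats through ``nibabel.streamlines``; volumes and orientation
fields use NIfTI-1.  All coordinates are mm; node and voxel indices are
0-based in memory (VTK/ABAQUS files use their native conventions on disk).

Every writer has a matching ``manifest`` helper so a run can record its
configuration, seed and package version next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import trimesh

from .fibers import FiberSet, OrientationField
from .grid import VoxelGrid
from .mesh import (WHITE, Atlas, TetMesh, extract_surface, tet_volumes)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# surfaces

_SURFACE_EXT = {".off": "off", ".ply": "ply", ".gii": "gifti",
                ".surf": "freesurfer", ".white": "freesurfer",
                ".pial": "freesurfer"}


def read_surface(path, fmt: Optional[str] = None):
    """Read a triangle surface; returns (vertices mm, faces, report dict).

    Formats: 'off', 'ply', 'gifti', 'freesurfer' (binary surface).  Faces
    are 0-based; winding is made consistent (and the fix is reported) using
    trimesh's orientation repair.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _SURFACE_EXT.get(path.suffix.lower())
    if fmt in ("off", "ply"):
        mesh = trimesh.load(str(path), file_type=fmt, process=False)
        if not isinstance(mesh, trimesh.Trimesh):
            raise FormatError(f"{path} did not parse as a triangle mesh")
        verts, faces = np.asarray(mesh.vertices, float), np.asarray(mesh.faces)
    elif fmt == "gifti":
        img = nib.load(str(path))
        verts = np.asarray(img.darrays[0].data, dtype=float)
        faces = np.asarray(img.darrays[1].data, dtype=int)
    elif fmt == "freesurfer":
        verts, faces = nib.freesurfer.read_geometry(str(path))
        verts = np.asarray(verts, dtype=float)
        faces = np.asarray(faces, dtype=int)
    else:
        raise FormatError(f"unknown surface format for {path}")

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    consistent = bool(tm.is_winding_consistent)
    if not consistent:
        trimesh.repair.fix_normals(tm)
    report = {"n_vertices": len(verts), "n_faces": len(faces),
              "winding_consistent_on_load": consistent,
              "reoriented": not consistent}
    return np.asarray(tm.vertices, float), np.asarray(tm.faces, int), report


def write_surface_off(vertices, faces, path):
    """Minimal OFF writer for round-trip tests and exports."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(vertices)} {len(faces)} 0\n")
        for v in vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# tetrahedral meshes

def write_vtk(mesh: TetMesh, path, positions: Optional[np.ndarray] = None):
    """Legacy-ASCII VTK unstructured grid with tissue/parcel point data."""
    pos = mesh.nodes if positions is None else np.asarray(positions)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("refold tetrahedral mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in pos:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join(["10"] * mesh.n_tets) + "\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in mesh.tissue) + "\n")
        if mesh.parcel is not None:
            fh.write("SCALARS parcel int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(p)) for p in mesh.parcel) + "\n")


def read_vtk(path) -> TetMesh:
    """Read a legacy-ASCII VTK unstructured grid of tetrahedra."""
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 5 or "vtk" not in lines[0].lower():
        raise FormatError(f"{path}: not a legacy VTK file")
    i = 0
    points = tets = None
    tissue = parcel = None
    n_nodes = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            n_nodes = n
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            points = np.array(vals).reshape(n, 3)
        elif key == "CELLS":
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < int(parts[2]):
                vals.extend(int(x) for x in lines[i].split())
                i += 1
            cells = np.array(vals).reshape(n, -1)
            if cells.shape[1] != 5 or not (cells[:, 0] == 4).all():
                raise FormatError(f"{path}: non-tetrahedral cells")
            tets = cells[:, 1:]
        elif key == "SCALARS" and len(parts) > 1:
            name = parts[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n_nodes and i < len(lines):
                vals.extend(int(float(x)) for x in lines[i].split())
                i += 1
            if name == "tissue":
                tissue = np.array(vals, dtype=np.uint8)
            elif name == "parcel":
                parcel = np.array(vals, dtype=int)
        else:
            i += 1
    if points is None or tets is None:
        raise FormatError(f"{path}: missing POINTS or CELLS")
    if tissue is None:
        tissue = np.full(len(points), WHITE, dtype=np.uint8)
    surface = extract_surface(points, tets)
    return TetMesh(nodes=points, tets=tets, tissue=tissue,
                   surface_faces=surface,
                   face_region=np.ones(len(surface), dtype=np.uint8),
                   parcel=parcel, meta={"source": str(path)})


def read_abaqus(path) -> TetMesh:
    """Read an ABAQUS-style ``*NODE`` / ``*ELEMENT`` tetrahedral deck.

    1-based ids on disk are remapped to dense 0-based indices.
    """
    nodes = {}
    elems = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                head = line.upper()
                section = ("node" if head.startswith("*NODE")
                           else "element" if head.startswith("*ELEMENT")
                           else None)
                continue
            parts = [p for p in line.replace(",", " ").split()]
            if section == "node" and len(parts) >= 4:
                nodes[int(parts[0])] = [float(x) for x in parts[1:4]]
            elif section == "element" and len(parts) >= 5:
                elems.append([int(x) for x in parts[1:5]])
    if not nodes or not elems:
        raise FormatError(f"{path}: no nodes or elements found")
    ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(ids)}
    pts = np.array([nodes[nid] for nid in ids])
    tets = np.array([[remap[i] for i in e] for e in elems])
    vols = tet_volumes(pts, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    surface = extract_surface(pts, tets)
    return TetMesh(nodes=pts, tets=tets,
                   tissue=np.full(len(pts), WHITE, dtype=np.uint8),
                   surface_faces=surface,
                   face_region=np.ones(len(surface), dtype=np.uint8),
                   meta={"source": str(path)})


def write_node_tet_text(mesh: TetMesh, nodes_path, tets_path):
    """Plain-text node (x y z) and tet (i0 i1 i2 i3) tables, 0-based."""
    np.savetxt(nodes_path, mesh.nodes, fmt="%.17g")
    np.savetxt(tets_path, mesh.tets, fmt="%d")


def read_node_tet_text(nodes_path, tets_path,
                       tissue: Optional[np.ndarray] = None) -> TetMesh:
    pts = np.loadtxt(nodes_path, ndmin=2)
    tets = np.loadtxt(tets_path, dtype=int, ndmin=2)
    surface = extract_surface(pts, tets)
    return TetMesh(nodes=pts, tets=tets,
                   tissue=(tissue if tissue is not None
                           else np.full(len(pts), WHITE, dtype=np.uint8)),
                   surface_faces=surface,
                   face_region=np.ones(len(surface), dtype=np.uint8),
                   meta={"source": str(nodes_path)})


def read_atlas(path) -> Atlas:
    """Atlas from a FreeSurfer annot file or a plain text table.

    Text tables are either one integer label per line (paired with an
    external vertex list) or ``x y z label`` rows.
    """
    path = Path(path)
    if path.suffix == ".annot":
        labels, ctab, names = nib.freesurfer.read_annot(str(path))
        raise FormatError(
            "annot files carry labels only; pair them with surface vertices "
            "via Atlas(vertices, labels)")
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 4:
        return Atlas(vertices=data[:, :3], labels=data[:, 3].astype(int))
    raise FormatError(f"{path}: expected 'x y z label' rows")


def read_annot_labels(path) -> np.ndarray:
    """Per-vertex integer labels from a FreeSurfer annot file."""
    labels, _, _ = nib.freesurfer.read_annot(str(path))
    return np.asarray(labels, dtype=int)


# ---------------------------------------------------------------------------
# streamlines

def write_fibers(fibers: FiberSet, path, fmt: Optional[str] = None,
                 affine: Optional[np.ndarray] = None):
    """Write streamlines as TCK (world mm) or TRK (with a voxel affine)."""
    if len(fibers) == 0:
        raise ValueError("refusing to write an empty fiber set")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(f, dtype=np.float32) for f in fibers],
        affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        nib.streamlines.save(tractogram, str(path))
    elif fmt == "trk":
        aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
        header = nib.streamlines.trk.TrkFile.create_empty_header()
        header["voxel_to_rasmm"] = aff.astype(np.float32)
        header["voxel_sizes"] = np.linalg.norm(aff[:3, :3], axis=0).astype(np.float32)
        header["voxel_order"] = "RAS"
        nib.streamlines.save(tractogram, str(path), header=header)
    else:
        raise FormatError(f"unknown streamline format {fmt!r}")


def read_fibers(path) -> FiberSet:
    tf = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    return FiberSet(fibers=streamlines, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# volumes

def write_volume(data: np.ndarray, affine: np.ndarray, path):
    """Scalar (3-D) or 3-vector (4-D, last dim 3) NIfTI-1 volume."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))


def read_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_orientation_field(field: OrientationField, path):
    """Orientation field as a 4-D NIfTI (x,y,z components); NaN marks empty."""
    data = field.vectors.copy()
    data[~field.mask] = np.nan
    write_volume(data, field.grid.affine(), path)


def read_orientation_field(path) -> OrientationField:
    data, affine = read_volume(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected a 4-D 3-vector volume")
    spacing = float(np.linalg.norm(affine[:3, 0]))
    origin = tuple(affine[:3, 3] - 0.5 * spacing)
    grid = VoxelGrid(origin=origin, spacing=spacing, shape=data.shape[:3])
    mask = np.isfinite(data).all(axis=-1)
    norms = np.linalg.norm(data, axis=-1)
    nz = mask & (norms > 1e-12)
    vec = np.zeros_like(data)
    vec[nz] = data[nz] / norms[nz][..., None]
    return OrientationField(grid=grid, vectors=vec, mask=nz)


def write_strain_map(strain_map, path):
    write_volume(strain_map.strain, strain_map.grid.affine(), path)


# ---------------------------------------------------------------------------
# manifests

def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: dict, seed: Optional[int] = None,
                   extras: Optional[dict] = None):
    """Provenance sidecar: version, config echo + hash, seed, extras."""
    from . import __version__
    payload = {
        "tool": "refold",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
    }
    if extras:
        payload.update(extras)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
    return payload


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    return str(o)
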