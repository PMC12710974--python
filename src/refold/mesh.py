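"""Tetrahedral mesh data model and labeling utilities.

A :class:`TetMesh` is the central container of the package: node positions in
millimetres, tetrahedra as 4-tuples of node indices (positively oriented),
the boundary triangle soup (outward-oriented), and per-node tissue labels
distinguishing the gray-matter shell from the white-matter core.  Optional
per-node parcellation labels and lumped masses are attached by the
operations below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

#: tissue label values
WHITE = 0
GRAY = 1

#: parcel label reserved for interior (non-surface) nodes
INTERIOR_PARCEL = -1


class MeshError(ValueError):
    """Raised for geometrically invalid meshes or mesh specs."""


@dataclass
class TetMesh:
    """Two-tissue tetrahedral mesh.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array, positively oriented
    tissue : (N,) int array of {WHITE, GRAY}
    surface_faces : (F, 3) int array, outward-oriented boundary triangles
    face_region : (F,) int array; 1 marks the "outer" (cortical) surface that
        carries area/smoothing constraints and enters the gyrification index,
        0 marks passive boundary (slab sides and base)
    parcel : optional (N,) int array of parcellation labels
    node_mass : optional (N,) float array, kg
    meta : free-form provenance dictionary (generator spec, envelope rule...)
    """

    nodes: np.ndarray
    tets: np.ndarray
    tissue: np.ndarray
    surface_faces: np.ndarray
    face_region: np.ndarray
    parcel: Optional[np.ndarray] = None
    node_mass: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    # -- derived geometry ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    def tet_volumes(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        """Signed volumes of all tetrahedra (mm^3); positive when well oriented."""
        return tet_volumes(positions if positions is not None else self.nodes, self.tets)

    def total_volume(self, positions: Optional[np.ndarray] = None) -> float:
        return float(self.tet_volumes(positions).sum())

    def face_areas(self, positions: Optional[np.ndarray] = None,
                   region: Optional[int] = None) -> np.ndarray:
        """Areas (mm^2) of surface faces, optionally restricted to a region."""
        pos = self.nodes if positions is None else positions
        faces = self.surface_faces
        if region is not None:
            faces = faces[self.face_region == region]
        return triangle_areas(pos, faces)

    def outer_surface_area(self, positions: Optional[np.ndarray] = None) -> float:
        return float(self.face_areas(positions, region=1).sum())

    def copy(self) -> "TetMesh":
        return replace(
            self,
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            tissue=self.tissue.copy(),
            surface_faces=self.surface_faces.copy(),
            face_region=self.face_region.copy(),
            parcel=None if self.parcel is None else self.parcel.copy(),
            node_mass=None if self.node_mass is None else self.node_mass.copy(),
            meta=dict(self.meta),
        )

    def surface_nodes(self) -> np.ndarray:
        """Sorted unique node indices on the boundary."""
        return np.unique(self.surface_faces)


@dataclass
class Atlas:
    """Labeled point cloud used to transfer parcellation labels to a mesh."""

    vertices: np.ndarray  # (K, 3) mm
    labels: np.ndarray    # (K,) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vertices.shape[0] != self.labels.shape[0]:
            raise MeshError("atlas vertices and labels differ in length")


# ---------------------------------------------------------------------------
# low-level geometry helpers

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def triangle_areas(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (nodes[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def extract_surface(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Boundary faces of a tet mesh, each outward-oriented.

    A boundary face appears in exactly one tetrahedron; it is oriented so its
    normal points away from the tet's opposite vertex.
    """
    # local faces with outward orientation for a positively oriented tet
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    return np.ascontiguousarray(boundary)


def surface_edge_adjacency(surface_faces: np.ndarray) -> list[np.ndarray]:
    """Per-surface-node arrays of edge-neighbouring surface nodes."""
    edges = np.concatenate(
        [surface_faces[:, [0, 1]], surface_faces[:, [1, 2]], surface_faces[:, [2, 0]]]
    )
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    nodes = np.unique(surface_faces)
    nbrs: dict[int, list[int]] = {int(n): [] for n in nodes}
    for u, v in edges:
        nbrs[int(u)].append(int(v))
        nbrs[int(v)].append(int(u))
    return {n: np.array(sorted(v), dtype=int) for n, v in nbrs.items()}


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    n_nodes: int
    n_tets: int
    min_tet_volume: float
    inverted_tets: int
    nonmanifold_surface_edges: int
    isolated_nodes: int
    messages: list

    @property
    def ok(self) -> bool:
        return (
            self.n_tets > 0
            and self.inverted_tets == 0
            and self.nonmanifold_surface_edges == 0
            and self.isolated_nodes == 0
        )


def validate_mesh(mesh: TetMesh) -> ValidationReport:
    """Report-only structural validation (never raises)."""
    messages = []
    if mesh.n_tets == 0:
        return ValidationReport(mesh.n_nodes, 0, np.nan, 0, 0, mesh.n_nodes,
                                ["no tetrahedra"])
    vols = mesh.tet_volumes()
    inverted = int((vols <= 0).sum())
    if inverted:
        messages.append(f"{inverted} inverted tetrahedra")

    edges = np.concatenate([mesh.surface_faces[:, [0, 1]],
                            mesh.surface_faces[:, [1, 2]],
                            mesh.surface_faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    nonmanifold = int((counts != 2).sum())
    if nonmanifold:
        messages.append(f"{nonmanifold} non-manifold surface edges")

    used = np.zeros(mesh.n_nodes, dtype=bool)
    used[mesh.tets.ravel()] = True
    isolated = int((~used).sum())
    if isolated:
        messages.append(f"{isolated} isolated nodes")

    if mesh.tissue.shape[0] != mesh.n_nodes:
        messages.append("tissue labels missing for some nodes")

    return ValidationReport(mesh.n_nodes, mesh.n_tets, float(vols.min()),
                            inverted, nonmanifold, isolated, messages)


# ---------------------------------------------------------------------------
# parcellation

def assign_parcellation(mesh: TetMesh, atlas: Atlas) -> TetMesh:
    """Nearest-atlas-vertex label transfer onto surface nodes.

    Interior nodes receive the reserved ``INTERIOR_PARCEL`` sentinel, which
    is excluded from majority voting.
    """
    if atlas.vertices.shape[0] == 0:
        raise MeshError("empty atlas")
    out = mesh.copy()
    parcel = np.full(mesh.n_nodes, INTERIOR_PARCEL, dtype=int)
    surf = mesh.surface_nodes()
    tree = cKDTree(atlas.vertices)
    _, idx = tree.query(mesh.nodes[surf])
    parcel[surf] = atlas.labels[idx]
    out.parcel = parcel
    return out


def majority_vote_relabel(mesh: TetMesh, max_iters: int = 10) -> TetMesh:
    """Iterative synchronous majority voting over surface-edge neighbourhoods.

    Each surface node adopts the most frequent label among itself and its
    surface-edge neighbours; ties keep the current label.  Updates are
    synchronous (computed from the previous iteration), which makes the
    result independent of node ordering.  Stops at a fixed point or after
    ``max_iters``; convergence status lands in ``mesh.meta``.
    """
    if mesh.parcel is None:
        raise MeshError("surface labels not assigned; run assign_parcellation first")
    out = mesh.copy()
    nbrs = surface_edge_adjacency(mesh.surface_faces)
    surf = list(nbrs.keys())
    labels = out.parcel
    converged = False
    for _ in range(max_iters):
        new = labels.copy()
        for n in surf:
            votes: dict[int, int] = {}
            cur = labels[n]
            votes[cur] = 1
            for m in nbrs[n]:
                lab = labels[m]
                if lab == INTERIOR_PARCEL:
                    continue
                votes[lab] = votes.get(lab, 0) + 1
            best, best_count = cur, votes.get(cur, 0)
            for lab, cnt in votes.items():
                if cnt > best_count:  # strict: ties keep current label
                    best, best_count = lab, cnt
            new[n] = best
        if np.array_equal(new, labels):
            converged = True
            break
        labels = new
    out.parcel = labels
    out.meta["relabel_converged"] = converged
    return out


# ---------------------------------------------------------------------------
# masses and gyrification

def compute_node_masses(mesh: TetMesh, density: float = 1040.0) -> TetMesh:
    """Lump tissue mass onto nodes: each tet's mass split equally 4 ways.

    ``density`` is in kg/m^3 (brain tissue ~1040); volumes are mm^3, so node
    masses come out in kg.  Total mass is conserved exactly up to float
    summation order.
    """
    if density <= 0:
        raise MeshError("density must be positive")
    out = mesh.copy()
    vols = mesh.tet_volumes()  # mm^3
    tet_mass = density * vols * 1e-9  # kg
    mass = np.zeros(mesh.n_nodes)
    np.add.at(mass, mesh.tets.ravel(), np.repeat(tet_mass / 4.0, 4))
    out.node_mass = mass
    return out


def gyrification_index(mesh: TetMesh, positions: Optional[np.ndarray] = None,
                       envelope: str = "auto") -> float:
    """Outer-surface area over the area of a smooth reference envelope.

    ``envelope='projection'`` (slabs): the outer surface's flat projection
    onto the base plane, computed as the summed |z-component| of the face
    area vectors — robust to lateral contraction during simulation.
    ``envelope='hull'`` (closed surfaces): convex-hull surface area.
    ``'auto'`` consults ``mesh.meta['envelope']`` and falls back to 'hull'
    for closed surfaces, erroring otherwise.
    """
    pos = mesh.nodes if positions is None else positions
    if envelope == "auto":
        envelope = mesh.meta.get("envelope", "")
        if envelope not in ("projection", "hull"):
            envelope = "hull" if _surface_is_closed(mesh) else ""
        if not envelope:
            raise MeshError("open non-slab surface: no definable GI envelope")
    faces = mesh.surface_faces[mesh.face_region == 1]
    a, b, c = (pos[faces[:, i]] for i in range(3))
    area_vec = 0.5 * np.cross(b - a, c - a)
    total = float(np.linalg.norm(area_vec, axis=1).sum())
    if envelope == "projection":
        ref = float(np.abs(area_vec[:, 2]).sum())
    elif envelope == "hull":
        hull = ConvexHull(pos[mesh.surface_nodes()])
        ref = float(hull.area)
    else:
        raise MeshError(f"unknown envelope rule {envelope!r}")
    if ref <= 0:
        raise MeshError("degenerate envelope")
    return total / ref


def isoperimetric_excess(mesh: TetMesh,
                         positions: Optional[np.ndarray] = None) -> float:
    """(surface area)^3 / (volume)^2 relative to the sphere's 36*pi, minus 1.

    Zero for a perfect sphere; positive for any other closed shape
    (isoperimetric inequality).
    """
    pos = mesh.nodes if positions is None else positions
    area = float(triangle_areas(pos, mesh.surface_faces).sum())
    vol = float(tet_volumes(pos, mesh.tets).sum())
    return area ** 3 / vol ** 2 / (36.0 * np.pi) - 1.0


def _surface_is_closed(mesh: TetMesh) -> bool:
    edges = np.concatenate([mesh.surface_faces[:, [0, 1]],
                            mesh.surface_faces[:, [1, 2]],
                            mesh.surface_faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all()) and np.all(mesh.face_region == 1)
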