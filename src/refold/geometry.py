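"""Synthetic two-tissue geometries with known folding structure.

Everything downstream of the solver is validated on bodies generated here:
a sinusoidally folded slab standing in for a folded cortical patch (gray
shell over white core), a 1 mm^3 white-matter cube used for material
calibration, and a lobed ("wavy") sphere for the isoperimetric sanity check.
Folds are 2.5-D — sinusoidal in x, extruded in y — so the ground-truth
radial orientation field of the folded configuration is known analytically.

All generators build a structured hexahedral lattice and split each cell
into 6 tetrahedra (Kuhn triangulation), which is conforming across cells
without checkerboard parity and yields bit-reproducible connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Callable

import numpy as np

from .mesh import GRAY, WHITE, MeshError, TetMesh, extract_surface, tet_volumes


@dataclass(frozen=True)
class SlabSpec:
    """Folded-slab geometry: top surface z = depth + A sin(2*pi*x / W).

    All lengths in mm.  ``gm_thickness`` is the gray shell measured inward
    from the top surface; ``h`` the target lattice spacing.
    """

    extent_x: float = 12.0
    extent_y: float = 3.0
    depth: float = 3.0
    fold_amplitude: float = 1.0
    fold_wavelength: float = 4.0
    gm_thickness: float = 0.75
    h: float = 0.35

    def __post_init__(self):
        if self.fold_amplitude < 0:
            raise MeshError("fold amplitude must be >= 0")
        if self.fold_wavelength <= 0:
            raise MeshError("fold wavelength must be > 0")
        if not (0 < self.gm_thickness < self.depth):
            raise MeshError("gm_thickness must lie in (0, depth)")
        if self.h <= 0 or self.h >= self.gm_thickness + 1e-12:
            raise MeshError("element size h must satisfy 0 < h < gm_thickness")
        if self.fold_amplitude >= self.depth:
            raise MeshError("degenerate spec: fold amplitude >= depth")

    def top_height(self, x):
        """Height of the folded top surface above z=0."""
        return self.depth + self.fold_amplitude * np.sin(
            2.0 * np.pi * np.asarray(x) / self.fold_wavelength)

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in (
            "extent_x", "extent_y", "depth", "fold_amplitude",
            "fold_wavelength", "gm_thickness", "h")}

    @classmethod
    def from_json(cls, d: dict) -> "SlabSpec":
        return cls(**d)


@dataclass
class AnalyticField:
    """Closed-form unit orientation field on an axis-aligned box domain."""

    direction: Callable[[np.ndarray], np.ndarray]  # (K,3) -> (K,3) unit
    domain_lo: np.ndarray
    domain_hi: np.ndarray

    def __call__(self, points: np.ndarray) -> np.ndarray:
        d = self.direction(np.atleast_2d(np.asarray(points, dtype=float)))
        return d / np.linalg.norm(d, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Kuhn lattice machinery

_KUHN_PATHS = []
for perm in sorted(permutations(range(3))):
    p0 = np.zeros(3, dtype=int)
    p1 = p0.copy(); p1[perm[0]] = 1
    p2 = p1.copy(); p2[perm[1]] = 1
    p3 = np.ones(3, dtype=int)
    _KUHN_PATHS.append(np.array([p0, p1, p2, p3]))


def _kuhn_cell_tets(corner_ids: np.ndarray) -> np.ndarray:
    """6 tets for one hex cell; corner_ids indexed by (i,j,k) offsets."""
    tets = []
    for path in _KUHN_PATHS:
        tets.append([corner_ids[tuple(p)] for p in path])
    return np.array(tets, dtype=np.int64)


def _lattice_tets(nx: int, ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Node index grid and Kuhn tets of an (nx,ny,nz)-cell lattice."""
    ids = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    cells = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = ids[i:i + 2, j:j + 2, k:k + 2]
                cells.append(_kuhn_cell_tets(corner))
    return ids, np.concatenate(cells)


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of any negatively oriented tet."""
    vols = tet_volumes(nodes, tets)
    bad = vols < 0
    if bad.any():
        tets = tets.copy()
        tets[bad] = tets[bad][:, [0, 2, 1, 3]]
    vols = tet_volumes(nodes, tets)
    if (vols <= 0).any():
        raise MeshError("degenerate tetrahedra after orientation fix")
    return tets


def _grid_counts(length: float, h: float) -> int:
    return max(1, int(round(length / h)))


# ---------------------------------------------------------------------------
# generators

def make_folded_slab(spec: SlabSpec) -> TetMesh:
    """Two-tissue folded slab: gray shell over white core, pinned-base ready.

    The lattice is sheared in z so columns follow the local top height:
    node z = zeta * top_height(x) for zeta in [0, 1].  Deterministic —
    identical specs produce bit-identical arrays.
    """
    nx = _grid_counts(spec.extent_x, spec.h)
    ny = _grid_counts(spec.extent_y, spec.h)
    nz = _grid_counts(spec.depth, spec.h)
    ids, tets = _lattice_tets(nx, ny, nz)

    xs = np.linspace(0.0, spec.extent_x, nx + 1)
    ys = np.linspace(0.0, spec.extent_y, ny + 1)
    zetas = np.linspace(0.0, 1.0, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zetas, indexing="ij")
    top = spec.top_height(X)
    nodes = np.stack([X, Y, Z * top], axis=-1).reshape(-1, 3)

    tets = _fix_orientation(nodes, tets)
    surface = extract_surface(nodes, tets)

    # tissue: within gm_thickness (measured vertically) of the local top
    local_top = spec.top_height(nodes[:, 0])
    tissue = np.where(nodes[:, 2] > local_top - spec.gm_thickness, GRAY, WHITE
                      ).astype(np.uint8)

    # face regions: 1 = folded top surface, 0 = sides and base
    centroids = nodes[surface].mean(axis=1)
    a, b, c = (nodes[surface[:, i]] for i in range(3))
    nrm = np.cross(b - a, c - a)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    on_top = (nrm[:, 2] > 0.3) & (
        centroids[:, 2] > 0.5 * spec.top_height(centroids[:, 0]))
    face_region = on_top.astype(np.uint8)

    mesh = TetMesh(nodes=nodes, tets=tets, tissue=tissue,
                   surface_faces=surface, face_region=face_region,
                   meta={"kind": "slab", "envelope": "projection",
                         "spec": spec.to_json(),
                         "lattice": (nx, ny, nz),
                         "tet_split": "kuhn6"})
    return mesh


def slab_base_nodes(mesh: TetMesh, tol: float = 1e-9) -> np.ndarray:
    """Indices of the z=0 base nodes (the natural pin set for slab runs)."""
    return np.flatnonzero(mesh.nodes[:, 2] < tol)


def make_unit_cube(edge: float = 1.0, h: float = 0.2) -> TetMesh:
    """All-white cube of the given edge length; volume is exactly edge^3."""
    if h >= edge:
        raise MeshError("element size h must be < edge")
    n = _grid_counts(edge, h)
    ids, tets = _lattice_tets(n, n, n)
    axis = np.linspace(0.0, edge, n + 1)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    tets = _fix_orientation(nodes, tets)
    surface = extract_surface(nodes, tets)
    mesh = TetMesh(nodes=nodes, tets=tets,
                   tissue=np.full(nodes.shape[0], WHITE, dtype=np.uint8),
                   surface_faces=surface,
                   face_region=np.ones(surface.shape[0], dtype=np.uint8),
                   meta={"kind": "cube", "envelope": "hull", "edge": edge,
                         "tet_split": "kuhn6"})
    return mesh


def _lobe_function(n_lobes: int):
    """Smooth equatorial lobe pattern; identically zero for n_lobes == 0.

    f(dir) = cos(n_lobes * azimuth) * (1 - z^2) on the unit sphere — a
    low-order sectoral-harmonic-like perturbation, smooth at the poles.
    """
    def f(dirs: np.ndarray) -> np.ndarray:
        if n_lobes == 0:
            return np.zeros(dirs.shape[0])
        az = np.arctan2(dirs[:, 1], dirs[:, 0])
        return np.cos(n_lobes * az) * (1.0 - dirs[:, 2] ** 2)
    return f


def make_wavy_sphere(radius: float = 5.0, n_lobes: int = 4,
                     amplitude: float = 0.0, h: float = 1.0,
                     gray_fraction: float = 0.2) -> TetMesh:
    """Ball with a lobed radial perturbation of the boundary.

    Built from a cube lattice mapped radially onto the ball (max-norm shells
    to Euclidean shells), then perturbed: r -> rho * (R + amp * f(dir) *
    rho^2), where rho in [0,1] is the normalized shell radius, so the center
    is untouched and the perturbation is smooth.  amplitude=0 (or
    n_lobes=0) gives a plain sphere up to meshing tolerance.
    """
    if amplitude >= radius:
        raise MeshError("amplitude must be < radius")
    n = max(2, _grid_counts(2 * radius, h))
    ids, tets = _lattice_tets(n, n, n)
    axis = np.linspace(-1.0, 1.0, n + 1)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    cube = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    rho = np.max(np.abs(cube), axis=1)  # max-norm shell in [0,1]
    norm = np.linalg.norm(cube, axis=1)
    dirs = np.zeros_like(cube)
    nz = norm > 0
    dirs[nz] = cube[nz] / norm[nz, None]

    f = _lobe_function(n_lobes)(dirs)
    r = rho * (radius + amplitude * f * rho ** 2)
    nodes = dirs * r[:, None]

    tets = _fix_orientation(nodes, tets)
    surface = extract_surface(nodes, tets)
    tissue = np.where(rho > 1.0 - gray_fraction, GRAY, WHITE).astype(np.uint8)
    mesh = TetMesh(nodes=nodes, tets=tets, tissue=tissue,
                   surface_faces=surface,
                   face_region=np.ones(surface.shape[0], dtype=np.uint8),
                   meta={"kind": "wavy_sphere", "envelope": "hull",
                         "radius": radius, "n_lobes": n_lobes,
                         "amplitude": amplitude,
                         "perturbation": "cos(n*az)*(1-z^2), rho^2 radial ramp",
                         "tet_split": "kuhn6"})
    return mesh


# ---------------------------------------------------------------------------
# analytic ground truth for the folded slab

def analytic_slab_orientation(spec: SlabSpec, n_samples: int = 4096) -> AnalyticField:
    """Inward-normal field of the folded top surface, propagated straight.

    For a query point p, the direction is the inward unit normal n(x*) of
    the surface point x* whose straight inward normal ray passes through p.
    Where several rays cross (below gyral crests, past the focal distance
    1/(A k^2) the flank normal lines converge under the crest), the branch
    belonging to the laterally nearest surface point is taken — each
    surface point keeps its own material column, matching a radial scaffold
    advected with the (volume-preserving) fold rather than straight lines
    shot through the folded geometry.
    """
    k = 2.0 * np.pi / spec.fold_wavelength
    # dense sampling of the surface curve over x (y-invariant geometry)
    xs = np.linspace(0.0, spec.extent_x, n_samples)
    zs = spec.top_height(xs)
    slope = spec.fold_amplitude * k * np.cos(k * xs)
    # inward (downward) unit normals at the samples, in the x-z plane
    nrm2 = np.stack([slope, -np.ones_like(xs)], axis=1)
    nrm2 /= np.linalg.norm(nrm2, axis=1, keepdims=True)
    curve = np.stack([xs, zs], axis=1)
    # ray-hit tolerance: a few sample spacings of the surface curve
    ds = float(np.hypot(np.diff(xs).max(), np.abs(np.diff(zs)).max()))
    tol = 3.0 * ds

    def direction(p: np.ndarray) -> np.ndarray:
        q = np.stack([p[:, 0], p[:, 2]], axis=1)
        # deduplicate x-z queries (grids repeat them along y)
        uq, inv = np.unique(q.round(9), axis=0, return_inverse=True)
        rel = uq[:, None, :] - curve[None, :, :]          # (Q, S, 2)
        d = np.einsum("qsj,sj->qs", rel, nrm2)           # ray parameter
        perp = rel - d[..., None] * nrm2[None, :, :]
        miss = np.linalg.norm(perp, axis=2)
        # among samples whose ray passes within tol, pick the laterally
        # nearest surface point (own-column branch)
        lateral = np.abs(uq[:, None, 0] - curve[None, :, 0])
        score = np.where((miss < tol) & (d >= -tol), lateral, np.inf)
        best = np.argmin(score, axis=1)
        none = ~np.isfinite(score[np.arange(len(uq)), best])
        if none.any():  # fall back to the nearest surface sample
            near = np.argmin(np.linalg.norm(rel[none], axis=2), axis=1)
            best[none] = near
        n2 = nrm2[best][inv]
        return np.stack([n2[:, 0], np.zeros(len(q)), n2[:, 1]], axis=1)

    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([spec.extent_x, spec.extent_y,
                   spec.depth + spec.fold_amplitude])
    return AnalyticField(direction=direction, domain_lo=lo, domain_hi=hi)


def slab_phase(spec: SlabSpec, x: np.ndarray) -> np.ndarray:
    """sin(2*pi*x/W): +1 at gyral crests, -1 at sulcal fundi."""
    return np.sin(2.0 * np.pi * np.asarray(x) / spec.fold_wavelength)


def slab_phase_labels(spec: SlabSpec, points: np.ndarray,
                      threshold: float = 0.5) -> np.ndarray:
    """Classify points by fold phase: 1=crown, 0=bank, -1=sulcal fundus."""
    s = slab_phase(spec, np.asarray(points)[:, 0])
    out = np.zeros(s.shape, dtype=int)
    out[s > threshold] = 1
    out[s < -threshold] = -1
    return out
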