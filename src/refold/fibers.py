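"""Fiber synthesis and advection: the radial scaffold and Bezier bundles.

The radial fiber model emulates the fetal white-matter scaffold: straight
fibers leave the (unfolded) cortical surface along local inward normals.
The direction field is built by voxelizing the surface normals, diffusing
them into the volume with 6-neighbourhood vector averaging, and
renormalizing.  Fibers are advected through a :class:`DeformationMap` to
any normalized time, bending and stretching with the local deformation.
Coherent long-range bundles are synthesized as randomized quadratic Bezier
curves between two endpoint sets, then deformed the same way.

Per-voxel primary peaks come from the orientation tensor sum(d d^T) of the
fiber segments crossing each voxel — the principal eigenvector, which is
invariant to segment sign flips (axial data convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional

import numpy as np

from .deformation import DeformationMap
from .grid import VoxelGrid
from .mesh import TetMesh, triangle_areas


@dataclass
class FiberSet:
    """Ordered polylines (mm) with stable per-fiber ids."""

    fibers: List[np.ndarray]
    ids: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fibers = [np.asarray(f, dtype=float) for f in self.fibers]
        for f in self.fibers:
            if f.ndim != 2 or f.shape[0] < 2 or f.shape[1] != 3:
                raise ValueError("each fiber needs >= 2 3-D points")
        if self.ids is None:
            self.ids = np.arange(len(self.fibers))

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.fibers)

    def __getitem__(self, i) -> np.ndarray:
        return self.fibers[i]

    def lengths(self) -> np.ndarray:
        return np.array([np.linalg.norm(np.diff(f, axis=0), axis=1).sum()
                         for f in self.fibers])

    def subset(self, ids) -> "FiberSet":
        """Fibers whose id is in ``ids``, in this set's order (for pairing
        with a set that dropped fibers during advection)."""
        want = set(int(i) for i in np.asarray(ids).ravel())
        keep = [i for i, fid in enumerate(self.ids) if int(fid) in want]
        return FiberSet(fibers=[self.fibers[i] for i in keep],
                        ids=np.asarray(self.ids)[keep],
                        meta=dict(self.meta))


@dataclass
class OrientationField:
    """Unit 3-vector per voxel, with an emptiness mask."""

    grid: VoxelGrid
    vectors: np.ndarray   # (nx,ny,nz,3)
    mask: np.ndarray      # (nx,ny,nz) bool, True where defined

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors[self.mask], axis=-1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("non-unit vectors in orientation field")

    def at_voxel(self, idx: np.ndarray):
        """Vectors at integer voxel indices; NaN rows where empty/outside."""
        idx = np.atleast_2d(idx)
        out = np.full((len(idx), 3), np.nan)
        ok = self.grid.inside(idx)
        ii = idx[ok]
        defined = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        sel = np.where(ok)[0][defined]
        out[sel] = self.vectors[ii[defined, 0], ii[defined, 1], ii[defined, 2]]
        return out

    def at_points(self, points: np.ndarray):
        return self.at_voxel(self.grid.voxel_of(points))


@dataclass(frozen=True)
class BundleSpec:
    """Randomized-Bezier bundle between two endpoint sets (unfolded space)."""

    endpoints_a: np.ndarray
    endpoints_b: np.ndarray
    n_fibers: int = 100
    midpoint_sigma: float = 1.0   # mm, Gaussian jitter of the control point
    seed: int = 0
    n_points: int = 32            # vertices sampled per curve

    def __post_init__(self):
        a = np.atleast_2d(np.asarray(self.endpoints_a, dtype=float))
        b = np.atleast_2d(np.asarray(self.endpoints_b, dtype=float))
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both endpoint sets must be non-empty")
        if self.midpoint_sigma < 0:
            raise ValueError("midpoint sigma must be >= 0")
        object.__setattr__(self, "endpoints_a", a)
        object.__setattr__(self, "endpoints_b", b)


# ---------------------------------------------------------------------------
# inward-normal field

def inward_normal_field(mesh: TetMesh, voxel_size: float = 0.325,
                        smooth_iters: int = 10, pad: float = 1.0,
                        positions: Optional[np.ndarray] = None) -> OrientationField:
    """Voxelized inward surface normals, diffused into the volume.

    Outer-surface faces are densely sampled; each sample splats the face's
    inward (surface-to-interior) normal into its voxel.  Each smoothing
    pass then averages vectors over the 6-neighbourhood *and* extends the
    field into empty voxels that touch a defined one, so with enough passes
    the field fills the interior; vectors are renormalized to unit length.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pos = mesh.nodes if positions is None else positions
    faces = mesh.surface_faces[mesh.face_region == 1]
    if not len(faces):
        raise ValueError("mesh has no outer surface faces")
    grid = VoxelGrid.from_bounds(pos.min(axis=0), pos.max(axis=0),
                                 voxel_size, pad=pad)

    a, b, c = (pos[faces[:, i]] for i in range(3))
    nrm = np.cross(b - a, c - a)
    nn = np.linalg.norm(nrm, axis=1, keepdims=True)
    ok = nn[:, 0] > 1e-12
    inward = np.zeros_like(nrm)
    inward[ok] = -nrm[ok] / nn[ok]   # faces are outward-oriented

    # dense barycentric sampling proportional to face size
    acc = np.zeros(grid.shape + (3,))
    per_face = max(2, int(np.ceil(np.sqrt(triangle_areas(pos, faces).max())
                                  / (0.5 * voxel_size))) + 1)
    us = []
    for i in range(per_face + 1):
        for j in range(per_face + 1 - i):
            us.append((i / per_face, j / per_face))
    us = np.array(us)
    w = np.stack([1.0 - us[:, 0] - us[:, 1], us[:, 0], us[:, 1]], axis=1)
    for s in range(len(w)):
        pts = w[s, 0] * a + w[s, 1] * b + w[s, 2] * c
        idx = grid.voxel_of(pts)
        keep = grid.inside(idx) & ok
        np.add.at(acc, (idx[keep, 0], idx[keep, 1], idx[keep, 2]), inward[keep])

    mask = np.linalg.norm(acc, axis=-1) > 1e-12
    for _ in range(max(0, smooth_iters)):
        acc, mask = _smooth_extend(acc, mask)

    vec = np.zeros_like(acc)
    norms = np.linalg.norm(acc, axis=-1)
    nz = mask & (norms > 1e-12)
    vec[nz] = acc[nz] / norms[nz][..., None]
    return OrientationField(grid=grid, vectors=vec, mask=nz)


def _smooth_extend(acc: np.ndarray, mask: np.ndarray):
    """One pass of 6-neighbour vector averaging with frontier growth."""
    summed = np.zeros_like(acc)
    counts = np.zeros(mask.shape)
    m = mask.astype(float)
    summed += acc * m[..., None]
    counts += m
    for axis in range(3):
        for shift in (1, -1):
            summed += np.roll(acc * m[..., None], shift, axis=axis)
            counts += np.roll(m, shift, axis=axis)
            # zero out wrap-around
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            summed[tuple(sl)] -= np.roll(acc * m[..., None], shift, axis=axis)[tuple(sl)]
            counts[tuple(sl)] -= np.roll(m, shift, axis=axis)[tuple(sl)]
    new_mask = counts > 0
    out = np.zeros_like(acc)
    out[new_mask] = summed[new_mask] / counts[new_mask][..., None]
    return out, new_mask


# ---------------------------------------------------------------------------
# radial fibers

def generate_radial_fibers(mesh: TetMesh, flow: OrientationField,
                           step: float = 0.2, max_len: float = 2.5,
                           n_seeds: int = 1000, seed: int = 0,
                           positions: Optional[np.ndarray] = None) -> FiberSet:
    """Seed the outer surface uniformly by area and advect inward.

    Each fiber starts at a surface sample nudged half a step inward along
    the face normal, then integrates through the (smoothed) direction field
    with fixed step length, terminating at ``max_len``, on leaving the
    grid, or on entering an empty voxel.  Fully deterministic for a given
    seed.  Seeds landing in empty voxels are skipped and counted in
    ``meta['skipped']``.
    """
    if not flow.mask.any():
        raise ValueError("empty orientation field")
    pos = mesh.nodes if positions is None else positions
    faces = mesh.surface_faces[mesh.face_region == 1]
    areas = triangle_areas(pos, faces)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(faces), size=n_seeds, p=areas / areas.sum())
    r1 = rng.random(n_seeds)
    r2 = rng.random(n_seeds)
    s1 = np.sqrt(r1)
    wa, wb, wc = 1.0 - s1, s1 * (1.0 - r2), s1 * r2
    a, b, c = (pos[faces[pick, i]] for i in range(3))
    seeds = wa[:, None] * a + wb[:, None] * b + wc[:, None] * c
    nrm = np.cross(b - a, c - a)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    seeds = seeds - 0.5 * step * nrm   # nudge inward off the surface

    n_steps = int(np.ceil(max_len / step))
    fibers, ids = [], []
    skipped = 0
    for i in range(n_seeds):
        p = seeds[i]
        d = flow.at_points(p[None, :])[0]
        if np.isnan(d).any():
            skipped += 1
            continue
        pts = [p]
        for _ in range(n_steps):
            d = flow.at_points(pts[-1][None, :])[0]
            if np.isnan(d).any():
                break
            pts.append(pts[-1] + step * d)
        if len(pts) >= 2:
            fibers.append(np.array(pts))
            ids.append(i)
        else:
            skipped += 1
    return FiberSet(fibers=fibers, ids=np.array(ids, dtype=int),
                    meta={"skipped": skipped, "seed": seed, "step": step,
                          "max_len": max_len, "seed_points": seeds})


def advect_fibers(dmap: DeformationMap, fibers: FiberSet, t: float,
                  drop_unlocatable: bool = False) -> FiberSet:
    """Map every polyline vertex through Phi_t; ids are preserved.

    Vertices outside the reference domain raise, or — with
    ``drop_unlocatable`` — their whole fiber is dropped and counted.
    """
    counts = [len(f) for f in fibers]
    allpts = np.concatenate(list(fibers.fibers))
    mapped = dmap.map_points(allpts, t,
                             on_outside="nan" if drop_unlocatable else "raise")
    out, ids, dropped = [], [], 0
    ofs = 0
    for fid, n in zip(fibers.ids, counts):
        chunk = mapped[ofs:ofs + n]
        ofs += n
        if np.isnan(chunk).any():
            dropped += 1
            continue
        out.append(chunk)
        ids.append(fid)
    return FiberSet(fibers=out, ids=np.array(ids, dtype=int),
                    meta=dict(fibers.meta, t=t, dropped=dropped))


# ---------------------------------------------------------------------------
# Bezier bundles

def bezier_bundle(spec: BundleSpec) -> FiberSet:
    """Randomized quadratic Bezier fibers between two endpoint sets.

    Endpoints are drawn uniformly (with the spec's seed) from each set;
    the control point is the endpoint midpoint plus isotropic Gaussian
    jitter.  Curves interpolate both endpoints exactly; with zero jitter
    the curve degenerates to the straight segment.
    """
    rng = np.random.default_rng(spec.seed)
    ia = rng.integers(0, len(spec.endpoints_a), size=spec.n_fibers)
    ib = rng.integers(0, len(spec.endpoints_b), size=spec.n_fibers)
    p0 = spec.endpoints_a[ia]
    p1 = spec.endpoints_b[ib]
    ctrl = 0.5 * (p0 + p1) + rng.normal(scale=spec.midpoint_sigma,
                                        size=(spec.n_fibers, 3))
    u = np.linspace(0.0, 1.0, spec.n_points)[None, :, None]
    curves = ((1 - u) ** 2 * p0[:, None, :] + 2 * u * (1 - u) * ctrl[:, None, :]
              + u ** 2 * p1[:, None, :])
    return FiberSet(fibers=list(curves),
                    meta={"seed": spec.seed, "sigma": spec.midpoint_sigma})


# ---------------------------------------------------------------------------
# primary peaks

def extract_primary_peaks(fibers: FiberSet, grid: VoxelGrid,
                          tie_tol: float = 1e-6) -> OrientationField:
    """Principal eigenvector of the per-voxel segment orientation tensor.

    Segments are subdivided to half-voxel pieces; each piece adds
    length * d d^T at its midpoint's voxel.  Voxels whose top two
    eigenvalues tie within ``tie_tol`` (relative) are flagged ambiguous and
    left empty; their count lands in the returned field's metadata... the
    mask excludes them.
    """
    if len(fibers) == 0:
        raise ValueError("empty fiber set")
    tensors = np.zeros(grid.shape + (6,))  # xx, yy, zz, xy, xz, yz
    half = 0.5 * grid.spacing
    for f in fibers:
        seg = np.diff(f, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        keep = lens > 1e-12
        seg, lens, base = seg[keep], lens[keep], f[:-1][keep]
        d = seg / lens[:, None]
        for i in range(len(seg)):
            n = max(1, int(np.ceil(lens[i] / half)))
            mids = base[i] + ((np.arange(n) + 0.5) / n)[:, None] * seg[i]
            idx = grid.voxel_of(mids)
            ok = grid.inside(idx)
            if not ok.any():
                continue
            idx = idx[ok]
            w = lens[i] / n
            dx, dy, dz = d[i]
            contrib = w * np.array([dx * dx, dy * dy, dz * dz,
                                    dx * dy, dx * dz, dy * dz])
            np.add.at(tensors, (idx[:, 0], idx[:, 1], idx[:, 2]), contrib)

    occupied = tensors[..., :3].sum(axis=-1) > 1e-12
    vec = np.zeros(grid.shape + (3,))
    mask = np.zeros(grid.shape, dtype=bool)
    ii = np.argwhere(occupied)
    if len(ii):
        t = tensors[occupied]
        M = np.zeros((len(t), 3, 3))
        M[:, 0, 0] = t[:, 0]; M[:, 1, 1] = t[:, 1]; M[:, 2, 2] = t[:, 2]
        M[:, 0, 1] = M[:, 1, 0] = t[:, 3]
        M[:, 0, 2] = M[:, 2, 0] = t[:, 4]
        M[:, 1, 2] = M[:, 2, 1] = t[:, 5]
        evals, evecs = np.linalg.eigh(M)
        leading = evecs[:, :, 2]
        scale = np.maximum(np.abs(evals[:, 2]), 1e-300)
        unambiguous = (evals[:, 2] - evals[:, 1]) > tie_tol * scale
        sel = ii[unambiguous]
        vec[sel[:, 0], sel[:, 1], sel[:, 2]] = leading[unambiguous]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    field = OrientationField(grid=grid, vectors=vec, mask=mask)
    field.n_ambiguous = int(occupied.sum() - mask.sum())
    return field
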