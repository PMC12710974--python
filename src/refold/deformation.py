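"""Volumetric deformation map between unfolded and folded configurations.

A simulation run yields a :class:`Trajectory` — node-position snapshots over
a mesh with fixed connectivity.  After time normalization (t=0 unfolded,
t=1 folded, interval durations proportional to mean node displacement) the
map Phi_t(p) = sum_i lambda_i x_i(t) carries any point of the reference
(unfolded) volume through the deformation using its barycentric coordinates
lambda_i in the reference tetrahedron, with linear interpolation of node
positions between bracketing snapshots.

Strain is a fiber-based quantity here: per-voxel mean of (folded fiber
length / unfolded fiber length) - 1, accumulated over the fibers whose
folded polyline crosses the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .grid import VoxelGrid
from .mesh import TetMesh


class OutsideDomainError(ValueError):
    """Query point not contained in the reference mesh."""


@dataclass
class Trajectory:
    """Ordered node-position snapshots with constant connectivity.

    ``mesh`` provides connectivity; ``snapshots[0]`` need not equal
    ``mesh.nodes`` (e.g. an unfold starts at the folded mesh).  ``times``
    is the normalized [0,1] parameterization; None until normalization.
    """

    mesh: TetMesh
    snapshots: np.ndarray          # (S, N, 3)
    raw_times: np.ndarray          # (S,)
    times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.snapshots = np.asarray(self.snapshots, dtype=float)
        self.raw_times = np.asarray(self.raw_times, dtype=float)
        if self.snapshots.ndim != 3 or self.snapshots.shape[0] != len(self.raw_times):
            raise ValueError("snapshots/raw_times shape mismatch")

    @property
    def n_snapshots(self) -> int:
        return int(self.snapshots.shape[0])

    def reversed(self) -> "Trajectory":
        """Time-reversed view (unfolding run -> unfolded-to-folded map)."""
        t = self.raw_times[-1] - self.raw_times[::-1]
        return Trajectory(mesh=self.mesh, snapshots=self.snapshots[::-1].copy(),
                          raw_times=t,
                          times=None if self.times is None
                          else (1.0 - self.times[::-1]).copy(),
                          meta=dict(self.meta, reversed=True))

    def positions_at(self, t: float) -> np.ndarray:
        """Node positions at normalized time t (linear between snapshots)."""
        times = self._times()
        t = float(t)
        if not (0.0 - 1e-12 <= t <= 1.0 + 1e-12):
            raise ValueError("t must lie in [0, 1]")
        t = min(max(t, times[0]), times[-1])
        k = int(np.searchsorted(times, t, side="right") - 1)
        k = min(k, len(times) - 2)
        t0, t1 = times[k], times[k + 1]
        w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        return (1.0 - w) * self.snapshots[k] + w * self.snapshots[k + 1]

    def _times(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        # fall back to rescaled raw times
        rt = self.raw_times
        span = rt[-1] - rt[0]
        if span <= 0:
            raise ValueError("degenerate trajectory times")
        return (rt - rt[0]) / span


def normalize_time(traj: Trajectory, statistic: str = "mean") -> Trajectory:
    """Displacement-based time normalization.

    Per-interval displacement d_k = mean (or max) over nodes of the
    Euclidean displacement between consecutive snapshots; normalized times
    are the cumulative d_k rescaled to [0, 1], so equal spans of t
    correspond to roughly equal amounts of physical deformation.
    """
    if traj.n_snapshots < 2:
        raise ValueError("need at least 2 snapshots to normalize")
    deltas = np.linalg.norm(np.diff(traj.snapshots, axis=0), axis=2)  # (S-1, N)
    agg = deltas.max(axis=1) if statistic == "max" else deltas.mean(axis=1)
    total = agg.sum()
    if total <= 0:
        raise ValueError("no deformation to normalize (all-zero displacement)")
    times = np.concatenate([[0.0], np.cumsum(agg)]) / total
    times[-1] = 1.0
    return Trajectory(mesh=traj.mesh, snapshots=traj.snapshots,
                      raw_times=traj.raw_times, times=times,
                      meta=dict(traj.meta, time_statistic=statistic))


class DeformationMap:
    """Phi_t realized over a normalized trajectory.

    Point location runs against the reference (t=0) tetrahedralization via
    a centroid k-d tree with exact barycentric acceptance (tolerance
    ``eps`` in barycentric units) and a brute-force fallback.
    """

    def __init__(self, trajectory: Trajectory, eps: float = 1e-6):
        if trajectory.times is None:
            trajectory = normalize_time(trajectory)
        self.trajectory = trajectory
        self.eps = float(eps)
        ref = trajectory.snapshots[0]
        tets = trajectory.mesh.tets
        self._ref = ref
        self._tets = tets
        x0 = ref[tets[:, 0]]
        edges = np.stack([ref[tets[:, 1]] - x0,
                          ref[tets[:, 2]] - x0,
                          ref[tets[:, 3]] - x0], axis=-1)  # (M,3,3)
        self._Tinv = np.linalg.inv(edges)
        self._x0 = x0
        self._tree = cKDTree(ref[tets].mean(axis=1))

    # -- location ------------------------------------------------------
    def _bary_for(self, points: np.ndarray, tet_idx: np.ndarray) -> np.ndarray:
        """(K,4) barycentric coords of points w.r.t. given tets."""
        rel = points - self._x0[tet_idx]
        lam123 = np.einsum("kij,kj->ki", self._Tinv[tet_idx], rel)
        lam0 = 1.0 - lam123.sum(axis=1)
        return np.column_stack([lam0, lam123])

    def locate_points(self, points: np.ndarray, k_candidates: int = 24):
        """(tet index, barycentric (K,4)) for each point; -1 if outside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        found = np.full(n, -1, dtype=int)
        bary = np.zeros((n, 4))
        k = min(k_candidates, len(self._tets))
        _, cand = self._tree.query(pts, k=k)
        cand = np.atleast_2d(cand)
        pending = np.arange(n)
        for col in range(cand.shape[1]):
            if not len(pending):
                break
            idx = cand[pending, col]
            lam = self._bary_for(pts[pending], idx)
            ok = lam.min(axis=1) >= -self.eps
            hit = pending[ok]
            found[hit] = idx[ok]
            bary[hit] = lam[ok]
            pending = pending[~ok]
        if len(pending):  # brute-force fallback, chunked over all tets
            for i in pending:
                lam = self._bary_for(pts[i][None, :].repeat(len(self._tets), 0),
                                     np.arange(len(self._tets)))
                j = int(np.argmax(lam.min(axis=1)))
                if lam[j].min() >= -self.eps:
                    found[i] = j
                    bary[i] = lam[j]
        # snap tiny negatives onto the face
        np.clip(bary, 0.0, None, out=bary)
        s = bary.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        bary /= s
        return found, bary

    def locate_point(self, p) -> tuple:
        tet, lam = self.locate_points(np.asarray(p, dtype=float)[None, :])
        if tet[0] < 0:
            raise OutsideDomainError(f"point {p} outside the reference mesh")
        return int(tet[0]), lam[0]

    # -- mapping -------------------------------------------------------
    def map_points(self, points: np.ndarray, t: float,
                   on_outside: str = "raise") -> np.ndarray:
        """Phi_t for an array of reference-space points.

        ``on_outside``: 'raise' or 'nan' (rows of NaN for unlocatable points).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tet, lam = self.locate_points(pts)
        bad = tet < 0
        if bad.any() and on_outside == "raise":
            raise OutsideDomainError(
                f"{int(bad.sum())} points outside the reference mesh")
        pos = self.trajectory.positions_at(t)
        corners = pos[self._tets[np.where(bad, 0, tet)]]     # (K,4,3)
        out = np.einsum("kc,kcd->kd", lam, corners)
        out[bad] = np.nan
        return out

    def map_point(self, p, t: float) -> np.ndarray:
        return self.map_points(np.asarray(p, dtype=float)[None, :], t)[0]


# ---------------------------------------------------------------------------
# strain maps

@dataclass
class StrainMap:
    grid: VoxelGrid
    strain: np.ndarray   # (nx,ny,nz) float, NaN where no fibers sampled
    count: np.ndarray    # (nx,ny,nz) int, fibers per voxel

    def defined_mask(self) -> np.ndarray:
        return self.count > 0


def _polyline_length(p: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def _polyline_voxels(p: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Unique in-grid voxel indices touched by a polyline (dense resampling)."""
    seg = np.diff(p, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    step = grid.spacing * 0.5
    pts = [p[:1]]
    for i, L in enumerate(lens):
        n = max(1, int(np.ceil(L / step)))
        u = (np.arange(1, n + 1) / n)[:, None]
        pts.append(p[i] + u * seg[i])
    dense = np.concatenate(pts)
    idx = grid.voxel_of(dense)
    idx = idx[grid.inside(idx)]
    if not len(idx):
        return idx.reshape(0, 3)
    return np.unique(idx, axis=0)


def strain_map(fibers_unfolded, fibers_folded, grid: VoxelGrid) -> StrainMap:
    """Per-voxel mean elongation ratio minus one, in folded space.

    The two fiber sets must be index-paired (same seeding).  Each fiber
    contributes its own length ratio to every voxel its *folded* polyline
    crosses; per-fiber ratios are averaged per voxel (see docs/methods.md
    for the alternative aggregation).  Strain is always > -1.
    """
    fu, ff = list(fibers_unfolded), list(fibers_folded)
    if len(fu) != len(ff):
        raise ValueError("fiber sets are not index-paired (count mismatch)")
    acc = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape, dtype=int)
    for pu, pf in zip(fu, ff):
        lu = _polyline_length(pu)
        if lu <= 0:
            continue
        ratio = _polyline_length(pf) / lu
        vox = _polyline_voxels(pf, grid)
        if not len(vox):
            continue
        acc[vox[:, 0], vox[:, 1], vox[:, 2]] += ratio
        cnt[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    strain = np.full(grid.shape, np.nan)
    nz = cnt > 0
    strain[nz] = acc[nz] / cnt[nz] - 1.0
    return StrainMap(grid=grid, strain=strain, count=cnt)
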