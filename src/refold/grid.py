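"""Axis-aligned voxel grids shared by the fiber, strain and evaluation code.

Voxel-center convention: voxel (i,j,k) is centered at
origin + (i+0.5, j+0.5, k+0.5) * spacing.  The NIfTI affine written by
:mod:`refold.io` encodes exactly this geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    origin: tuple        # mm, lower corner of voxel (0,0,0)
    spacing: float       # mm, isotropic
    shape: tuple         # (nx, ny, nz)

    @classmethod
    def from_bounds(cls, lo, hi, spacing: float, pad: float = 0.0) -> "VoxelGrid":
        lo = np.asarray(lo, dtype=float) - pad
        hi = np.asarray(hi, dtype=float) + pad
        shape = np.maximum(1, np.ceil((hi - lo) / spacing).astype(int))
        return cls(tuple(lo), float(spacing), tuple(int(s) for s in shape))

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices of points; may fall outside the grid."""
        p = np.atleast_2d(points)
        return np.floor((p - np.asarray(self.origin)) / self.spacing).astype(int)

    def inside(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        shp = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shp), axis=1)

    def centers(self) -> np.ndarray:
        """(nx,ny,nz,3) array of voxel-center coordinates."""
        ax = [np.asarray(self.origin)[d] + (np.arange(self.shape[d]) + 0.5) * self.spacing
              for d in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (voxel-center convention)."""
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.spacing
        A[:3, 3] = np.asarray(self.origin) + 0.5 * self.spacing
        return A

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.spacing - other.spacing) < tol
                and np.allclose(self.origin, other.origin, atol=tol))
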