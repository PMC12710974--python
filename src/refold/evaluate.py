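"""Voxel-wise orientation agreement and its regional/depth aggregation.

The agreement score between two orientation fields is the absolute cosine
C(v) = |a(v) . b(v)| per voxel — sign-invariant, as appropriate for axial
(fiber-orientation) data, in [0, 1].  Scores can be grouped by an integer
parcel volume (regional means, as done for atlas parcels) or binned by
distance from a surface (depth profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fibers import OrientationField
from .grid import VoxelGrid


@dataclass
class SimilarityMap:
    grid: VoxelGrid
    scores: np.ndarray    # (nx,ny,nz) float, NaN where undefined

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.scores)

    def mean(self) -> float:
        return float(np.nanmean(self.scores))


def cosine_similarity_map(a: OrientationField, b: OrientationField,
                          mask: Optional[np.ndarray] = None) -> SimilarityMap:
    """C(v) = |a(v) . b(v)| where both fields are defined and mask is true.

    The two fields must share grid geometry.  ``mask`` is a caller-supplied
    include mask (e.g. a white-matter mask excluding interhemispheric
    voxels); None includes everything.
    """
    if not a.grid.same_geometry(b.grid):
        raise ValueError("orientation fields live on different grids")
    valid = a.mask & b.mask
    if mask is not None:
        if mask.shape != valid.shape:
            raise ValueError("mask shape does not match grid")
        valid = valid & mask.astype(bool)
    dots = np.abs(np.einsum("...d,...d->...", a.vectors, b.vectors))
    scores = np.where(valid, np.clip(dots, 0.0, 1.0), np.nan)
    return SimilarityMap(grid=a.grid, scores=scores)


def region_scores(sim: SimilarityMap, parcels: np.ndarray,
                  exclude: Iterable[int] = ()) -> pd.DataFrame:
    """Per-parcel count/mean/min/max of the defined similarity scores.

    ``parcels`` is an integer label volume aligned with the score grid.
    Labels with no defined voxels are omitted.  The returned frame carries
    the overall mean, with and without the excluded label set, in
    ``DataFrame.attrs``.
    """
    if parcels.shape != sim.scores.shape:
        raise ValueError("parcel volume shape does not match score grid")
    ok = sim.defined_mask()
    rows = []
    for label in np.unique(parcels[ok]):
        vals = sim.scores[ok & (parcels == label)]
        rows.append({"label": int(label), "count": int(vals.size),
                     "mean": float(vals.mean()), "min": float(vals.min()),
                     "max": float(vals.max())})
    df = pd.DataFrame(rows, columns=["label", "count", "mean", "min", "max"])
    df.attrs["overall_mean"] = float(sim.scores[ok].mean()) if ok.any() else np.nan
    excl = set(int(e) for e in exclude)
    keep = ok & ~np.isin(parcels, list(excl))
    df.attrs["overall_mean_excluding"] = (
        float(sim.scores[keep].mean()) if keep.any() else np.nan)
    df.attrs["excluded_labels"] = sorted(excl)
    return df


def depth_profile(sim: SimilarityMap, surface_points: np.ndarray,
                  bin_width: float = 1.0, max_depth: float = 6.0) -> pd.DataFrame:
    """Mean similarity binned by Euclidean distance to the nearest surface point.

    Depth bins are [0,w), [w,2w), ... up to ``max_depth``; empty bins are
    reported with count 0 and NaN mean.
    """
    ok = sim.defined_mask()
    centers = sim.grid.centers()[ok]
    scores = sim.scores[ok]
    tree = cKDTree(np.asarray(surface_points, dtype=float))
    depth, _ = tree.query(centers)
    edges = np.arange(0.0, max_depth + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (depth >= lo) & (depth < hi)
        rows.append({"depth_lo": lo, "depth_hi": hi, "count": int(sel.sum()),
                     "mean": float(scores[sel].mean()) if sel.any() else np.nan})
    return pd.DataFrame(rows)
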