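"""Canonical slab experiments: unfold/refold round trip and fiber pipeline.

These functions bundle the package's study conditions — the synthetic
folded slab, the calibrated solver configuration, and the fiber/evaluation
parameters — so that tests, the acceptance script, the CLI and the examples
all run the same experiments.

Two slabs are used:

* the *round-trip slab* (fold amplitude/wavelength = 0.25, pinned base):
  gentle folds and an anchored frame, used to measure unfolding efficacy
  (gyrification index, volume drift) and quasi-reversibility (height-field
  correlation, RMS node error);
* the *fiber-study slab* (amplitude/wavelength ~ 0.47, free base): deeper
  sulci where sulcal-wall bending is strong enough to show the expected
  gyral-vs-sulcal alignment asymmetry of the deformed radial scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .deformation import DeformationMap, StrainMap, normalize_time, strain_map
from .evaluate import SimilarityMap, cosine_similarity_map
from .fibers import (FiberSet, OrientationField, advect_fibers,
                     extract_primary_peaks, generate_radial_fibers,
                     inward_normal_field)
from .geometry import (SlabSpec, analytic_slab_orientation, make_folded_slab,
                       slab_base_nodes, slab_phase)
from .grid import VoxelGrid
from .mesh import TetMesh, compute_node_masses, gyrification_index
from .xpbd import MaterialParams, SimConfig, run_refold, run_simulation

#: round-trip study slab: A/W = 0.25, ~16.5k tets at h = 0.35
ROUND_TRIP_SLAB = SlabSpec(extent_x=12.0, extent_y=3.0, depth=3.0,
                           fold_amplitude=1.0, fold_wavelength=4.0,
                           gm_thickness=0.75, h=0.35)

#: fiber study slab: deeper folds (A/W ~ 0.47), ~24k tets at h = 0.3
FIBER_STUDY_SLAB = SlabSpec(extent_x=12.0, extent_y=3.0, depth=3.0,
                            fold_amplitude=1.4, fold_wavelength=3.0,
                            gm_thickness=0.75, h=0.3)


def default_sim_config(**overrides) -> SimConfig:
    """The calibrated slab solver configuration (docs/methods.md)."""
    kw = dict(n_steps=150, stop_gi=1.05)
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# round trip

@dataclass
class RoundTripResult:
    mesh: TetMesh
    unfold: "Trajectory"
    refold: "Trajectory"
    gi_history: list
    volume_drift: float           # max |V/V0 - 1| during unfold
    gi_monotone: bool
    height_correlation: float     # folded vs refolded top-surface heights
    rms_node_error: float         # mm, refolded vs original positions


def slab_round_trip(spec: SlabSpec = ROUND_TRIP_SLAB,
                    mat: Optional[MaterialParams] = None,
                    config: Optional[SimConfig] = None,
                    do_refold: bool = True) -> RoundTripResult:
    """Unfold the folded slab to GI <= stop_gi, then refold and compare."""
    mat = mat or MaterialParams()
    config = config or default_sim_config()
    mesh = compute_node_masses(make_folded_slab(spec), mat.density)
    pinned = slab_base_nodes(mesh)
    unfold = run_simulation(mesh, mat, config, pinned=pinned)

    gi = unfold.meta["gi_history"]
    vols = np.asarray(unfold.meta["volume_history"])
    drift = float(np.abs(vols / vols[0] - 1.0).max())
    mono = bool(all(a >= b - 1e-9 for a, b in zip(gi, gi[1:])))

    corr = rms = np.nan
    refold = None
    if do_refold:
        refold = run_refold(mesh, mat, config, unfold)
        final = refold.snapshots[-1]
        top = np.unique(mesh.surface_faces[mesh.face_region == 1])
        corr = float(np.corrcoef(mesh.nodes[top, 2], final[top, 2])[0, 1])
        rms = float(np.sqrt(np.mean(np.sum((final - mesh.nodes) ** 2, axis=1))))
    return RoundTripResult(mesh=mesh, unfold=unfold, refold=refold,
                           gi_history=gi, volume_drift=drift, gi_monotone=mono,
                           height_correlation=corr, rms_node_error=rms)


# ---------------------------------------------------------------------------
# fiber pipeline

@dataclass
class FiberPipelineResult:
    spec: SlabSpec
    mesh: TetMesh
    unfold: "Trajectory"
    dmap: DeformationMap
    fibers_unfolded: FiberSet
    fibers_folded: FiberSet
    peaks: OrientationField
    reference: OrientationField
    similarity: SimilarityMap
    strain: StrainMap
    grid: VoxelGrid
    wm_mask: np.ndarray
    phase: np.ndarray              # sin(2 pi x / W) at voxel centers
    summary: dict = field(default_factory=dict)


def slab_fiber_pipeline(spec: SlabSpec = FIBER_STUDY_SLAB,
                        mat: Optional[MaterialParams] = None,
                        config: Optional[SimConfig] = None,
                        voxel_size: float = 0.325,
                        smooth_iters: int = 30,
                        fiber_step: float = 0.2,
                        max_len: float = 2.0,
                        n_seeds: int = 6000,
                        seed: int = 0) -> FiberPipelineResult:
    """Unfold, seed radial fibers, advect to the folded state, evaluate.

    The deformation map is the time-reversed unfolding trajectory with
    displacement-normalized time (t=0 unfolded, t=1 folded).  Simulated
    primary peaks from the advected fibers are scored against the analytic
    radial orientation field of the folded slab within a white-matter mask
    (gray shell and domain margins excluded); the fiber-elongation strain
    map is computed in folded space on the same grid.
    """
    mat = mat or MaterialParams()
    config = config or default_sim_config()
    mesh = compute_node_masses(make_folded_slab(spec), mat.density)
    unfold = run_simulation(mesh, mat, config, pinned=None)

    traj = normalize_time(unfold.reversed())
    dmap = DeformationMap(traj)
    unfolded_pos = traj.snapshots[0]

    flow = inward_normal_field(mesh, voxel_size=voxel_size,
                               smooth_iters=smooth_iters,
                               positions=unfolded_pos)
    fib_u = generate_radial_fibers(mesh, flow, step=fiber_step,
                                   max_len=max_len, n_seeds=n_seeds,
                                   seed=seed, positions=unfolded_pos)
    fib_f = advect_fibers(dmap, fib_u, 1.0, drop_unlocatable=True)
    fib_u_paired = fib_u.subset(fib_f.ids)

    grid = VoxelGrid.from_bounds(mesh.nodes.min(axis=0),
                                 mesh.nodes.max(axis=0), voxel_size)
    peaks = extract_primary_peaks(fib_f, grid)

    anal = analytic_slab_orientation(spec)
    centers = grid.centers()
    ref = OrientationField(
        grid=grid,
        vectors=anal(centers.reshape(-1, 3)).reshape(grid.shape + (3,)),
        mask=np.ones(grid.shape, dtype=bool))

    X, Y, Z = np.moveaxis(centers, -1, 0)
    margin = 2.0 * voxel_size
    wm = ((Z < spec.top_height(X) - spec.gm_thickness) & (Z > margin)
          & (X > margin) & (X < spec.extent_x - margin)
          & (Y > margin) & (Y < spec.extent_y - margin))
    similarity = cosine_similarity_map(peaks, ref, mask=wm)
    strain = strain_map(fib_u_paired, fib_f, grid)
    phase = slab_phase(spec, X)

    ok = np.isfinite(similarity.scores)
    oks = np.isfinite(strain.strain) & wm

    def _mean(arr, m):
        return float(arr[m].mean()) if m.any() else float("nan")

    summary = {
        "final_gi": unfold.meta["gi_history"][-1],
        "n_fibers": len(fib_f),
        "cos_overall": float(np.nanmean(similarity.scores)),
        "cos_crown": _mean(similarity.scores, ok & (phase > 0.5)),
        "cos_bank": _mean(similarity.scores, ok & (np.abs(phase) <= 0.5)),
        "cos_fundus": _mean(similarity.scores, ok & (phase < -0.5)),
        "cos_gyral": _mean(similarity.scores, ok & (phase > 0)),
        "cos_sulcal": _mean(similarity.scores, ok & (phase < 0)),
        "strain_crown": _mean(strain.strain, oks & (phase > 0.5)),
        "strain_bank": _mean(strain.strain, oks & (np.abs(phase) <= 0.5)),
        "strain_fundus": _mean(strain.strain, oks & (phase < -0.5)),
    }
    return FiberPipelineResult(spec=spec, mesh=mesh, unfold=unfold, dmap=dmap,
                               fibers_unfolded=fib_u_paired, fibers_folded=fib_f,
                               peaks=peaks, reference=ref,
                               similarity=similarity, strain=strain,
                               grid=grid, wm_mask=wm, phase=phase,
                               summary=summary)
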