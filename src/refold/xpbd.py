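"""Quasi-static XPBD solver for reversible folding/unfolding.

The mechanical model is a two-tissue neo-Hookean solid,

    Psi_Neo = (lambda/2) (det F - 1)^2 + (mu/2) (tr(F^T F) - 3) = Psi_H + Psi_D,

discretised as per-tet "stable" constraints — a hydrostatic constraint
C_H = V/V0 - 1 (compliance 1/(lambda*V0)) and a deviatoric constraint
C_D = ||F||_F (compliance 1/(mu*V0)) — plus scheduled surface-area
constraints (the tangential contraction/expansion drive) and smoothing
constraints on adjacent outer-face pairs.

Integration is quasi-static with infinite viscous damping: there is no
inertial predictor, every solver ministep starts from the current
positions, resets the Lagrange multipliers and applies one Gauss-Seidel
sweep with alpha~ = alpha/dt_sub^2.  ``dt_sub`` must resolve the elastic
timescale of the mesh (sqrt(E/rho) wave transit across an element — about
2e-4 s at brain-tissue stiffness and sub-mm elements); at that scale the
soft (deviatoric) family acts as a damped gradient flow on the elastic
energy while near-incompressibility and the area drive stay stiff.  The
outer step's ``dt`` is purely a schedule clock.

Unfolding decreases the area / smoothing rest targets geometrically each
step, clamped from below at their *flat-envelope* values (the area of each
face, and the in-plane part of each smoothing offset, projected onto the
reference envelope) — reverse tangential growth stops at the unfolded
amount rather than contracting indefinitely, which would wrinkle the
surface.  Per-step targets are recorded; refolding replays them in reverse
and then anneals to the restored equilibrium, which realizes the
quasi-reversibility of slow folding.

Viscoelastic rest-pose relaxation blends each tet's rest-edge matrix
toward its current pose, relaxing deviatoric (shape) stress while the
hydrostatic constraint keeps its original rest volume (volume memory is
never erased).

Internal solver units are mm / mg / s, so stiffnesses in Pa are scaled by
1e3 and node masses in kg by 1e6 on entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .deformation import Trajectory
from .mesh import (GRAY, MeshError, TetMesh, compute_node_masses,
                   gyrification_index, isoperimetric_excess)

_PA_TO_INTERNAL = 1e3   # Pa -> mg / (mm s^2)
_KG_TO_INTERNAL = 1e6   # kg -> mg


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialParams:
    """Tissue material constants.

    Stiffness defaults are experimentally reported brain-tissue values:
    1.895 kPa (white), 1.389 kPa (gray), Poisson ratio 0.48, density
    1040 kg/m^3.  ``visco_factor`` (1/s of schedule time) is the rest-pose
    relaxation rate; 0 disables viscoelasticity (pure elasticity, full
    fold memory — the right setting for round-trip reversibility).
    """

    E_white: float = 1895.0   # Pa
    E_gray: float = 1389.0    # Pa
    nu: float = 0.48
    density: float = 1040.0   # kg/m^3
    visco_factor: float = 0.0  # 1/s

    def __post_init__(self):
        if not (0.0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must be in (0, 0.5)")
        if self.E_white <= 0 or self.E_gray <= 0 or self.density <= 0:
            raise ValueError("stiffness and density must be positive")
        if self.visco_factor < 0:
            raise ValueError("visco_factor must be >= 0")

    def lame(self, E):
        """(lambda, mu) in Pa for Young's modulus E."""
        lam = E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = E / (2.0 * (1.0 + self.nu))
        return lam, mu


@dataclass
class SimConfig:
    """Solver and schedule configuration.

    ``dt`` is the schedule clock; each outer step runs ``substeps`` solver
    ministeps of duration ``dt_sub`` (physical seconds — keep at the
    elastic timescale of the mesh).  ``rate_area`` / ``rate_smooth`` are
    fractional per-unit-schedule-time decay rates of the rest targets.
    ``scale_*`` multiply the physically derived compliances per family
    (1 = physical stiffness, larger = softer).  Defaults were calibrated
    once on the folded-slab round trip (docs/methods.md) and are the
    package's study conditions.
    """

    dt: float = 1.0
    dt_sub: float = 1e-4
    substeps: int = 100
    n_steps: int = 150
    direction: str = "unfold"
    snapshot_every: int = 6
    stop_gi: Optional[float] = None
    stop_iso_excess: Optional[float] = None
    seed: int = 0
    rate_area: float = 0.03
    rate_smooth: float = 0.06
    scale_h: float = 1.0
    scale_d: float = 50.0
    scale_area: float = 0.001
    scale_smooth: float = 0.001
    schedule_floor: str = "auto"   # 'flat' (slab envelope), 'none', 'auto'
    enable_tet: bool = True
    enable_deviatoric: bool = True
    enable_area: bool = True
    enable_smoothing: bool = True
    max_inverted_frac: float = 0.05
    settle_plan: tuple = ((4e-4, 4000), (2e-4, 2000), (1e-4, 2000))

    def __post_init__(self):
        if self.dt <= 0 or self.dt_sub <= 0:
            raise ValueError("dt and dt_sub must be > 0")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.direction not in ("unfold", "refold"):
            raise ValueError("direction must be 'unfold' or 'refold'")
        if self.schedule_floor not in ("flat", "none", "auto"):
            raise ValueError("schedule_floor must be 'flat', 'none' or 'auto'")


# ---------------------------------------------------------------------------
# energy / kinematics primitives

def deformation_gradient(tet_positions: np.ndarray, Dm: np.ndarray) -> np.ndarray:
    """F = Ds * Dm^-1 for one tetrahedron (rows of tet_positions: x0..x3)."""
    Dm = np.asarray(Dm, dtype=float)
    if abs(np.linalg.det(Dm)) < 1e-300:
        raise ValueError("singular rest matrix Dm")
    p = np.asarray(tet_positions, dtype=float)
    Ds = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
    return Ds @ np.linalg.inv(Dm)


def neo_hookean_energy(F: np.ndarray, lam: float, mu: float) -> tuple:
    """(Psi_H, Psi_D) energy densities; Psi_D is the signed trace form."""
    F = np.asarray(F, dtype=float)
    psi_h = 0.5 * lam * (np.linalg.det(F) - 1.0) ** 2
    psi_d = 0.5 * mu * (np.trace(F.T @ F) - 3.0)
    return float(psi_h), float(psi_d)


# ---------------------------------------------------------------------------
# single-constraint projection API (unit-test surface of the kernels)

@dataclass
class TetConstraint:
    tet: np.ndarray          # 4 node indices
    Dm: np.ndarray           # 3x3 rest edge matrix (columns = edges), mm
    rest_volume: float       # mm^3 (= det(Dm)/6 at build time)
    lam_tet: float           # Pa
    mu_tet: float            # Pa

    def __post_init__(self):
        if np.linalg.det(self.Dm) <= 0:
            raise ValueError("rest matrix must have positive determinant")


@dataclass
class AreaConstraint:
    face: np.ndarray         # 3 node indices
    rest_area: float         # mm^2


@dataclass
class SmoothingConstraint:
    quad: np.ndarray         # (s0, s1, a, b)
    rest_distance: float     # mm


def project_tet_constraint(positions, inv_mass, c: TetConstraint,
                           compliance_h: float, compliance_d: float,
                           dt_sub: float, multipliers=(0.0, 0.0),
                           deviatoric: bool = True):
    """One XPBD projection of the hydrostatic + deviatoric pair, in place.

    Returns the updated (lambda_H, lambda_D) multipliers.  Compliances are
    the raw alpha values (1/(lam*V0), 1/(mu*V0) for the physical ones).
    """
    tets = np.asarray(c.tet, dtype=np.int64).reshape(1, 4)
    Bm = np.ascontiguousarray(np.linalg.inv(c.Dm).reshape(1, 3, 3))
    lam_h = np.array([multipliers[0]])
    lam_d = np.array([multipliers[1]])
    K.project_tets(positions, inv_mass, tets, Bm,
                   np.array([c.rest_volume]),
                   np.array([compliance_h]),
                   np.array([compliance_d if deviatoric else -1.0]),
                   lam_h, lam_d, 1.0 / dt_sub ** 2)
    return float(lam_h[0]), float(lam_d[0])


def project_area_constraint(positions, inv_mass, c: AreaConstraint,
                            compliance: float, dt_sub: float,
                            multiplier: float = 0.0) -> float:
    lam = np.array([multiplier])
    K.project_areas(positions, inv_mass,
                    np.asarray(c.face, dtype=np.int64).reshape(1, 3),
                    np.array([c.rest_area]), np.array([compliance]),
                    lam, 1.0 / dt_sub ** 2)
    return float(lam[0])


def project_smoothing_constraint(positions, inv_mass, c: SmoothingConstraint,
                                 compliance: float, dt_sub: float,
                                 multiplier: float = 0.0) -> float:
    lam = np.array([multiplier])
    K.project_smoothing(positions, inv_mass,
                        np.asarray(c.quad, dtype=np.int64).reshape(1, 4),
                        np.array([c.rest_distance]), np.array([compliance]),
                        lam, 1.0 / dt_sub ** 2)
    return float(lam[0])


def update_viscoelastic_rest(positions, tets, Dm, Bm, beta: float, dt: float):
    """Blend rest matrices toward current pose: kappa = 1 - exp(-beta*dt)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    kappa = 1.0 - np.exp(-beta * dt)
    K.relax_rest_pose(positions, np.asarray(tets, dtype=np.int64), Dm, Bm, kappa)
    return kappa


# ---------------------------------------------------------------------------
# full simulation state

def _surface_face_pairs(faces: np.ndarray) -> np.ndarray:
    """(s0, s1, a, b) quads for every pair of faces sharing an edge."""
    from collections import defaultdict
    edge_faces = defaultdict(list)
    for fi, (u, v, w) in enumerate(faces):
        for a, b in ((u, v), (v, w), (w, u)):
            edge_faces[(min(a, b), max(a, b))].append(fi)
    quads = []
    for (s0, s1), fl in sorted(edge_faces.items()):
        if len(fl) != 2:
            continue
        opp = []
        for fi in fl:
            tri = set(int(x) for x in faces[fi])
            opp.append((tri - {s0, s1}).pop())
        quads.append((s0, s1, opp[0], opp[1]))
    return np.array(quads, dtype=np.int64).reshape(-1, 4)


class SimState:
    """Evolving solver state: positions, constraint arrays, schedules."""

    def __init__(self, mesh: TetMesh, mat: MaterialParams, config: SimConfig,
                 pinned: Optional[Sequence[int]] = None):
        if mesh.node_mass is None:
            mesh = compute_node_masses(mesh, mat.density)
        self.mesh = mesh
        self.mat = mat
        self.config = config

        self.pos = mesh.nodes.astype(np.float64).copy()
        self.inv_mass = 1.0 / (mesh.node_mass * _KG_TO_INTERNAL)
        if pinned is not None and len(pinned):
            self.inv_mass[np.asarray(pinned, dtype=int)] = 0.0
        self.pinned = np.asarray(pinned if pinned is not None else [], dtype=int)

        # --- tet constraints -------------------------------------------
        tets = np.ascontiguousarray(mesh.tets.astype(np.int64))
        p = self.pos
        Dm = np.stack([p[tets[:, 1]] - p[tets[:, 0]],
                       p[tets[:, 2]] - p[tets[:, 0]],
                       p[tets[:, 3]] - p[tets[:, 0]]], axis=-1)  # (M,3,3) cols
        self.tets = tets
        self.Dm = np.ascontiguousarray(Dm)
        self.Bm = np.ascontiguousarray(np.linalg.inv(Dm))
        self.rest_vol = np.linalg.det(Dm) / 6.0
        if (self.rest_vol <= 0).any():
            raise MeshError("mesh contains non-positive tets")
        E_node = np.where(mesh.tissue == GRAY, mat.E_gray, mat.E_white)
        E_tet = E_node[tets].mean(axis=1)
        lam_pa, mu_pa = mat.lame(E_tet)
        self.alpha_h = config.scale_h / (lam_pa * _PA_TO_INTERNAL * self.rest_vol)
        self.alpha_d = config.scale_d / (mu_pa * _PA_TO_INTERNAL * self.rest_vol)
        if not config.enable_deviatoric:
            self.alpha_d = np.full_like(self.alpha_d, -1.0)

        # --- surface constraints on the outer (region-1) faces ---------
        faces = np.ascontiguousarray(
            mesh.surface_faces[mesh.face_region == 1].astype(np.int64))
        self.faces = faces
        a, b, c = (p[faces[:, i]] for i in range(3))
        area_vec = 0.5 * np.cross(b - a, c - a)
        self.rest_area0 = np.linalg.norm(area_vec, axis=1)
        self.rest_area = self.rest_area0.copy()
        mu_surf = mat.lame(mat.E_gray)[1] * _PA_TO_INTERNAL
        h_ref = float(np.sqrt(self.rest_area0.mean())) if len(faces) else 1.0
        self.alpha_a = np.full(len(faces),
                               config.scale_area / (mu_surf * max(h_ref, 1e-9) ** 3))

        self.quads = _surface_face_pairs(faces)
        d0 = np.zeros((len(self.quads), 3))
        if len(self.quads):
            d0 = ((p[self.quads[:, 2]] + p[self.quads[:, 3]])
                  - (p[self.quads[:, 0]] + p[self.quads[:, 1]]))
        self.rest_len0 = 0.5 * np.linalg.norm(d0, axis=1)
        self.rest_len = self.rest_len0.copy()
        self.alpha_s = np.full(len(self.quads),
                               config.scale_smooth / (mu_surf * max(h_ref, 1e-9) ** 3))

        # --- schedule floors: stop reverse growth at the flat envelope --
        floor_mode = config.schedule_floor
        if floor_mode == "auto":
            floor_mode = ("flat" if mesh.meta.get("envelope") == "projection"
                          else "none")
        if floor_mode == "flat":
            # area of each face, and in-plane part of each smoothing offset,
            # projected onto the slab base plane
            self.area_floor = np.abs(area_vec[:, 2])
            self.len_floor = 0.5 * np.linalg.norm(d0[:, :2], axis=1)
        else:
            self.area_floor = np.zeros(len(faces))
            self.len_floor = np.zeros(len(self.quads))

        # multipliers (reset each ministep)
        self.lam_h = np.zeros(len(tets))
        self.lam_d = np.zeros(len(tets))
        self.lam_a = np.zeros(len(faces))
        self.lam_s = np.zeros(len(self.quads))

        self.time = 0.0
        self.step_count = 0
        self.schedule_targets: list = []   # (rest_area, rest_len) per step
        self.residual_history: list = []

    # ------------------------------------------------------------------
    def advance_schedules(self, targets: Optional[tuple] = None):
        """Decay (unfold) or replay (refold) the rest targets for one step."""
        cfg = self.config
        if targets is None:
            fa = 1.0 - cfg.rate_area * cfg.dt
            fs = 1.0 - cfg.rate_smooth * cfg.dt
            if fa <= 0 or fs <= 0:
                raise SimulationError("schedule rate too large for dt")
            self.rest_area = np.maximum(self.rest_area * fa, self.area_floor)
            self.rest_len = np.maximum(self.rest_len * fs, self.len_floor)
        else:
            self.rest_area = targets[0].copy()
            self.rest_len = targets[1].copy()
        self.schedule_targets.append((self.rest_area.copy(),
                                      self.rest_len.copy()))

    def ministep(self, dt_sub: Optional[float] = None):
        """One solver ministep: multiplier reset + one Gauss-Seidel sweep."""
        cfg = self.config
        inv_dt2 = 1.0 / (dt_sub if dt_sub is not None else cfg.dt_sub) ** 2
        self.lam_h[:] = 0.0
        self.lam_d[:] = 0.0
        self.lam_a[:] = 0.0
        self.lam_s[:] = 0.0
        if cfg.enable_tet:
            K.project_tets(self.pos, self.inv_mass, self.tets, self.Bm,
                           self.rest_vol, self.alpha_h, self.alpha_d,
                           self.lam_h, self.lam_d, inv_dt2)
        if cfg.enable_area and len(self.faces):
            K.project_areas(self.pos, self.inv_mass, self.faces,
                            self.rest_area, self.alpha_a, self.lam_a, inv_dt2)
        if cfg.enable_smoothing and len(self.quads):
            K.project_smoothing(self.pos, self.inv_mass, self.quads,
                                self.rest_len, self.alpha_s, self.lam_s, inv_dt2)

    def residuals(self) -> dict:
        rh, rd, ra, rs = K.residuals(self.pos, self.tets, self.Bm, self.rest_vol,
                                     self.faces, self.rest_area,
                                     self.quads, self.rest_len)
        return {"hydrostatic": rh, "deviatoric": rd, "area": ra, "smoothing": rs}

    def check_health(self):
        if not np.isfinite(self.pos).all():
            raise SimulationError("NaN/inf positions; aborting")
        vols = self.mesh.tet_volumes(self.pos)
        frac = float((vols <= 0).mean())
        if frac > self.config.max_inverted_frac:
            raise SimulationError(
                f"inverted-tet fraction {frac:.3f} exceeds limit "
                f"{self.config.max_inverted_frac}")


def quasi_static_step(state: SimState, targets: Optional[tuple] = None,
                      advance: bool = True) -> dict:
    """One outer step: advance schedules, then ``substeps`` ministeps.

    With infinite damping every ministep starts at rest (no inertial
    prediction); the sweep sequence relaxes the mesh toward the elastic
    equilibrium under the current rest targets.  The viscoelastic rest-pose
    update runs once per outer step.  Returns per-family max-|C| residuals.
    """
    if advance:
        state.advance_schedules(targets)
    for _ in range(state.config.substeps):
        state.ministep()
    kappa = 1.0 - np.exp(-state.mat.visco_factor * state.config.dt)
    if kappa > 0:
        K.relax_rest_pose(state.pos, state.tets, state.Dm, state.Bm, kappa)
    state.time += state.config.dt
    state.step_count += 1
    res = state.residuals()
    state.residual_history.append(res)
    return res


def solve_equilibrium(state: SimState,
                      dts=(1e-3, 3e-4, 1e-4, 3e-5, 1e-5),
                      tol: float = 1e-12, max_sweeps: int = 60000) -> int:
    """Relax a state to its elastic equilibrium with frozen schedules.

    Anneals the ministep duration downward; each stage runs until the max
    per-ministep node displacement falls below ``tol``.  The ministep bias
    shrinks quadratically with dt_sub, so the final fixed point matches the
    constrained energy minimum to high accuracy.  Returns total sweeps.
    """
    total = 0
    for dt_sub in dts:
        prev = state.pos.copy() + np.inf
        for _ in range(max_sweeps):
            state.ministep(dt_sub)
            total += 1
            if np.abs(state.pos - prev).max() < tol:
                break
            prev = state.pos.copy()
    return total


# ---------------------------------------------------------------------------
# drivers

def run_simulation(mesh: TetMesh, mat: MaterialParams, config: SimConfig,
                   pinned: Optional[Sequence[int]] = None,
                   replay: Optional[Sequence[tuple]] = None,
                   initial_positions: Optional[np.ndarray] = None,
                   initial_rest: Optional[tuple] = None) -> Trajectory:
    """Run a full unfold (or refold) and return the recorded trajectory.

    Unfold: rest targets decay toward the flat-envelope floors; stops early
    once the gyrification index reaches ``config.stop_gi`` (checked at
    snapshots).  Refold: pass ``replay`` — the unfold's recorded per-step
    target arrays — replayed in reverse, followed by the annealed settling
    plan; :func:`run_refold` assembles this from an unfold trajectory.
    """
    state = SimState(mesh, mat, config, pinned=pinned)
    if initial_positions is not None:
        state.pos[:] = np.asarray(initial_positions, dtype=float)
    if initial_rest is not None:
        state.Dm[:] = initial_rest[0]
        state.Bm[:] = np.ascontiguousarray(np.linalg.inv(state.Dm))

    if config.direction == "refold":
        if replay is None:
            raise SimulationError("refold requires the unfold schedule replay")
        target_seq = list(replay)
        n_steps = len(target_seq)
        if n_steps and replay is not None:
            # start from the decayed targets of the unfold end
            state.rest_area = replay[0][0].copy()
            state.rest_len = replay[0][1].copy()
    else:
        target_seq = [None] * config.n_steps
        n_steps = config.n_steps

    snapshots = [state.pos.copy()]
    times = [0.0]
    gi0 = gyrification_index(mesh, state.pos)
    gi_history = [gi0]
    vol_history = [float(mesh.tet_volumes(state.pos).sum())]

    stopped = False
    if (config.direction == "unfold" and config.stop_gi is not None
            and gi0 <= config.stop_gi):
        stopped = True
        n_steps = 0

    for k in range(n_steps):
        quasi_static_step(state, targets=target_seq[k])
        is_snap = ((k + 1) % config.snapshot_every == 0) or (k + 1 == n_steps)
        if is_snap:
            state.check_health()
            snapshots.append(state.pos.copy())
            times.append(state.time)
            gi_history.append(gyrification_index(mesh, state.pos))
            vol_history.append(float(mesh.tet_volumes(state.pos).sum()))
            if (config.direction == "unfold" and config.stop_gi is not None
                    and gi_history[-1] <= config.stop_gi):
                stopped = True
                break
            if (config.direction == "unfold"
                    and config.stop_iso_excess is not None
                    and isoperimetric_excess(mesh, state.pos)
                    <= config.stop_iso_excess):
                stopped = True
                break

    if config.direction == "refold":
        # anneal to the restored-target equilibrium
        for dt_sub, n in config.settle_plan:
            for _ in range(int(n)):
                state.ministep(dt_sub)
            state.time += config.dt
        state.check_health()
        snapshots.append(state.pos.copy())
        times.append(state.time)
        gi_history.append(gyrification_index(mesh, state.pos))
        vol_history.append(float(mesh.tet_volumes(state.pos).sum()))

    traj = Trajectory(
        mesh=mesh,
        snapshots=np.array(snapshots),
        raw_times=np.array(times),
        meta={
            "direction": config.direction,
            "gi_history": gi_history,
            "volume_history": vol_history,
            "residual_history": state.residual_history,
            "schedule_targets": state.schedule_targets,
            "initial_targets": (state.rest_area0.copy(), state.rest_len0.copy()),
            "stopped_at_gi_target": stopped,
            "config": {k: v for k, v in vars(config).items()},
            "material": {k: v for k, v in vars(mat).items()},
            "final_Dm": state.Dm.copy(),
            "pinned": state.pinned,
        },
    )
    return traj


def run_refold(mesh: TetMesh, mat: MaterialParams, config: SimConfig,
               unfold: Trajectory) -> Trajectory:
    """Replay an unfold's schedule in reverse, starting from its final state.

    The refold begins at the unfolded configuration with the unfold's final
    rest-pose matrices and rest targets, restores the recorded targets step
    by step in reverse order (ending at the original folded-state targets),
    and settles.  With ``visco_factor == 0`` the elastic memory plus the
    target replay drive the surface back to the folded configuration.
    """
    recorded = unfold.meta["schedule_targets"]
    if not recorded:
        raise SimulationError("unfold trajectory carries no schedule record")
    r0, l0 = unfold.meta["initial_targets"]
    replay = [recorded[k] for k in range(len(recorded) - 2, -1, -1)]
    replay.append((r0, l0))
    cfg_kwargs = {k: v for k, v in vars(config).items()}
    cfg_kwargs["direction"] = "refold"
    cfg = SimConfig(**cfg_kwargs)
    return run_simulation(
        mesh, mat, cfg,
        pinned=unfold.meta.get("pinned"),
        replay=replay,
        initial_positions=unfold.snapshots[-1],
        initial_rest=(unfold.meta["final_Dm"], None),
    )
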