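# Methods

## Model

The simulator treats cortical folding as a quasi-static, approximately
reversible mechanical process.  A two-tissue tetrahedral solid (gray shell
over white core) carries a neo-Hookean energy per tetrahedron,

    Ψ_Neo = (λ/2)(det F − 1)² + (μ/2)(tr(FᵀF) − 3) = Ψ_H + Ψ_D,

expressed as two XPBD constraints per tet:

* hydrostatic `C_H = V(x)/V₀ − 1`, compliance `α_H = 1/(λ V₀)`.  `V₀` is
  the *original* rest volume and is never updated, so volume memory
  survives viscoelastic relaxation;
* deviatoric `C_D = ‖F‖_F = √tr(FᵀF)`, compliance `α_D = 1/(μ V₀)`, with
  `F = D_s D_m⁻¹` computed against the (possibly relaxing) rest-edge
  matrix `D_m`.

The deviatoric constraint is implemented without a rest offset, exactly as
the energy above prescribes.  A consequence is that the stress-free state
carries a tiny compliance-weighted shrink (≈0.1% linear at λ/μ ≈ 24);
the XPBD fixed point then coincides with the true minimizer of `Ψ_Neo`,
which is what the single-tetrahedron equilibrium check verifies against a
derivative-free minimizer (agreement ≈ 1e-7 relative after annealing, see
below).

Folding is driven in reverse by two scheduled surface families on the
outer (cortical) surface only: per-face area constraints whose rest areas
decay geometrically (`R ← R·(1 − r_A·dt)`), and per-face-pair smoothing
constraints (`C = ½‖(a+b) − (s₀+s₁)‖ − L`, `L ← L·(1 − r_L·dt)`) that bias
the solve toward globally area-minimizing, smooth surfaces — the local
surrogate for the isoperimetric tendency of a shrinking closed surface.

**Schedule floors.** Rest targets are clamped from below at their
flat-envelope values: each face's area projected onto the slab base plane,
and the in-plane component of each smoothing offset.  Without the floors
the drive keeps contracting past the flat state and the surface buckles
into compressive wrinkles (the gyrification index stalls near 1.15);
with them the reverse growth stops at the unfolded amount and GI reaches
the stop target monotonically.  For closed surfaces (sphere runs) the
floors are zero and the run is stopped by an isoperimetric-excess target
instead.

**Reversibility.** The per-step target arrays are recorded during
unfolding; refolding replays them in reverse order (ending at the original
folded-state targets) and then anneals to equilibrium.  With pure
elasticity (`visco_factor = 0`) the tet rest poses still encode the folded
configuration, so the replayed targets and the elastic memory agree on the
end state: on the study slab the refolded surface correlates with the
original height field at 0.99996 with 0.025 mm RMS node error (2.5% of
the fold amplitude).

**Viscoelasticity.** `D_m ← (1−κ) D_m + κ D_s` once per outer step with
`κ = 1 − exp(−β·dt)`; exponential blending makes half steps compose
exactly.  β = 0 by default: the round-trip experiments need full elastic
memory, and the slab unfolds to its GI target without relaxation.  β > 0
demonstrates stress relaxation on the 1 mm³ cube and lets deeply folded
inputs unfold further, at the cost of refold fidelity.

## Solver

Integration is quasi-static with infinite viscous damping: there is no
inertial predictor and no velocity state.  Each outer step (schedule
clock `dt = 1`) runs `substeps` solver *ministeps*; a ministep resets all
Lagrange multipliers and performs one Gauss–Seidel sweep with
`α̃ = α/dt_sub²`.  Within a tet the hydrostatic/deviatoric pair is applied
as a block (both evaluated at the same positions) — sequential projection
biases the fixed point away from the elastic equilibrium by a zig-zag
term.

`dt_sub` must resolve the elastic timescale `h/√(E/ρ)` of the mesh
(≈ 2.6e-4 s for 0.35 mm elements at brain stiffness); the default is
1e-4 s.  In this regime the deviatoric family acts as a stable damped
gradient flow on the elastic energy while near-incompressibility and the
area drive remain stiff.  Larger ministeps make the deviatoric constraint
effectively hard, which is unstable (it alone drives `tr(FᵀF)` toward
zero).  Equilibrium solves anneal `dt_sub` downward (bias shrinks
quadratically with `dt_sub`).

Internal units are mm / mg / s (1 Pa = 1e3 mg·mm⁻¹·s⁻²; node masses in kg
are scaled by 1e6).  All kernels are sequential numba code: runs are
bit-reproducible, and the only randomness in the package is fiber seeding
and Bézier jitter, both driven by explicit seeds.

Calibrated defaults (chosen once on the slab round trip and used as the
package's study conditions): `dt_sub = 1e-4`, `substeps = 100`,
`n_steps = 150` with GI stop 1.05, `rate_area = 0.03`,
`rate_smooth = 0.06`, compliance scales (softness multipliers)
`scale_h = 1`, `scale_d = 50`, `scale_area = scale_smooth = 1e-3`.
The refold settling plan anneals `dt_sub` over (4e-4)×4000, (2e-4)×2000,
(1e-4)×2000 ministeps.

## Synthetic geometries

All generators build a structured lattice split into 6 tets per cell
(Kuhn triangulation — conforming without checkerboard parity,
bit-reproducible connectivity):

* **folded slab** — top surface `z = depth + A sin(2πx/W)`, extruded in y
  (2.5-D), sheared lattice columns, gray within `gm_thickness` of the top.
  Round-trip slab: 12×3×3 mm, A = 1, W = 4 (A/W = 0.25), h = 0.35
  (~16.5k tets), base nodes pinned (a stand-in for deep tissue and a fixed
  frame for round-trip error).  Fiber-study slab: A = 1.4, W = 3
  (A/W ≈ 0.47), h = 0.3 (~24k tets), free base — the deeper sulci produce
  enough wall bending to show the gyral-vs-sulcal alignment asymmetry.
* **unit cube** — all-white, volume exactly `edge³`; the mass-lumping and
  viscoelasticity calibration body.
* **lobed sphere** — cube lattice mapped radially onto the ball with a
  smooth sectoral perturbation `cos(n·azimuth)(1 − z̄²)` ramped as ρ²; used
  for the isoperimetric relaxation test (19% initial excess of
  `area³/vol²` over `36π`, relaxed below 4% monotonically).

These bodies emulate fold geometry, two-tissue structure and scale; they
do **not** mimic real cortical statistics (curvature spectra, sulcal depth
distributions, interlocked gyri), so passing results demonstrate the
machinery and its mechanics, not anatomical fidelity on brain data.

## Fiber pipeline and ground truth

The deformation map uses the time-reversed unfolding trajectory (t = 0
unfolded, t = 1 folded), normalized so interval durations are proportional
to mean per-node displacement (the max-displacement statistic is available
as an option).  Point location is exact barycentric evaluation with a
centroid k-d-tree candidate search and brute-force fallback; boundary
tolerance 1e-6 in barycentric units.

Radial fibers are seeded uniformly by area on the unfolded outer surface
and integrated through the voxelized inward-normal field (0.325 mm voxels,
matching the strain-map resolution used on real data; 30
smoothing/fill passes; 0.2 mm steps; 2 mm max length).  Smoothing passes
both average over the 6-neighbourhood and extend the field one voxel into
the interior, so the field fills the integration domain.

The analytic reference for the folded slab is the inward surface normal
propagated along straight lines.  Past the caustic of the normal
congruence (focal distance `1/(A k²)`, above 0.41 mm here — shallower than
the slab) the straight-line field is multi-valued under crests; the
implementation takes the *own-column branch* — the ray of the laterally
nearest surface point — which matches what a volume-preserving advection
of the radial scaffold actually does (flank fibers do not cross under the
crest).  The smallest-travel-distance branch would label deep under-crest
voxels with flank normals and does not correspond to any material fiber.

Per-voxel peaks: principal eigenvector of the length-weighted segment
orientation tensor, ambiguity flagged when the top two eigenvalues tie
within 1e-6 relative.  Alignment: `C(v) = |a·b|` within a white-matter
mask (below the gray shell, domain margins excluded).  Fold-phase classes
use `s = sin(2πx/W)`: crown `s > 0.5`, fundus `s < −0.5`, banks between;
"gyral"/"sulcal" means `s > 0` / `s < 0`.  Strain: per-fiber length ratio
minus one, averaged per folded-space voxel over the fibers crossing it
(averaging per-fiber ratios, not pooled lengths — the alternative would
weight long fibers more).

Measured on the fiber-study slab (seed 0): overall |cos| 0.82, crowns
0.91, gyral 0.83 vs sulcal 0.79 — gyri align better than sulci because
the advected scaffold cannot follow the sharp normal rotation of sulcal
walls, the synthetic counterpart of radial fibers failing to capture
sulcal bending in real data.

## Known limitations

* **Strain localization differs from envelope-preserving folding.**  In
  this slab geometry the folded surface is `depth + A sin kx` over a flat
  base, so crest columns are `(depth+A)/depth` taller than the unfolded
  state and their fibers carry the largest elongation (+0.24 vs +0.17 on
  sulcal walls).  Real folding is closer to envelope-preserving: sulci
  invaginate while crowns keep their radius, concentrating elongation in
  the U-shaped arcs along sulcal banks.  A mesh-refinement study (h = 0.4
  → 0.25) confirms crest dominance is the converged behaviour of this
  geometry, not a discretization effect.  Reproducing bank-dominant strain
  would require a generator whose folds grow inward under a fixed outer
  envelope.
* No self-collision handling: fold separation relies on valid input
  meshing.  Contact is an extension point.
* Isometric whole-body growth is ignored (it does not contribute to the
  deformation map); no multi-layer laminae, no stress-dependent fiber
  growth.
* The CLI's imported-mesh path treats the whole boundary as active
  cortical surface unless the mesh carries region metadata.

## Problem sizes

The shipped experiments use ~16.5k tets (round trip, ~35 s), ~24k tets
(fiber study, ~60 s including fibers), 6k tets (sphere, ~3 s) and 750
tets (cube); the test suite and the acceptance script each complete in a
few minutes on one CPU.  All sizes are configuration, not code limits —
`SlabSpec.h` and `SimConfig` scale the same pipeline up.
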