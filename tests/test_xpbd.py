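"""XPBD constraint projections, energy primitives, and quasi-static stepping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from refold.geometry import SlabSpec, make_folded_slab, slab_base_nodes
from refold.mesh import compute_node_masses
from refold.xpbd import (AreaConstraint, MaterialParams, SimConfig, SimState,
                         SmoothingConstraint, TetConstraint,
                         deformation_gradient, neo_hookean_energy,
                         project_area_constraint,
                         project_smoothing_constraint, project_tet_constraint,
                         quasi_static_step, run_simulation,
                         update_viscoelastic_rest)


def _random_tet(rng):
    P = rng.normal(size=(4, 3))
    Dm = np.column_stack([P[1] - P[0], P[2] - P[0], P[3] - P[0]])
    if np.linalg.det(Dm) < 0:
        P[[1, 2]] = P[[2, 1]]
        Dm = np.column_stack([P[1] - P[0], P[2] - P[0], P[3] - P[0]])
    return P, Dm


class TestDeformationGradient:
    def test_identity_at_rest(self, rng):
        P, Dm = _random_tet(rng)
        assert np.allclose(deformation_gradient(P, Dm), np.eye(3), atol=1e-12)

    def test_uniform_scale(self, rng):
        P, Dm = _random_tet(rng)
        Q = (P - P[0]) * 1.7 + P[0]
        assert np.allclose(deformation_gradient(Q, Dm), 1.7 * np.eye(3),
                           atol=1e-12)

    def test_recovers_linear_part_of_affine_map(self, rng):
        P, Dm = _random_tet(rng)
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        assert np.allclose(deformation_gradient(P @ A.T + b, Dm), A, atol=1e-10)

    def test_singular_rest_matrix_rejected(self):
        with pytest.raises(ValueError):
            deformation_gradient(np.zeros((4, 3)), np.zeros((3, 3)))


class TestNeoHookeanEnergy:
    def test_zero_at_identity(self):
        assert neo_hookean_energy(np.eye(3), 2.0, 3.0) == (0.0, 0.0)

    def test_hydrostatic_arithmetic(self):
        # F = 2I: (lam/2)(det-1)^2 = (2/2)(8-1)^2 = 49
        psi_h, psi_d = neo_hookean_energy(2.0 * np.eye(3), 2.0, 0.0)
        assert psi_h == pytest.approx(49.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_rotations_carry_no_energy(self, seed):
        R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        psi_h, psi_d = neo_hookean_energy(R, 2.0, 3.0)
        assert abs(psi_h) < 1e-9 and abs(psi_d) < 1e-9


class TestTetProjection:
    def test_hydrostatic_at_rest_is_noop(self, rng):
        P, Dm = _random_tet(rng)
        pos = P.copy()
        c = TetConstraint(np.arange(4), Dm, np.linalg.det(Dm) / 6, 1e4, 1e3)
        project_tet_constraint(pos, np.ones(4), c, 1e-4, 1e-4, 0.01,
                               deviatoric=False)
        assert np.allclose(pos, P, atol=1e-12)

    def test_scaled_tet_recovers_unit_volume_with_zero_compliance(self, rng):
        P, Dm = _random_tet(rng)
        pos = (P - P.mean(0)) * 1.5 + P.mean(0)
        c = TetConstraint(np.arange(4), Dm, np.linalg.det(Dm) / 6, 1e4, 1e3)
        lam = (0.0, 0.0)
        for _ in range(400):
            lam = project_tet_constraint(pos, np.ones(4), c, 0.0, 0.0, 1.0,
                                         lam, deviatoric=False)
        F = deformation_gradient(pos, Dm)
        assert np.linalg.det(F) == pytest.approx(1.0, abs=1e-6)

    def test_pinned_vertices_do_not_move(self, rng):
        P, Dm = _random_tet(rng)
        pos = (P - P.mean(0)) * 1.3 + P.mean(0)
        before = pos.copy()
        invm = np.array([0.0, 0.0, 0.0, 1.0])
        c = TetConstraint(np.arange(4), Dm, np.linalg.det(Dm) / 6, 1e4, 1e3)
        project_tet_constraint(pos, invm, c, 1e-6, 1e-6, 0.01)
        assert np.allclose(pos[:3], before[:3])
        assert not np.allclose(pos[3], before[3])


class TestAreaProjection:
    tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                    [0, 0, 1.0]])

    def _area(self, pos):
        return 0.5 * np.linalg.norm(np.cross(pos[1] - pos[0], pos[2] - pos[0]))

    def test_satisfied_constraint_is_stationary(self):
        pos = self.tri.copy()
        c = AreaConstraint(np.array([0, 1, 2]), self._area(pos))
        project_area_constraint(pos, np.ones(4), c, 0.0, 1.0)
        assert (pos == self.tri).all()

    def test_equilateral_shrinks_symmetrically_to_half_area(self):
        pos = self.tri.copy()
        target = self._area(pos) / 2.0
        c = AreaConstraint(np.array([0, 1, 2]), target)
        lam = 0.0
        for _ in range(300):
            lam = project_area_constraint(pos, np.ones(4), c, 0.0, 1.0, lam)
        assert self._area(pos) == pytest.approx(target, rel=1e-9)
        # symmetric shrink: centroid fixed, similar shape
        assert np.allclose(pos[:3].mean(0), self.tri[:3].mean(0), atol=1e-9)
        e0 = np.linalg.norm(pos[1] - pos[0])
        e1 = np.linalg.norm(pos[2] - pos[1])
        assert e0 == pytest.approx(e1, rel=1e-6)

    def test_pinned_vertices_leave_only_free_vertex_moving(self):
        pos = self.tri.copy()
        invm = np.array([0.0, 0.0, 1.0, 0.0])
        c = AreaConstraint(np.array([0, 1, 2]), self._area(pos) / 2)
        project_area_constraint(pos, invm, c, 0.0, 1.0)
        assert (pos[[0, 1, 3]] == self.tri[[0, 1, 3]]).all()
        assert not np.allclose(pos[2], self.tri[2])


class TestSmoothingProjection:
    # roof quad: shared edge s0-s1 raised, opposite nodes a, b lower
    roof = np.array([[0, 0, 1.0], [0, 1, 1.0], [1, 0.5, 0.0], [-1, 0.5, 0.0]])

    def _half_dist(self, pos):
        return 0.5 * np.linalg.norm((pos[2] + pos[3]) - (pos[0] + pos[1]))

    def test_rest_distance_is_stationary(self):
        pos = self.roof.copy()
        c = SmoothingConstraint(np.array([0, 1, 2, 3]), self._half_dist(pos))
        project_smoothing_constraint(pos, np.ones(4), c, 0.0, 1.0)
        assert (pos == self.roof).all()

    def test_shrinking_rest_distance_flattens_monotonically(self):
        pos = self.roof.copy()
        c = SmoothingConstraint(np.array([0, 1, 2, 3]), 0.0)
        lam, prev = 0.0, self._half_dist(pos)
        for _ in range(50):
            lam = project_smoothing_constraint(pos, np.ones(4), c, 0.0, 1.0, lam)
            cur = self._half_dist(pos)
            assert cur <= prev + 1e-12
            prev = cur
        assert prev < 1e-6

    def test_translation_invariant_displacements(self):
        pos_a = self.roof.copy()
        pos_b = self.roof + np.array([5.0, -3.0, 2.0])
        c = SmoothingConstraint(np.array([0, 1, 2, 3]), 0.1)
        project_smoothing_constraint(pos_a, np.ones(4), c, 0.0, 1.0)
        project_smoothing_constraint(pos_b, np.ones(4), c, 0.0, 1.0)
        assert np.allclose(pos_a - self.roof,
                           pos_b - (self.roof + np.array([5.0, -3.0, 2.0])),
                           atol=1e-12)


class TestViscoelasticRest:
    def _state(self, small_slab):
        cfg = SimConfig(rate_area=0.0, rate_smooth=0.0)
        return SimState(small_slab, MaterialParams(), cfg)

    def test_beta_zero_leaves_rest_matrices(self, small_slab):
        st_ = self._state(small_slab)
        Dm0 = st_.Dm.copy()
        update_viscoelastic_rest(st_.pos, st_.tets, st_.Dm, st_.Bm, 0.0, 1.0)
        assert (st_.Dm == Dm0).all()

    def test_full_relaxation_makes_current_pose_the_rest_pose(self, small_slab, rng):
        st_ = self._state(small_slab)
        st_.pos += 0.05 * rng.normal(size=st_.pos.shape)
        # kappa = 1 - exp(-beta dt) ~ 1 for large beta
        update_viscoelastic_rest(st_.pos, st_.tets, st_.Dm, st_.Bm, 1e9, 1.0)
        t = st_.tets[10]
        Ds = np.column_stack([st_.pos[t[1]] - st_.pos[t[0]],
                              st_.pos[t[2]] - st_.pos[t[0]],
                              st_.pos[t[3]] - st_.pos[t[0]]])
        F = Ds @ st_.Bm[10]
        assert np.allclose(F, np.eye(3), atol=1e-9)

    def test_two_half_steps_compose_to_one_full_step(self, small_slab):
        a = self._state(small_slab)
        b = self._state(small_slab)
        beta, dt = 0.7, 1.0
        update_viscoelastic_rest(a.pos, a.tets, a.Dm, a.Bm, beta, dt)
        update_viscoelastic_rest(b.pos, b.tets, b.Dm, b.Bm, beta, dt / 2)
        update_viscoelastic_rest(b.pos, b.tets, b.Dm, b.Bm, beta, dt / 2)
        assert np.allclose(a.Dm, b.Dm, atol=1e-12)

    def test_rest_volume_is_never_updated(self, small_slab, rng):
        st_ = self._state(small_slab)
        rv0 = st_.rest_vol.copy()
        st_.pos *= 1.1
        update_viscoelastic_rest(st_.pos, st_.tets, st_.Dm, st_.Bm, 10.0, 1.0)
        assert (st_.rest_vol == rv0).all()


class TestQuasiStaticStep:
    def test_satisfied_surface_constraints_are_exactly_stationary(self, small_slab):
        # frozen schedules, tet family disabled: area and smoothing targets
        # equal their current values, so every projection is a strict no-op
        cfg = SimConfig(rate_area=0.0, rate_smooth=0.0, enable_tet=False,
                        substeps=20)
        state = SimState(small_slab, MaterialParams(), cfg,
                         pinned=slab_base_nodes(small_slab))
        before = state.pos.copy()
        for _ in range(3):
            quasi_static_step(state)
        assert (state.pos == before).all()

    def test_unfold_surface_area_monotonically_non_increasing(self, small_slab):
        cfg = SimConfig(n_steps=10, substeps=60, snapshot_every=2)
        state = SimState(small_slab, MaterialParams(), cfg,
                         pinned=slab_base_nodes(small_slab))
        areas = [small_slab.face_areas(state.pos, region=1).sum()]
        for _ in range(10):
            quasi_static_step(state)
            areas.append(small_slab.face_areas(state.pos, region=1).sum())
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_more_substeps_do_not_worsen_residuals(self, small_slab):
        res = {}
        for substeps in (40, 80):
            cfg = SimConfig(substeps=substeps, rate_area=0.02, rate_smooth=0.04)
            state = SimState(small_slab, MaterialParams(), cfg,
                             pinned=slab_base_nodes(small_slab))
            for _ in range(3):
                r = quasi_static_step(state)
            res[substeps] = max(r["area"], r["smoothing"])
        assert res[80] <= res[40] + 1e-9


class TestRunSimulation:
    def test_already_unfolded_slab_stops_immediately(self):
        spec = SlabSpec(extent_x=6.0, extent_y=2.0, depth=2.0,
                        fold_amplitude=0.0, fold_wavelength=4.0,
                        gm_thickness=0.5, h=0.4)
        mesh = compute_node_masses(make_folded_slab(spec))
        cfg = SimConfig(stop_gi=1.0, n_steps=50)
        traj = run_simulation(mesh, MaterialParams(), cfg,
                              pinned=slab_base_nodes(mesh))
        assert traj.n_snapshots == 1
        assert traj.meta["stopped_at_gi_target"]

    def test_unfold_is_bit_deterministic(self, small_slab):
        cfg = SimConfig(n_steps=4, substeps=30)
        mat = MaterialParams()
        pin = slab_base_nodes(small_slab)
        a = run_simulation(small_slab, mat, cfg, pinned=pin)
        b = run_simulation(small_slab, mat, cfg, pinned=pin)
        assert (a.snapshots == b.snapshots).all()

    def test_material_invariants(self):
        with pytest.raises(ValueError):
            MaterialParams(nu=0.6)
        with pytest.raises(ValueError):
            MaterialParams(E_white=-1.0)
        lam, mu = MaterialParams().lame(1895.0)
        assert lam > 0 and mu > 0
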