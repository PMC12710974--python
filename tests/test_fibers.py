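"""Orientation fields, radial fiber generation, Bezier bundles, peaks."""

import numpy as np
import pytest

from refold.deformation import DeformationMap, Trajectory, normalize_time
from refold.fibers import (BundleSpec, FiberSet, advect_fibers, bezier_bundle,
                           extract_primary_peaks, generate_radial_fibers,
                           inward_normal_field)
from refold.geometry import (SlabSpec, make_folded_slab, make_unit_cube,
                             make_wavy_sphere)
from refold.grid import VoxelGrid


@pytest.fixture(scope="module")
def flat_slab():
    from refold.mesh import compute_node_masses
    spec = SlabSpec(extent_x=6.0, extent_y=3.0, depth=3.0,
                    fold_amplitude=0.0, fold_wavelength=4.0,
                    gm_thickness=0.8, h=0.4)
    return compute_node_masses(make_folded_slab(spec))


class TestInwardNormalField:
    def test_flat_slab_field_is_uniformly_downward(self, flat_slab):
        field = inward_normal_field(flat_slab, voxel_size=0.4, smooth_iters=4)
        vecs = field.vectors[field.mask]
        assert np.allclose(vecs, [0.0, 0.0, -1.0], atol=1e-6)

    def test_sphere_field_points_to_center(self):
        mesh = make_wavy_sphere(5.0, 4, 0.0, 0.8)
        field = inward_normal_field(mesh, voxel_size=0.5, smooth_iters=1)
        centers = field.grid.centers()
        r = np.linalg.norm(centers, axis=-1)
        shell = field.mask & (np.abs(r - 5.0) < 0.5)
        vec = field.vectors[shell]
        radial = -centers[shell] / r[shell][..., None]
        cos = np.einsum("kd,kd->k", vec, radial)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).mean() < 5.0

    def test_smoothing_does_not_increase_angular_variation(self):
        mesh = make_folded_slab(SlabSpec(extent_x=8.0, extent_y=2.0,
                                         fold_amplitude=1.0, fold_wavelength=4.0,
                                         depth=3.0, gm_thickness=0.75, h=0.4))
        def roughness(field):
            v, m = field.vectors, field.mask
            worst = 0.0
            for ax in range(3):
                a = np.swapaxes(v, 0, ax)[:-1]
                b = np.swapaxes(v, 0, ax)[1:]
                ma = np.swapaxes(m, 0, ax)[:-1] & np.swapaxes(m, 0, ax)[1:]
                dots = np.abs(np.einsum("...d,...d->...", a, b))[ma]
                if len(dots):
                    worst = max(worst, float(np.mean(1.0 - dots)))
            return worst
        raw = inward_normal_field(mesh, voxel_size=0.4, smooth_iters=0)
        smooth = inward_normal_field(mesh, voxel_size=0.4, smooth_iters=3)
        assert roughness(smooth) <= roughness(raw) + 1e-12

    def test_invalid_voxel_size_rejected(self, flat_slab):
        with pytest.raises(ValueError):
            inward_normal_field(flat_slab, voxel_size=0.0)


@pytest.fixture(scope="module")
def flow(flat_slab):
    return inward_normal_field(flat_slab, voxel_size=0.3, smooth_iters=12)


class TestRadialFibers:
    def test_flat_slab_fibers_are_vertical_and_reach_max_len(self, flat_slab, flow):
        fibers = generate_radial_fibers(flat_slab, flow, step=0.2, max_len=2.0,
                                        n_seeds=50, seed=0)
        for f in fibers:
            dx = np.abs(np.diff(f[:, :2], axis=0)).max()
            assert dx < 1e-6  # strictly vertical
            depth = f[0, 2] - f[-1, 2]
            assert depth == pytest.approx(2.0, abs=0.21)  # within one step

    def test_first_segment_follows_local_inward_normal(self, flat_slab, flow):
        fibers = generate_radial_fibers(flat_slab, flow, step=0.2, max_len=1.0,
                                        n_seeds=80, seed=3)
        for f in fibers:
            d = f[1] - f[0]
            d = d / np.linalg.norm(d)
            assert d @ np.array([0.0, 0.0, -1.0]) >= 0.99

    def test_seeded_determinism(self, flat_slab, flow):
        a = generate_radial_fibers(flat_slab, flow, 0.2, 1.5, 40, seed=9)
        b = generate_radial_fibers(flat_slab, flow, 0.2, 1.5, 40, seed=9)
        c = generate_radial_fibers(flat_slab, flow, 0.2, 1.5, 40, seed=10)
        assert all((x == y).all() for x, y in zip(a.fibers, b.fibers))
        assert not np.allclose(a.meta["seed_points"], c.meta["seed_points"])

    def test_fibers_stay_inside_bounding_volume(self, flat_slab, flow):
        fibers = generate_radial_fibers(flat_slab, flow, 0.2, 2.5, 100, seed=1)
        lo = flat_slab.nodes.min(0) - 0.5
        hi = flat_slab.nodes.max(0) + 0.5
        pts = np.concatenate(list(fibers))
        assert (pts >= lo).all() and (pts <= hi).all()


class TestAdvectFibers:
    @pytest.fixture()
    def translation_map(self, small_slab):
        c = np.array([2.0, 1.0, -0.5])
        snaps = np.array([small_slab.nodes + t * c for t in np.linspace(0, 1, 4)])
        traj = Trajectory(mesh=small_slab, snapshots=snaps,
                          raw_times=np.arange(4.0))
        return DeformationMap(normalize_time(traj)), c

    def _interior_fibers(self, small_slab, rng, n=20):
        lo = small_slab.nodes.min(0) + 0.4
        hi = small_slab.nodes.max(0) * [1, 1, 0.4]
        hi[0] -= 0.7
        hi[1] -= 0.7
        starts = rng.uniform(lo, hi, size=(n, 3))
        return FiberSet([np.linspace(s, s + [0.2, 0.1, 0.3], 5)
                         for s in starts])

    def test_t0_is_identity(self, small_slab, translation_map, rng):
        dmap, _ = translation_map
        fibers = self._interior_fibers(small_slab, rng)
        out = advect_fibers(dmap, fibers, 0.0)
        for a, b in zip(fibers, out):
            assert np.abs(a - b).max() < 1e-9

    def test_rigid_translation_preserves_lengths(self, small_slab, translation_map, rng):
        dmap, c = translation_map
        fibers = self._interior_fibers(small_slab, rng)
        out = advect_fibers(dmap, fibers, 1.0)
        for a, b in zip(fibers, out):
            assert np.allclose(b, a + c, atol=1e-9)
        assert np.allclose(fibers.lengths(), out.lengths(), atol=1e-9)

    def test_unlocatable_fibers_are_dropped_and_counted(self, small_slab, translation_map):
        dmap, _ = translation_map
        inside = small_slab.nodes[small_slab.tets[5]].mean(axis=0)
        fibers = FiberSet([np.linspace(inside, inside + [0.1, 0, 0], 4),
                           np.linspace([500.0, 0, 0], [501.0, 0, 0], 4)])
        out = advect_fibers(dmap, fibers, 0.5, drop_unlocatable=True)
        assert len(out) == 1
        assert out.meta["dropped"] == 1
        assert out.ids.tolist() == [0]


class TestBezierBundle:
    def test_zero_jitter_single_endpoints_degenerate_to_segment(self):
        spec = BundleSpec(endpoints_a=[[0.0, 0.0, 0.0]],
                          endpoints_b=[[4.0, 0.0, 0.0]],
                          n_fibers=5, midpoint_sigma=0.0, seed=0,
                          n_points=33)
        bundle = bezier_bundle(spec)
        assert len(bundle) == 5
        for f in bundle:
            assert np.allclose(f[0], [0, 0, 0]) and np.allclose(f[-1], [4, 0, 0])
            # curve midpoint = endpoint midpoint for a midpoint control point
            assert np.allclose(f[len(f) // 2], [2, 0, 0], atol=1e-9)
        lengths = bundle.lengths()
        assert np.allclose(lengths, 4.0, rtol=1e-9)
        assert all((bundle[0] == f).all() for f in bundle)

    def test_seeded_determinism_and_jitter(self):
        spec = dict(endpoints_a=[[0.0, 0, 0], [0, 1.0, 0]],
                    endpoints_b=[[5.0, 0, 0], [5.0, 1, 0]],
                    n_fibers=20, midpoint_sigma=0.5)
        a = bezier_bundle(BundleSpec(seed=4, **spec))
        b = bezier_bundle(BundleSpec(seed=4, **spec))
        c = bezier_bundle(BundleSpec(seed=5, **spec))
        assert all((x == y).all() for x, y in zip(a, b))
        assert any(not np.allclose(x, y) for x, y in zip(a, c))

    def test_curves_interpolate_endpoints_exactly(self):
        spec = BundleSpec(endpoints_a=[[0.0, 1, 2], [3.0, 4, 5]],
                          endpoints_b=[[9.0, 8, 7]],
                          n_fibers=10, midpoint_sigma=2.0, seed=11)
        ea = np.asarray(spec.endpoints_a)
        for f in bezier_bundle(spec):
            assert any(np.allclose(f[0], e) for e in ea)
            assert np.allclose(f[-1], [9.0, 8, 7])

    def test_empty_endpoint_sets_rejected(self):
        with pytest.raises(ValueError):
            BundleSpec(endpoints_a=np.zeros((0, 3)),
                       endpoints_b=[[1.0, 0, 0]])


class TestPrimaryPeaks:
    grid = VoxelGrid((0.0, 0.0, 0.0), 1.0, (4, 4, 4))

    def test_parallel_segments_give_their_direction(self):
        fibers = FiberSet([np.array([[0.1, 1.5, 1.5], [3.9, 1.5, 1.5]])
                           for _ in range(3)])
        field = extract_primary_peaks(fibers, self.grid)
        vecs = field.vectors[field.mask]
        assert np.allclose(np.abs(vecs @ [1, 0, 0]), 1.0, atol=1e-9)

    def test_balanced_orthogonal_populations_are_flagged_ambiguous(self):
        fx = np.array([[1.0, 1.5, 1.5], [2.0, 1.5, 1.5]])
        fy = np.array([[1.5, 1.0, 1.5], [1.5, 2.0, 1.5]])
        fibers = FiberSet([fx, fy])
        field = extract_primary_peaks(fibers, self.grid)
        assert field.n_ambiguous >= 1
        assert not field.mask[1, 1, 1]

    def test_dominant_direction_of_a_mixture(self, rng):
        # 80% along +x, 20% along +y, all in one voxel
        segs = []
        for _ in range(40):
            p = np.array([1.2, 1.5, 1.5]) + rng.normal(scale=0.05, size=3)
            segs.append(np.array([p, p + [0.6, 0, 0]]))
        for _ in range(10):
            p = np.array([1.5, 1.2, 1.5]) + rng.normal(scale=0.05, size=3)
            segs.append(np.array([p, p + [0, 0.6, 0]]))
        field = extract_primary_peaks(FiberSet(segs), self.grid)
        v = field.vectors[1, 1, 1]
        angle = np.degrees(np.arccos(min(1.0, abs(v[0]))))
        assert angle < 10.0

    def test_antipodal_symmetry(self, rng):
        pts = rng.uniform(0.5, 3.5, size=(30, 3))
        dirs = rng.normal(size=(30, 3))
        fibers = [np.array([p, p + 0.4 * d / np.linalg.norm(d)])
                  for p, d in zip(pts, dirs)]
        flipped = [f[::-1].copy() for f in fibers]
        a = extract_primary_peaks(FiberSet(fibers), self.grid)
        b = extract_primary_peaks(FiberSet(flipped), self.grid)
        assert (a.mask == b.mask).all()
        dots = np.abs(np.einsum("...d,...d->...", a.vectors, b.vectors)[a.mask])
        assert np.allclose(dots, 1.0, atol=1e-9)

    def test_empty_fiber_set_rejected(self):
        with pytest.raises(ValueError):
            extract_primary_peaks(FiberSet([]), self.grid)


def test_fiberset_invariants():
    with pytest.raises(ValueError):
        FiberSet([np.zeros((1, 3))])   # too short
    fs = FiberSet([np.zeros((2, 3)), np.ones((3, 3))])
    assert len(fs) == 2 and fs.ids.tolist() == [0, 1]
    sub = fs.subset([1])
    assert len(sub) == 1 and sub.ids.tolist() == [1]
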