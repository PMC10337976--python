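"""Direction field, trajectories, flatmap-stack construction, isotropy."""

import numpy as np
import pytest

from cortexstack import flatstack
from cortexstack.flatstack import (FlatmapStack, build_flatstack,
                                   compute_direction_field, flat_projection,
                                   isotropy_validate, map_points_from_stack,
                                   map_to_stack, trace_trajectory,
                                   trace_trajectories)
from cortexstack.volgeom import VoxelGrid


def _interior_points(truth):
    cx = truth.cortex
    idx = np.argwhere(cx.interior.data > 0)
    return cx.grid.voxel_to_world(idx)


class TestDirectionField:
    def test_slab_field_is_exactly_the_normal(self, slab, slab_field):
        v = slab_field.vectors[slab.cortex.interior.data > 0]
        ang = np.degrees(np.arccos(np.clip(v[:, 2], -1, 1)))
        assert np.median(ang) < 0.5
        assert ang.max() < 5.0

    @pytest.mark.parametrize("method", ["potential", "vector"])
    def test_shell_field_tracks_the_radial_oracle(self, small_shell, method):
        field = compute_direction_field(small_shell.cortex, method=method)
        w = _interior_points(small_shell)
        radial = w / np.linalg.norm(w, axis=1, keepdims=True)
        v = field.vectors[small_shell.cortex.interior.data > 0]
        ang = np.degrees(np.arccos(np.clip(np.sum(v * radial, axis=1), -1, 1)))
        assert np.median(ang) < 5.0

    def test_field_is_unit_length_on_domain(self, small_field, small_shell):
        norms = np.linalg.norm(
            small_field.vectors[small_shell.cortex.domain], axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_unreachable_interior_is_an_error(self, small_shell):
        from cortexstack.flatstack import CortexModel
        from cortexstack.volgeom import Mask
        cx = small_shell.cortex
        # island far away from the boundaries
        interior = cx.interior.data.copy()
        interior[0:3, 0:3, 0:3] = 1
        bad = CortexModel(Mask(interior, cx.grid.spacing, cx.grid.origin),
                          cx.inner_boundary, cx.outer_boundary,
                          cx.mid_surface)
        with pytest.raises(ValueError, match="unreachable"):
            compute_direction_field(bad)

    def test_vector_method_non_convergence_raises(self, small_shell):
        with pytest.raises(RuntimeError, match="converge"):
            compute_direction_field(small_shell.cortex, method="vector",
                                    tol=1e-9, max_iter=3)


class TestTrajectories:
    def test_slab_trajectory_is_straight_with_slab_thickness(self, slab,
                                                             slab_field):
        # start on the inner (bottom) interface below the slab center
        start = np.array([0.0, 0.0, -300.0])
        traj = trace_trajectory(start, slab_field, slab.cortex, step=25.0)
        assert traj.success
        assert abs(traj.total_length - 600.0) <= 50.0
        # straightness: lateral drift below one voxel
        assert np.abs(traj.points[:, :2] - start[:2]).max() < 50.0

    def test_shell_trajectory_length_close_to_thickness(self, small_shell,
                                                        small_field):
        starts = flatstack._seed_points(small_shell.cortex, small_field, 1)
        paths, n_points, success = trace_trajectories(
            starts, small_field, small_shell.cortex, step=25.0)
        lengths = (n_points[success] - 1) * 25.0
        assert abs(np.median(lengths) - 500.0) / 500.0 <= 0.02
        # individual trajectories within raster quantization of the oracle
        assert np.mean(np.abs(lengths - 500.0) <= 50.0) > 0.8

    def test_halving_step_moves_endpoint_less_than_one_voxel(self, small_shell,
                                                             small_field):
        start = small_shell.cortex.grid.voxel_to_world(
            np.argwhere(small_shell.cortex.inner_boundary.data)[40])
        a = trace_trajectory(start, small_field, small_shell.cortex, step=25.0)
        b = trace_trajectory(start, small_field, small_shell.cortex, step=12.5)
        assert a.success and b.success
        assert np.linalg.norm(a.points[-1] - b.points[-1]) < 50.0

    def test_arc_length_strictly_increasing(self, small_shell, small_field):
        start = small_shell.cortex.grid.voxel_to_world(
            np.argwhere(small_shell.cortex.inner_boundary.data)[0])
        traj = trace_trajectory(start, small_field, small_shell.cortex)
        assert np.all(np.diff(traj.arc_length) > 0)

    def test_max_len_flags_failure_without_crash(self, small_shell,
                                                 small_field):
        starts = flatstack._seed_points(small_shell.cortex, small_field, 1)[:5]
        _, _, success = trace_trajectories(starts, small_field,
                                           small_shell.cortex, step=25.0,
                                           max_len=30.0)
        assert not success.any()


class TestBuildFlatstack:
    def test_depth_and_flat_coordinates_recovered(self, small_shell, small_fs):
        w = _interior_points(small_shell)
        uvd = small_fs.from_world[small_shell.cortex.interior.data > 0]
        depth_err = np.abs(uvd[:, 2] - small_shell.depth_fn(w))
        assert np.nanmean(depth_err) < 0.05
        uv_err = np.linalg.norm(uvd[:, :2] - small_shell.flat_fn(w), axis=1)
        # < 2 stack voxels of the (u, v) grid
        assert np.nanmean(uv_err) * (small_fs.dims[0] - 1) < 2.0

    def test_depth_axis_has_requested_layers(self, small_fs):
        assert small_fs.to_world.shape == (120, 120, 24, 3)
        assert small_fs.dims == (120, 120, 24)

    def test_determinism(self, small_shell, small_field, small_fs):
        again = build_flatstack(small_shell.cortex, small_field,
                                dims=(120, 120, 24))
        assert np.array_equal(again.to_world, small_fs.to_world,
                              equal_nan=True)
        assert np.array_equal(again.from_world, small_fs.from_world,
                              equal_nan=True)

    def test_too_many_failed_trajectories_is_an_error(self, small_shell,
                                                      small_field):
        with pytest.raises(ValueError, match="failed"):
            build_flatstack(small_shell.cortex, small_field,
                            dims=(40, 40, 10), max_failed_frac=0.0)

    def test_save_load_round_trip(self, small_fs, tmp_path):
        small_fs.save(tmp_path / "fs")
        back = FlatmapStack.load(tmp_path / "fs")
        assert back.dims == small_fs.dims
        assert np.allclose(back.to_world, small_fs.to_world, equal_nan=True)
        assert np.allclose(back.from_world, small_fs.from_world,
                           equal_nan=True)


class TestMapping:
    def test_constant_volume_maps_to_constant_stack(self, small_shell,
                                                    small_fs):
        cx = small_shell.cortex
        vol = VoxelGrid(np.where(cx.domain, 7.0, 0.0), cx.grid.spacing,
                        cx.grid.origin)
        stack = map_to_stack(vol, small_fs)
        u, v, d = small_fs.dims
        center = stack.data[u // 4: -u // 4, v // 4: -v // 4, 2:-2]
        # convex interpolation of a constant: essentially 7 everywhere, with
        # at most boundary-support bleed on isolated voxels
        assert np.mean(np.abs(center - 7.0)) < 0.05
        assert np.percentile(np.abs(center - 7.0), 99) < 0.1

    def test_analytic_depth_volume_maps_to_linear_depth_ramp(self, small_shell,
                                                             small_fs):
        cx = small_shell.cortex
        w = cx.grid.voxel_centers()
        depth_vol = VoxelGrid(
            np.where(cx.domain,
                     small_shell.depth_fn(w.reshape(-1, 3)).reshape(w.shape[:3]),
                     0.0), cx.grid.spacing, cx.grid.origin)
        stack = map_to_stack(depth_vol, small_fs)
        u, v, d = small_fs.dims
        expected = np.arange(d) / (d - 1)
        center = stack.data[u // 4: -u // 4, v // 4: -v // 4, 2:-2]
        err = np.abs(center - expected[2:-2])
        # the source volume quantizes depth to 0.1/voxel on this thin shell,
        # so aggregate error is the meaningful check
        assert err.mean() < 0.05
        assert np.percentile(err, 99) < 0.1

    def test_round_trip_stack_point_within_one_voxel(self, small_fs):
        u, v, d = small_fs.dims
        pts = np.array([[u // 2, v // 2, d // 2],
                        [u // 3, 2 * v // 3, d // 3]], dtype=float)
        world = map_points_from_stack(pts, small_fs)
        back = small_fs.world_to_stack(world.points)
        assert np.abs(back - pts).max() <= 1.5

    def test_mid_layer_seeds_land_at_mid_radius(self, small_shell, small_fs):
        u, v, d = small_fs.dims
        layer = (d - 1) // 2
        iu = np.arange(u // 4, 3 * u // 4, 8)
        pts = np.stack([iu, np.full_like(iu, v // 2),
                        np.full_like(iu, layer)], axis=-1).astype(float)
        world = map_points_from_stack(pts, small_fs)
        radii = np.linalg.norm(world.points, axis=1)
        expected = 500.0 + (layer / (d - 1)) * 500.0
        assert abs(np.median(radii) - expected) <= 50.0

    def test_out_of_bounds_stack_point_is_an_error(self, small_fs):
        with pytest.raises(ValueError, match="bounds"):
            map_points_from_stack(np.array([[1e4, 0, 0]]), small_fs)


class TestFlatProjection:
    def test_one_hot_max_projection(self):
        stack = np.zeros((4, 5, 6))
        stack[2, 3, 4] = 1.0
        img = flat_projection(stack, "max")
        assert img[2, 3] == 1.0 and img.sum() == 1.0

    def test_sum_conserves_signal(self, rng):
        stack = rng.random((5, 5, 7))
        assert np.isclose(flat_projection(stack, "sum").sum(), stack.sum())

    def test_max_dominates_mean(self, rng):
        stack = rng.random((5, 5, 7))
        assert np.all(flat_projection(stack, "max")
                      >= flat_projection(stack, "mean"))


def _affine_stack(dims, stack_to_world_scale, world_extent=4000.0,
                  grid_spacing=50.0):
    """FlatmapStack realizing an exact affine map (for isotropy oracles)."""
    dims = tuple(dims)
    scale = np.asarray(stack_to_world_scale, dtype=float)
    u, v, d = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    stack_vox = np.stack([u, v, d], axis=-1).astype(float)
    to_world = stack_vox * scale
    n = int(world_extent / grid_spacing)
    i, j, k = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    world = np.stack([i, j, k], axis=-1) * grid_spacing
    uvd = world / scale / (np.array(dims) - 1.0)
    return FlatmapStack(dims, to_world, uvd, np.full(3, grid_spacing),
                        np.zeros(3))


class TestIsotropy:
    def test_isometric_stack_scores_near_one(self):
        fs = _affine_stack((40, 40, 20), (50.0, 50.0, 50.0))
        rep = isotropy_validate(fs, layers=(10,), seed_spacing=8,
                                radius=100.0, n_sphere_samples=500, seed=0)
        assert len(rep.table) > 0
        assert rep.table["isotropy"].min() >= 0.95

    def test_uniaxial_double_stretch_scores_half(self):
        # one stack voxel covers 25 μm along u but 50 μm along v/d: a world
        # sphere maps to a 2:1 ellipsoid, so sqrt(λ3/λ1) = 0.5
        fs = _affine_stack((40, 40, 20), (25.0, 50.0, 50.0),
                           world_extent=2000.0)
        rep = isotropy_validate(fs, layers=(10,), seed_spacing=12,
                                radius=80.0, n_sphere_samples=20000, seed=0)
        assert np.allclose(rep.table["isotropy"], 0.5, atol=0.01)

    def test_scores_invariant_to_sphere_radius_under_affine(self):
        fs = _affine_stack((40, 40, 20), (25.0, 50.0, 50.0),
                           world_extent=2000.0)
        reps = [isotropy_validate(fs, layers=(10,), seed_spacing=10,
                                  radius=r, n_sphere_samples=300, seed=3)
                for r in (50.0, 100.0)]
        a, b = (r.table["isotropy"].to_numpy() for r in reps)
        assert np.allclose(a, b, atol=1e-9)

    def test_scores_bounded_and_eigenvalues_sorted(self, small_fs):
        rep = isotropy_validate(small_fs, layers=(5, 12, 18), seed_spacing=20,
                                radius=75.0, n_sphere_samples=100, seed=1)
        t = rep.table
        assert ((t["isotropy"] >= 0) & (t["isotropy"] <= 1)).all()
        assert (t["lambda1"] >= t["lambda2"]).all()
        assert (t["lambda2"] >= t["lambda3"]).all()

    def test_bad_layer_is_an_error(self, small_fs):
        with pytest.raises(ValueError, match="layer"):
            isotropy_validate(small_fs, layers=(99,))
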