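"""Volume assembly, filtering and 3D object counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bspim import (
    AcquisitionConfig,
    DetectionParams,
    GridGeometry,
    count_objects,
    detect_nematodes,
    gaussian_smooth,
    make_scene,
    reconstruct_gd_volume,
    rescale_to_8bit,
    simulate_scan,
    subtract_boxcar,
)
from bspim.detect import GDVolume
from bspim.simulate import Nematode, SceneSpec

from conftest import SMALL_ACQ, small_scene


def vol(arr, size=(10.0, 10.0, 10.0), state="8bit"):
    return GDVolume(voxels=np.asarray(arr, dtype=np.float32), voxel_size_um=size, state=state)


OFFSETS = {
    6: [(dz, dy, dx) for dz, dy, dx in np.ndindex(3, 3, 3)
        if abs(dz - 1) + abs(dy - 1) + abs(dx - 1) == 1],
    18: [(dz, dy, dx) for dz, dy, dx in np.ndindex(3, 3, 3)
         if 0 < abs(dz - 1) + abs(dy - 1) + abs(dx - 1) <= 2],
    26: [(dz, dy, dx) for dz, dy, dx in np.ndindex(3, 3, 3) if (dz, dy, dx) != (1, 1, 1)],
}


def floodfill_components(mask, connectivity):
    """Brute-force BFS labeller; the independent oracle for count_objects."""
    offsets = [(a - 1, b - 1, c - 1) for a, b, c in OFFSETS[connectivity]]
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        queue = [idx]
        seen[idx] = True
        size = 0
        while queue:
            z, y, x = queue.pop()
            size += 1
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        queue.append(n)
        sizes.append(size)
    return sizes


class TestRescale:
    def test_known_linear_mapping_with_half_up_rounding(self):
        v = vol(np.array([[[0.0, 255.0, 510.0]]]), state="raw")
        out = rescale_to_8bit(v)
        np.testing.assert_array_equal(out.voxels[0, 0], [0.0, 128.0, 255.0])
        assert out.state == "8bit"

    def test_constant_volume_maps_to_zero(self):
        out = rescale_to_8bit(vol(np.full((3, 3, 3), 7.0), state="raw"))
        assert not out.voxels.any()

    def test_endpoints_for_any_nonconstant_volume(self, rng):
        data = rng.gamma(2.0, 100.0, size=(4, 6, 6))
        out = rescale_to_8bit(vol(data, state="raw"))
        assert out.voxels.min() == 0.0
        assert out.voxels.max() == 255.0

    def test_requires_raw_state(self):
        with pytest.raises(ValueError, match="raw"):
            rescale_to_8bit(vol(np.zeros((2, 2, 2))))


class TestBoxcar:
    def test_constant_slice_goes_to_zero(self):
        out = subtract_boxcar(vol(np.full((2, 20, 20), 40.0)), radius_um=50.0)
        assert not out.voxels.any()

    def test_single_bright_voxel_loses_only_its_window_share(self):
        data = np.zeros((1, 41, 41), dtype=np.float32)
        data[0, 20, 20] = 200.0
        radius_um = 50.0  # 5 px at 10 um -> 11x11 window
        out = subtract_boxcar(vol(data), radius_um=radius_um)
        expected = 200.0 - 200.0 / 121.0
        assert out.voxels[0, 20, 20] == pytest.approx(expected, rel=1e-5)
        assert out.voxels[0, 20, 20] > 0

    def test_slow_ramp_residual_much_smaller_than_amplitude(self):
        ramp = np.tile(np.linspace(0, 100, 256, dtype=np.float32), (64, 1))[None]
        out = subtract_boxcar(vol(ramp), radius_um=200.0)  # 41 px window
        # a symmetric window centred on a linear ramp averages to the centre
        interior = out.voxels[0, :, 45:-45]
        assert interior.max() < 1.0
        assert out.voxels.max() < 50.0  # only border asymmetry remains

    def test_matches_bruteforce_windowed_mean(self, rng):
        data = rng.integers(0, 255, size=(1, 12, 12)).astype(np.float32)
        out = subtract_boxcar(vol(data), radius_um=10.0)  # 3x3 window
        padded = np.pad(data[0], 1, mode="symmetric")  # edge-duplicating reflection
        for r in range(12):
            for c in range(12):
                mean = padded[r : r + 3, c : c + 3].mean()
                assert out.voxels[0, r, c] == pytest.approx(
                    max(data[0, r, c] - mean, 0.0), abs=1e-3
                )

    def test_subpixel_radius_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="below one pixel"):
            out = subtract_boxcar(vol(np.full((1, 8, 8), 9.0)), radius_um=1.0)
        assert not out.voxels.any()


class TestGaussian:
    def test_interior_mass_conserved(self):
        data = np.zeros((9, 31, 31), dtype=np.float32)
        data[4, 15, 15] = 1000.0
        out = gaussian_smooth(vol(data, size=(10.0, 10.0, 10.0)), sigma_um=20.0)
        assert out.voxels.sum() == pytest.approx(1000.0, rel=1e-3)

    def test_impulse_response_sd_matches_sigma_per_axis(self):
        data = np.zeros((15, 41, 41), dtype=np.float32)
        data[7, 20, 20] = 1.0
        size = (10.0, 10.0, 50.0)  # anisotropic voxels (dx, dy, dz)
        sigma_um = 50.0
        out = gaussian_smooth(vol(data, size=size), sigma_um=sigma_um).voxels
        for axis, step in ((0, 50.0), (1, 10.0), (2, 10.0)):
            other = tuple(a for a in range(3) if a != axis)
            profile = out.sum(axis=other)
            x = np.arange(profile.size) - profile.argmax()
            sd_vox = np.sqrt((profile * x**2).sum() / profile.sum())
            assert sd_vox == pytest.approx(sigma_um / step, rel=0.05)

    def test_sigma_zero_is_identity(self, rng):
        data = rng.random((3, 8, 8)).astype(np.float32)
        out = gaussian_smooth(vol(data), sigma_um=0.0)
        np.testing.assert_array_equal(out.voxels, data)


class TestCountObjects:
    def test_empty_volume_counts_zero(self):
        res = count_objects(vol(np.zeros((8, 8, 8))))
        assert res.count == 0 and res.objects == []

    def test_two_separated_cubes(self):
        data = np.zeros((12, 12, 12), dtype=np.float32)
        data[1:5, 1:5, 1:5] = 255.0
        data[7:11, 7:11, 7:11] = 255.0
        res = count_objects(vol(data))
        assert res.count == 2
        assert sorted(o.voxel_count for o in res.objects) == [64, 64]

    def test_small_cube_fails_size_filter(self):
        data = np.zeros((10, 10, 10), dtype=np.float32)
        data[2:5, 2:5, 2:5] = 255.0  # 27 voxels < 50
        assert count_objects(vol(data)).count == 0

    def test_corner_touch_depends_on_connectivity(self):
        data = np.zeros((4, 4, 4), dtype=np.float32)
        data[0, 0, 0] = data[1, 1, 1] = 255.0
        p26 = DetectionParams(min_voxels=1, connectivity=26)
        p6 = DetectionParams(min_voxels=1, connectivity=6)
        assert count_objects(vol(data), p26).count == 1
        assert count_objects(vol(data), p6).count == 2

    def test_centroid_in_physical_units(self):
        data = np.zeros((5, 5, 5), dtype=np.float32)
        data[2, 1:3, 4] = 255.0
        res = count_objects(vol(data, size=(10.0, 20.0, 125.0)), DetectionParams(min_voxels=1))
        (obj,) = res.objects
        assert obj.centroid_um == pytest.approx((40.0, 30.0, 250.0))  # (x, y, z)

    @settings(deadline=None, max_examples=25)
    @given(
        st.integers(0, 2**31 - 1),
        st.sampled_from([6, 18, 26]),
        st.floats(0.05, 0.35),
    )
    def test_matches_floodfill_oracle(self, seed, connectivity, density):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 20, size=3))
        mask = rng.random(shape) < density
        data = np.where(mask, 255.0, 0.0)
        params = DetectionParams(min_voxels=1, connectivity=connectivity)
        res = count_objects(vol(data.astype(np.float32)), params)
        oracle_sizes = sorted(floodfill_components(mask, connectivity))
        assert sorted(o.voxel_count for o in res.objects) == oracle_sizes

    def test_count_monotone_in_threshold_and_min_voxels(self, rng):
        data = (rng.random((16, 16, 16)) * 255).astype(np.float32)
        data = gaussian_smooth(vol(data), sigma_um=15.0).voxels  # create blobs
        counts_t = [
            count_objects(vol(data), DetectionParams(threshold=t, min_voxels=1)).count
            for t in (10, 40, 80, 120, 200)
        ]
        assert all(b <= a for a, b in zip(counts_t, counts_t[1:]))
        counts_v = [
            count_objects(vol(data), DetectionParams(threshold=40, min_voxels=v)).count
            for v in (1, 5, 20, 50, 200)
        ]
        assert all(b <= a for a, b in zip(counts_v, counts_v[1:]))


class TestReconstruct:
    def test_depth_matches_positions_and_single_position_identity(self, tiny_scan):
        from bspim import generalized_differences

        volume = reconstruct_gd_volume(tiny_scan)
        assert volume.shape[0] == tiny_scan.n_positions
        single = type(tiny_scan)(
            stacks=[tiny_scan.stacks[0]],
            acquisition=tiny_scan.acquisition,
            pixel_size_um=tiny_scan.pixel_size_um,
        )
        v1 = reconstruct_gd_volume(single)
        assert v1.shape[0] == 1
        np.testing.assert_array_equal(
            v1.voxels[0], generalized_differences(tiny_scan.stacks[0]).values
        )

    def test_static_noiseless_scan_gives_zero_volume(self):
        geom = GridGeometry(grid_shape=(32, 32, 4), voxel_size_xy=39.0625)
        scene = make_scene(0, geometry=geom, seed=1)
        acq = AcquisitionConfig(frames_per_position=8, n_positions=4, read_noise_sd=0.0)
        volume = reconstruct_gd_volume(simulate_scan(scene, acq))
        assert not volume.voxels.any()

    def test_nonuniform_z_rejected(self, tiny_scan):
        import dataclasses

        stacks = list(tiny_scan.stacks)
        stacks[-1] = dataclasses.replace(stacks[-1], z_position_um=stacks[-1].z_position_um + 30.0)
        bad = type(tiny_scan)(
            stacks=stacks, acquisition=tiny_scan.acquisition, pixel_size_um=tiny_scan.pixel_size_um
        )
        with pytest.raises(ValueError, match="non-uniform"):
            reconstruct_gd_volume(bad)

    def test_crop_limits_physical_extent(self, tiny_scan):
        volume = reconstruct_gd_volume(tiny_scan, crop_um=((0, 500), (0, 1000), (0, 1000)))
        assert volume.shape[0] <= 6


class TestDetectPipeline:
    def test_live_nematodes_counted_dead_silent(self):
        live = small_scene(3, seed=13)
        dead = small_scene(3, seed=13, alive_fraction=0.0)
        res_live = detect_nematodes(simulate_scan(live, SMALL_ACQ))
        res_dead = detect_nematodes(simulate_scan(dead, SMALL_ACQ))
        assert res_live.count == 3
        assert res_dead.count == 0

    def test_detected_centroids_near_truth(self):
        scene = small_scene(3, seed=21)
        res = detect_nematodes(simulate_scan(scene, SMALL_ACQ))
        truth = np.array([n.centroid_um for n in scene.nematodes])
        found = np.array([o.centroid_um for o in res.objects])
        assert len(found) == 3
        for t in truth:
            d = np.linalg.norm(found - t, axis=1).min()
            assert d < 300.0  # within a body length

    def test_empty_scene_counts_zero(self):
        scene = small_scene(0, seed=2)
        assert detect_nematodes(simulate_scan(scene, SMALL_ACQ)).count == 0

    def test_single_nematode_under_overlapping_sheets_merges_to_one(self):
        # the ~8-slice footprint of a 1 mm sheet at 125 um steps must label
        # as a single 3D object, not one per slice
        geom = GridGeometry(grid_shape=(64, 64, 20), voxel_size_xy=39.0625)
        nem = Nematode(
            centroid_um=(1250.0, 1250.0, 1187.5),
            length_um=400.0,
            width_um=30.0,
            orientation=(0.0, 1.0, 0.0),
            alive=True,
            decorrelation=0.5,
        )
        scene = SceneSpec(geometry=geom, nematodes=[nem], seed=3)
        acq = AcquisitionConfig(
            frames_per_position=32, n_positions=20, sheet_thickness_um=1000.0
        )
        res = detect_nematodes(simulate_scan(scene, acq))
        assert res.count == 1
        (obj,) = res.objects
        assert obj.voxel_count >= 50
        assert obj.centroid_um[2] == pytest.approx(1187.5, abs=250.0)

    def test_stage_stats_recorded(self, tiny_scan):
        res = detect_nematodes(tiny_scan)
        assert set(res.stage_stats) == {"gd", "8bit", "boxcar", "gaussian"}
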