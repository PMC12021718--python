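import numpy as np
import pytest

from interactiveseg.imaging import SegmentationMask, VolumeImage
from interactiveseg.interactions import (
    EmptyObjectError,
    InteractionConfig,
    InteriorMarginPoints,
    compute_voi,
    egd_map,
    load_points,
    perturb_points,
    save_points,
    simulate_points,
)

from .conftest import make_cuboid_mask, make_ellipsoid_mask
from .oracles import brute_force_extremes, dijkstra_egd


def point_for(pts: InteriorMarginPoints, axis: int, side: str) -> np.ndarray:
    for p, (a, s) in zip(pts.points, pts.axis_tags):
        if a == axis and s == side:
            return p
    raise KeyError((axis, side))


class TestSimulatePoints:
    def test_isotropic_cuboid_shifts_five_voxels(self):
        # cuboid spanning x,y in [10,30], z in [5,15] at 1 mm isotropic
        mask = make_cuboid_mask((40, 40, 24), (10, 10, 5), (30, 30, 15))
        pts = simulate_points(mask)
        assert point_for(pts, 0, "min")[0] == 15
        assert point_for(pts, 0, "max")[0] == 25
        assert point_for(pts, 1, "min")[1] == 15
        assert point_for(pts, 1, "max")[1] == 25
        assert point_for(pts, 2, "min")[2] == 10
        assert point_for(pts, 2, "max")[2] == 10

    def test_anisotropic_out_of_plane_shifts_one_voxel(self):
        # spacing ratio 4 > 3: the z extremes move inward by 1 voxel only
        mask = make_cuboid_mask((40, 40, 24), (10, 10, 5), (30, 30, 15), spacing=(1, 1, 4))
        pts = simulate_points(mask)
        assert point_for(pts, 2, "min")[2] == 6
        assert point_for(pts, 2, "max")[2] == 14
        assert point_for(pts, 0, "min")[0] == 15  # in-plane still 5

    def test_thin_plate_clamps_shift_to_foreground(self):
        # extent 1 along x: no room to move inward, stay on the plate
        mask = make_cuboid_mask((30, 30, 30), (12, 5, 5), (12, 25, 25))
        pts = simulate_points(mask)
        assert point_for(pts, 0, "min")[0] == 12
        assert point_for(pts, 0, "max")[0] == 12
        for p in pts.points:
            assert mask.labels[tuple(p)] == 1

    def test_zero_shift_recovers_exact_extremes(self, rng):
        cfg = InteractionConfig(inward_shift_inplane=0, inward_shift_outplane=0)
        for seed in range(3):
            mask = make_ellipsoid_mask(
                (32, 32, 32),
                center=16 + rng.integers(-3, 4, size=3),
                semiaxes=rng.uniform(5, 10, size=3),
            )
            pts = simulate_points(mask, cfg=cfg)
            for axis in range(3):
                for side in ("min", "max"):
                    assert point_for(pts, axis, side)[axis] == brute_force_extremes(
                        mask.labels, axis, side
                    )

    def test_all_points_foreground(self, rng):
        for seed in range(5):
            mask = make_ellipsoid_mask(
                (28, 28, 28), center=(14, 14, 14), semiaxes=rng.uniform(4, 9, size=3)
            )
            pts = simulate_points(mask)
            for p in pts.points:
                assert mask.labels[tuple(p)] == 1

    def test_empty_mask_raises(self):
        mask = SegmentationMask(np.zeros((10, 10, 10), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(EmptyObjectError):
            simulate_points(mask)


class TestPerturbPoints:
    def test_zero_magnitude_is_identity(self, cuboid_mask):
        pts = simulate_points(cuboid_mask)
        out = perturb_points(pts, cuboid_mask, InteractionConfig(perturbation_magnitude=0))
        np.testing.assert_array_equal(out.points, pts.points)

    def test_seeded_determinism(self, cuboid_mask):
        pts = simulate_points(cuboid_mask)
        cfg = InteractionConfig(perturbation_magnitude=2, rng_seed=7)
        a = perturb_points(pts, cuboid_mask, cfg)
        b = perturb_points(pts, cuboid_mask, cfg)
        np.testing.assert_array_equal(a.points, b.points)
        other = perturb_points(
            pts, cuboid_mask, InteractionConfig(perturbation_magnitude=2, rng_seed=8)
        )
        assert not np.array_equal(a.points, other.points)

    def test_bounded_displacement_and_foreground(self, cuboid_mask):
        pts = simulate_points(cuboid_mask)
        for seed in range(5):
            cfg = InteractionConfig(perturbation_magnitude=2, rng_seed=seed)
            out = perturb_points(pts, cuboid_mask, cfg)
            assert np.abs(out.points - pts.points).max() <= 2
            for p in out.points:
                assert cuboid_mask.labels[tuple(p)] == 1


class TestComputeVoi:
    def test_default_relaxation_arithmetic(self):
        pts = InteriorMarginPoints(
            np.array([[15, 20, 20], [25, 20, 20], [20, 15, 20],
                      [20, 25, 20], [20, 20, 15], [20, 20, 25]])
        )
        box = compute_voi(pts, (64, 64, 64))
        # extent 10, 0.1*10 = 1 < 5 so the 5-voxel floor applies
        assert box.lower == (10, 10, 10)
        assert box.upper == (31, 31, 31)

    def test_zero_relaxation_is_tight_box(self):
        pts = InteriorMarginPoints(
            np.array([[15, 20, 20], [25, 20, 20], [20, 15, 20],
                      [20, 25, 20], [20, 20, 15], [20, 20, 25]])
        )
        cfg = InteractionConfig(relaxation_fraction=0, relaxation_min_voxels=0)
        box = compute_voi(pts, (64, 64, 64), cfg)
        assert box.lower == (15, 15, 15)
        assert box.upper == (26, 26, 26)

    def test_clipped_at_grid_edge_still_contains_points(self):
        pts = InteriorMarginPoints(
            np.array([[0, 3, 3], [6, 3, 3], [3, 0, 3], [3, 6, 3], [3, 3, 0], [3, 3, 6]])
        )
        box = compute_voi(pts, (8, 8, 8))
        assert box.lower == (0, 0, 0)
        assert box.upper == (8, 8, 8)
        for p in pts.points:
            assert box.contains_point(p)

    def test_voi_contains_mask_for_simulated_points(self, rng):
        # the relaxation exists to encapsulate the whole object
        for seed in range(10):
            mask = make_ellipsoid_mask(
                (40, 40, 40),
                center=20 + rng.integers(-4, 5, size=3),
                semiaxes=rng.uniform(5, 12, size=3),
            )
            pts = simulate_points(mask)
            box = compute_voi(pts, mask.shape)
            fg = np.argwhere(mask.labels > 0)
            assert np.all(fg >= box.lower) and np.all(fg < box.upper)


class TestEgdMap:
    def _random_points(self, rng, shape, n=6):
        return InteriorMarginPoints(
            np.stack([rng.integers(0, s, size=n) for s in shape], axis=1)
        )

    def test_matches_dijkstra_oracle_exactly(self, rng):
        for _ in range(5):
            shape = (9, 8, 7)
            img = VolumeImage(rng.normal(size=shape), (1.0, 1.3, 2.0))
            pts = self._random_points(rng, shape)
            for lam in (0.0, 0.5, 1.0):
                got = egd_map(img, pts, alpha=1.2, lam=lam)
                ref = dijkstra_egd(img.voxels, img.spacing, pts.points, 1.2, lam)
                np.testing.assert_array_equal(got.values, ref)

    def test_seed_voxels_are_exactly_one_and_range(self, rng):
        shape = (10, 10, 10)
        img = VolumeImage(rng.normal(size=shape), (1, 1, 1))
        pts = self._random_points(rng, shape)
        gm = egd_map(img, pts)
        for p in pts.points:
            assert gm.values[tuple(p)] == 1.0
        assert np.all(gm.values > 0) and np.all(gm.values <= 1)

    def test_uniform_intensity_lam0_equals_grid_geodesic(self, rng):
        # lam=0 on a constant image: D is the weighted L1 (city-block)
        # distance in mm to the nearest seed
        shape = (8, 9, 10)
        spacing = (1.0, 2.0, 0.5)
        img = VolumeImage(np.full(shape, 3.3), spacing)
        pts = self._random_points(rng, shape)
        gm = egd_map(img, pts, alpha=1.0, lam=0.0)
        grids = np.meshgrid(*map(np.arange, shape), indexing="ij")
        expected = np.full(shape, np.inf)
        for p in pts.points:
            d = sum(
                np.abs(g - c) * s for g, c, s in zip(grids, p, spacing)
            )
            expected = np.minimum(expected, d)
        np.testing.assert_allclose(gm.values, np.exp(-expected), rtol=1e-12)

    def test_highlights_bright_object_containing_seeds(self):
        # pure-intensity EGD: inside a bright blob with interior seeds,
        # the map stays high; crossing the boundary costs intensity
        mask = make_ellipsoid_mask((24, 24, 24), (12, 12, 12), (7, 7, 7))
        img = VolumeImage(mask.labels * 2.0, (1, 1, 1))
        pts = simulate_points(mask)
        gm = egd_map(img, pts, alpha=1.0, lam=1.0)
        inside = gm.values[mask.labels > 0].mean()
        outside = gm.values[mask.labels == 0].mean()
        assert inside > outside

    def test_intensity_scaling_scales_distance(self, rng):
        shape = (8, 8, 8)
        base = rng.normal(size=shape)
        pts = self._random_points(rng, shape)
        g1 = egd_map(VolumeImage(base, (1, 1, 1)), pts, alpha=1.0, lam=1.0)
        g3 = egd_map(VolumeImage(3.0 * base, (1, 1, 1)), pts, alpha=1.0, lam=1.0)
        d1 = -np.log(g1.values)
        d3 = -np.log(g3.values)
        np.testing.assert_allclose(d3, 3.0 * d1, atol=1e-9)

    def test_point_outside_crop_rejected(self, rng):
        img = VolumeImage(rng.normal(size=(6, 6, 6)), (1, 1, 1))
        pts = InteriorMarginPoints(np.full((6, 3), 9))
        with pytest.raises(ValueError):
            egd_map(img, pts)


class TestPointsJson:
    def test_round_trip(self, tmp_path, cuboid_mask):
        pts = simulate_points(cuboid_mask)
        path = tmp_path / "pts.json"
        save_points(pts, path, image="images/x.nii.gz")
        back = load_points(path, grid_shape=cuboid_mask.shape)
        np.testing.assert_array_equal(back.points, pts.points)

    def test_wrong_count_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"space": "voxel", "points": [[1,1,1]]}')
        with pytest.raises(ValueError):
            load_points(path)
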