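"""Metric morphology against brute-force distance oracles."""

import numpy as np
import pytest

from aortapet.imaging import BinaryMask, GeometryError, ImageVolume
from aortapet.masks import (
    SphereVOI,
    close_mask,
    dilate_metric,
    rasterize_spheres,
    spill_over_corrected_aorta,
    subtract_mask,
)


def brute_force_dilate(mask: BinaryMask, distance_mm: float) -> np.ndarray:
    """All-pairs voxel-center distance check (independent oracle)."""
    sp = np.asarray(mask.spacing)
    pts = np.argwhere(mask.data) * sp
    out = np.zeros(mask.shape, dtype=bool)
    if pts.size == 0:
        return out
    for idx in np.ndindex(mask.shape):
        c = np.asarray(idx) * sp
        d = np.sqrt(((pts - c) ** 2).sum(axis=1)).min()
        out[idx] = d <= distance_mm + 1e-9
    return out


def single_voxel_mask(shape, spacing):
    data = np.zeros(shape, dtype=bool)
    data[tuple(s // 2 for s in shape)] = True
    return BinaryMask(data, spacing)


class TestDilateMetric:
    def test_distance_zero_is_identity(self):
        m = single_voxel_mask((5, 5, 5), (1, 1, 1))
        np.testing.assert_array_equal(dilate_metric(m, 0).data, m.data)

    def test_isotropic_ball_voxel_count(self):
        # single voxel, 1 mm grid, 2 mm radius: 33 centers within distance
        m = single_voxel_mask((9, 9, 9), (1, 1, 1))
        assert dilate_metric(m, 2.0).count() == 33

    def test_anisotropic_spacing_excludes_far_slices(self):
        # 3 mm slices: 2 mm dilation must not reach neighbouring slices
        m = single_voxel_mask((9, 9, 9), (1, 1, 3))
        out = dilate_metric(m, 2.0)
        assert not out.data[:, :, 3].any() and not out.data[:, :, 5].any()
        assert out.data[:, :, 4].sum() == 13  # 2D disc of radius 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        spacing = tuple(rng.choice([0.7, 1.0, 3.0], size=3))
        m = BinaryMask(rng.random((10, 9, 8)) > 0.92, spacing)
        d = float(rng.uniform(0, 4))
        np.testing.assert_array_equal(
            dilate_metric(m, d).data, brute_force_dilate(m, d)
        )

    def test_extensive_and_monotone(self):
        rng = np.random.default_rng(3)
        m = BinaryMask(rng.random((12, 12, 6)) > 0.9, (1, 1, 2))
        d1, d2 = dilate_metric(m, 2.0), dilate_metric(m, 4.0)
        assert (d1.data | m.data).sum() == d1.count()  # output contains input
        assert (d2.data | d1.data).sum() == d2.count()  # monotone in distance

    def test_empty_mask_stays_empty(self):
        m = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert dilate_metric(m, 5.0).is_empty()


class TestCloseMask:
    def test_radius_zero_is_identity(self):
        m = single_voxel_mask((5, 5, 5), (1, 1, 1))
        np.testing.assert_array_equal(close_mask(m, 0).data, m.data)

    def test_fills_gap_between_blocks(self):
        # two solid blocks separated by a 2 mm gap; 3 mm closing bridges it
        data = np.zeros((20, 7, 7), dtype=bool)
        data[2:8, 2:5, 2:5] = True
        data[10:16, 2:5, 2:5] = True
        out = close_mask(BinaryMask(data, (1, 1, 1)), 3.0)
        assert out.data[8:10, 3, 3].all()
        assert (out.data & ~data)[:, 2:5, 2:5].any()

    def test_solid_ball_unchanged(self):
        x = np.arange(15) - 7.0
        ball = (
            x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        ) <= 25
        m = BinaryMask(ball, (1, 1, 1))
        out = close_mask(m, 2.0)
        assert (out.data & ~m.data).sum() == 0  # convex solid: no additions

    @pytest.mark.parametrize("seed", range(4))
    def test_extensive_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = BinaryMask(rng.random((14, 14, 7)) > 0.85, (1, 1, 2))
        once = close_mask(m, 2.5)
        assert (once.data & ~m.data).sum() >= 0 and (m.data & ~once.data).sum() == 0
        twice = close_mask(once, 2.5)
        np.testing.assert_array_equal(twice.data, once.data)


class TestSubtractAndCorrection:
    def test_subtract_is_set_difference(self):
        rng = np.random.default_rng(0)
        a = BinaryMask(rng.random((6, 6, 6)) > 0.5, (1, 1, 1))
        b = BinaryMask(rng.random((6, 6, 6)) > 0.5, (1, 1, 1))
        out = subtract_mask(a, b)
        np.testing.assert_array_equal(out.data, a.data & ~b.data)
        # empty exclusion leaves the mask unchanged
        empty = BinaryMask(np.zeros((6, 6, 6), bool), (1, 1, 1))
        np.testing.assert_array_equal(subtract_mask(a, empty).data, a.data)
        # superset exclusion empties the mask (valid output)
        assert subtract_mask(a, a).is_empty()

    def test_subtract_rejects_geometry_mismatch(self):
        a = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        b = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 2))
        with pytest.raises(GeometryError):
            subtract_mask(a, b)

    def test_correction_with_empty_vertebrae_is_identity(self):
        rng = np.random.default_rng(1)
        aorta = BinaryMask(rng.random((8, 8, 8)) > 0.5, (1, 1, 3))
        vert = BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 3))
        out = spill_over_corrected_aorta(aorta, vert)
        np.testing.assert_array_equal(out.data, aorta.data)

    def test_zero_close_zero_dilate_is_plain_subtraction(self):
        rng = np.random.default_rng(2)
        aorta = BinaryMask(rng.random((8, 8, 8)) > 0.4, (1, 1, 1))
        vert = BinaryMask(rng.random((8, 8, 8)) > 0.7, (1, 1, 1))
        out = spill_over_corrected_aorta(aorta, vert, 0.0, 0.0)
        np.testing.assert_array_equal(out.data, aorta.data & ~vert.data)

    def test_no_surviving_voxel_near_bone(self):
        # column 5 mm from the tube: audit every surviving voxel center
        shape, sp = (30, 30, 8), (1.0, 1.0, 3.0)
        x = np.arange(30)
        aorta2d = (x[:, None] - 15) ** 2 + (x[None, :] - 18) ** 2 <= 64
        aorta = np.repeat(aorta2d[:, :, None], 8, axis=2)
        vert = np.zeros(shape, bool)
        vert[10:20, 0:5, :] = True
        am, vm = BinaryMask(aorta, sp), BinaryMask(vert, sp)
        out = spill_over_corrected_aorta(am, vm, close_radius_mm=3.0, dilate_mm=10.0)
        closed = close_mask(vm, 3.0)
        pts = np.argwhere(closed.data) * np.asarray(sp)
        surv = np.argwhere(out.data) * np.asarray(sp)
        assert surv.size and pts.size
        for c in surv:
            d = np.sqrt(((pts - c) ** 2).sum(axis=1)).min()
            assert d > 10.0


class TestRasterizeSpheres:
    def test_one_ml_sphere_voxel_count(self):
        vol = ImageVolume(np.zeros((24, 24, 24)), (1, 1, 1))
        mask, idx = rasterize_spheres(vol, [SphereVOI((11.5, 11.5, 11.5), 1.0)])
        assert mask.count() == len(idx[0])
        assert abs(mask.count() - 1000.0) / 1000.0 < 0.05  # ~1 mL of 1 mm^3 voxels

    def test_tiny_sphere_hits_single_voxel(self):
        vol = ImageVolume(np.zeros((9, 9, 9)), (1, 1, 1))
        voi = SphereVOI((4.0, 4.0, 4.0), 4.0 / 3.0 * np.pi * 0.4**3 / 1000.0)
        assert voi.radius_mm < 0.5
        mask, _ = rasterize_spheres(vol, [voi])
        assert mask.count() == 1
        assert mask.data[4, 4, 4]

    def test_disjoint_spheres_partition_union(self):
        vol = ImageVolume(np.zeros((40, 20, 20)), (1, 1, 1))
        mask, idx = rasterize_spheres(
            vol, [SphereVOI((8, 10, 10)), SphereVOI((30, 10, 10))]
        )
        assert len(np.intersect1d(idx[0], idx[1])) == 0
        assert mask.count() == len(idx[0]) + len(idx[1])

    def test_sphere_outside_volume_errors(self):
        vol = ImageVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError, match="sphere 0"):
            rasterize_spheres(vol, [SphereVOI((50.0, 5.0, 5.0))])
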