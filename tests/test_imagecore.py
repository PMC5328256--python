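import numpy as np
import pytest

from imiomics.imagecore import (
    BinaryMask,
    Grid,
    LabelVolume,
    ScalarVolume,
    dice,
    distance_transform,
    interpolate,
    read_nifti,
    resample,
    threshold_mask,
    write_nifti,
)
from imiomics.transforms import AffineTransform, SimilarityTransform

from conftest import make_volume


class TestInterpolate:
    def test_constant_field_everywhere(self):
        vol = make_volume(np.full((5, 5, 5), 42.0))
        assert interpolate(vol, (1.7, 2.2, 3.9)) == pytest.approx(42.0)

    def test_voxel_center_exact_both_modes(self, rng):
        vol = make_volume(rng.uniform(0, 100, (4, 5, 6)), spacing=(2.0, 3.0, 1.5))
        for mode in ("linear", "nearest"):
            assert interpolate(vol, (2 * 2.0, 3 * 3.0, 4 * 1.5), mode=mode) == pytest.approx(
                vol.values[2, 3, 4]
            )

    def test_midpoint_between_centers(self):
        vals = np.zeros((2, 1, 1))
        vals[1] = 100.0
        vol = make_volume(vals, spacing=(4.0, 1.0, 1.0))
        assert interpolate(vol, (2.0, 0.0, 0.0)) == pytest.approx(50.0)

    def test_linear_reproduction_of_affine_intensity(self, rng):
        """Trilinear interpolation is exact for affine intensity fields."""
        g = Grid((6, 6, 6), (2.0, 1.0, 3.0), (-1.0, 0.0, 2.0))
        coef = np.array([0.3, -0.7, 1.1])
        pts_grid = g.voxel_centers()
        vol = ScalarVolume(5.0 + pts_grid @ coef, g.spacing, g.origin)
        interior = g.index_to_physical(rng.uniform(0.5, 4.5, (50, 3)))
        expected = 5.0 + interior @ coef
        np.testing.assert_allclose(interpolate(vol, interior), expected, atol=1e-10)

    def test_outside_returns_fill(self):
        vol = make_volume(np.full((3, 3, 3), 7.0))
        assert interpolate(vol, (100.0, 0.0, 0.0)) == 0.0
        assert interpolate(vol, (100.0, 0.0, 0.0), fill=-1.0) == -1.0

    def test_nonfinite_point_rejected(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            interpolate(vol, (np.nan, 0.0, 0.0))


class TestResample:
    def test_identity_is_voxel_exact(self, rng):
        vol = make_volume(rng.uniform(0, 100, (5, 6, 7)), spacing=(2.0, 2.0, 8.0))
        out = resample(vol, None, vol.grid)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_one_voxel_translation_shifts_indices(self, rng):
        vol = make_volume(rng.uniform(0, 100, (6, 6, 6)), spacing=(2.0, 3.0, 4.0))
        t = AffineTransform(b=np.array([2.0, 0.0, 0.0]))  # +1 voxel along x
        out = resample(vol, t, vol.grid)
        np.testing.assert_allclose(out.values[:-1], vol.values[1:], atol=1e-9)

    def test_uniform_scale_of_constant_volume(self):
        vol = make_volume(np.full((6, 6, 6), 13.0))
        t = SimilarityTransform(s=1.3, c=np.array([2.5, 2.5, 2.5]))
        out = resample(vol, t, vol.grid)
        # interior stays constant; only voxels mapped outside pick up fill
        assert out.values[1:-1, 1:-1, 1:-1] == pytest.approx(13.0)

    def test_zero_size_axis_rejected(self, rng):
        vol = make_volume(rng.uniform(0, 1, (3, 3, 3)))
        with pytest.raises(ValueError):
            resample(vol, None, Grid((3, 0, 3), (1, 1, 1)))


def brute_force_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """O(n^2) exhaustive oracle: min distance to any object voxel."""
    obj = np.argwhere(mask) * np.asarray(spacing)
    out = np.zeros(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * np.asarray(spacing)
        out[idx] = np.min(np.linalg.norm(obj - p, axis=1))
    return out


class TestDistanceTransform:
    def test_all_ones_is_zero(self):
        m = BinaryMask(np.ones((4, 4, 4)), (1, 1, 1))
        assert np.all(distance_transform(m).values == 0)

    def test_single_voxel_neighbors(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 1
        dt = distance_transform(BinaryMask(vals, (1, 1, 1))).values
        assert dt[0, 1, 1] == pytest.approx(1.0)
        assert dt[0, 0, 1] == pytest.approx(np.sqrt(2))
        assert dt[0, 0, 0] == pytest.approx(np.sqrt(3))

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (2.0, 2.0, 8.0)])
    def test_matches_brute_force_oracle(self, spacing, rng):
        mask = rng.random((10, 10, 10)) < 0.05
        mask[4, 4, 4] = True  # ensure non-empty
        dt = distance_transform(BinaryMask(mask.astype(np.uint8), spacing))
        np.testing.assert_allclose(dt.values, brute_force_distance(mask, spacing), atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_transform(BinaryMask(np.zeros((3, 3, 3)), (1, 1, 1)))


class TestThresholdAndDice:
    def test_threshold_is_strict(self):
        assert threshold_mask(make_volume(np.full((2, 2, 2), 60.0)), 50).n_voxels == 8
        assert threshold_mask(make_volume(np.full((2, 2, 2), 50.0)), 50).n_voxels == 0

    def test_threshold_half_volume(self):
        vals = np.full((4, 4, 4), 40.0)
        vals[:2] = 60.0
        mask = threshold_mask(make_volume(vals), 50)
        np.testing.assert_array_equal(mask.values[:2], 1)
        np.testing.assert_array_equal(mask.values[2:], 0)

    def test_dice_self_disjoint_and_half(self):
        a = np.zeros((10, 10, 2))
        a[:5] = 1
        b = np.zeros((10, 10, 2))
        b[2:7, :, :] = 1  # 100 voxels, overlap rows 2..4 = 60... construct exact
        ma = BinaryMask(a, (1, 1, 1))
        assert dice(ma, ma) == 1.0
        mb = BinaryMask(1 - a, (1, 1, 1))
        assert dice(ma, mb) == 0.0

    def test_dice_hand_count(self):
        a = np.zeros((20, 10, 1))
        b = np.zeros((20, 10, 1))
        a.flat[:100] = 1  # |A| = 100
        b.flat[50:150] = 1  # |B| = 100, |A ∩ B| = 50
        got = dice(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1)))
        assert got == pytest.approx(0.5)

    def test_dice_empty_pair_is_one(self):
        z = BinaryMask(np.zeros((3, 3, 3)), (1, 1, 1))
        assert dice(z, z) == 1.0

    def test_dice_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = BinaryMask((rng.random((6, 6, 6)) < 0.4).astype(np.uint8), (1, 1, 1))
            b = BinaryMask((rng.random((6, 6, 6)) < 0.4).astype(np.uint8), (1, 1, 1))
            d = dice(a, b)
            assert 0.0 <= d <= 1.0
            assert d == dice(b, a)

    def test_dice_geometry_mismatch_rejected(self):
        a = BinaryMask(np.ones((3, 3, 3)), (1, 1, 1))
        b = BinaryMask(np.ones((3, 3, 3)), (2, 1, 1))
        with pytest.raises(ValueError):
            dice(a, b)


class TestContainersAndIO:
    def test_mask_values_validated(self):
        with pytest.raises(ValueError):
            BinaryMask(np.full((2, 2, 2), 0.5), (1, 1, 1))

    def test_spacing_validated(self):
        with pytest.raises(ValueError):
            ScalarVolume(np.zeros((2, 2, 2)), (0.0, 1.0, 1.0))

    def test_label_region(self):
        lab = LabelVolume(np.arange(8).reshape(2, 2, 2) % 3, (1, 1, 1))
        assert set(lab.labels()) == {1, 2}
        assert lab.region(1).n_voxels == int((lab.values == 1).sum())

    def test_nifti_roundtrip(self, tmp_path, rng):
        vol = ScalarVolume(
            rng.uniform(0, 100, (4, 5, 6)), (2.07, 2.07, 8.0), (-10.0, 3.0, 0.0)
        )
        write_nifti(vol, tmp_path / "v.nii.gz")
        back = read_nifti(tmp_path / "v.nii.gz")
        assert back.same_geometry(vol, atol=1e-4)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-4)

    def test_nifti_mask_roundtrip_uint8(self, tmp_path):
        m = BinaryMask(np.eye(4)[..., None] * np.ones((1, 1, 3)), (1, 1, 1))
        write_nifti(m, tmp_path / "m.nii.gz")
        back = read_nifti(tmp_path / "m.nii.gz", BinaryMask)
        np.testing.assert_array_equal(back.values, m.values)
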