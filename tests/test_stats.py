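import numpy as np
import pytest
from scipy import stats as sps

from imiomics.imagecore import BinaryMask, Grid, ScalarVolume
from imiomics.imiomics_stats import (
    anomaly_pmap,
    bh_adjust,
    build_atlas,
    group_pmap,
    local_volume_map,
    longitudinal_diff,
    rmap,
)
from imiomics.transforms import SimilarityTransform

from conftest import make_volume

SHAPE = (16, 16, 10)  # 2560 voxels >= the calibration sample size


def stack_of(rng, n, mean=50.0, sd=5.0):
    return [make_volume(rng.normal(mean, sd, SHAPE)) for _ in range(n)]


class TestAtlas:
    def test_identical_volumes(self, rng):
        v = make_volume(rng.uniform(0, 100, SHAPE))
        atlas = build_atlas([v.copy() for _ in range(4)])
        np.testing.assert_allclose(atlas.mean.values, v.values)
        np.testing.assert_allclose(atlas.sd.values, 0.0, atol=1e-12)

    def test_two_value_hand_computation(self):
        a = make_volume(np.full(SHAPE, 10.0))
        b = make_volume(np.full(SHAPE, 20.0))
        atlas = build_atlas([a, b])
        assert atlas.mean.values.flat[0] == pytest.approx(15.0)
        assert atlas.sd.values.flat[0] == pytest.approx(np.sqrt(50.0))

    def test_single_volume_sd_zero(self, rng):
        v = make_volume(rng.uniform(0, 100, SHAPE))
        atlas = build_atlas([v])
        assert atlas.n == 1
        assert np.all(atlas.sd.values == 0)

    def test_matches_two_pass_computation(self, rng):
        vols = stack_of(rng, 7)
        atlas = build_atlas(vols)
        stack = np.stack([v.values for v in vols])
        np.testing.assert_allclose(atlas.mean.values, stack.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(atlas.sd.values, stack.std(axis=0, ddof=1), atol=1e-12)

    def test_geometry_mismatch_rejected(self, rng):
        a = make_volume(rng.uniform(0, 1, SHAPE))
        b = ScalarVolume(rng.uniform(0, 1, SHAPE), (2, 2, 2))
        with pytest.raises(ValueError):
            build_atlas([a, b])


class TestAnomalyPmap:
    def test_subject_equal_to_mean_gives_p_one(self, rng):
        vols = stack_of(rng, 10)
        atlas = build_atlas(vols)
        pmap = anomaly_pmap(atlas.mean, atlas)
        np.testing.assert_allclose(pmap.volume.values, 1.0)

    def test_z_of_1p96_gives_p_05(self, rng):
        vols = stack_of(rng, 20)
        atlas = build_atlas(vols)
        subj = ScalarVolume.like(atlas.mean, atlas.mean.values + 1.96 * atlas.sd.values)
        pmap = anomaly_pmap(subj, atlas)
        np.testing.assert_allclose(pmap.volume.values, 0.05, atol=1e-3)

    def test_null_calibration(self, rng):
        """A subject drawn from the atlas population triggers ~5% of voxels."""
        n = 200  # large atlas so mean/sd are accurate
        vols = stack_of(rng, n)
        atlas = build_atlas(vols)
        subject = make_volume(rng.normal(50.0, 5.0, SHAPE))
        pmap = anomaly_pmap(subject, atlas)
        fpr = float((pmap.volume.values < 0.05).mean())
        assert 0.03 <= fpr <= 0.07

    def test_small_atlas_rejected(self, rng):
        atlas = build_atlas(stack_of(rng, 2))
        with pytest.raises(ValueError):
            anomaly_pmap(atlas.mean, atlas)

    def test_percentile_variant(self, rng):
        vols = stack_of(rng, 50)
        atlas = build_atlas(vols, keep_values=True)
        pmap = anomaly_pmap(atlas.mean, atlas, method="percentile")
        assert np.nanmin(pmap.volume.values) > 0.5  # the mean is never extreme


class TestGroupPmap:
    def test_identical_groups_give_p_one(self, rng):
        vols = stack_of(rng, 5)
        pmap = group_pmap(vols, [v.copy() for v in vols])
        np.testing.assert_allclose(pmap.volume.values, 1.0, atol=1e-12)

    def test_null_p_values_uniform(self, rng):
        a = stack_of(rng, 12)
        b = stack_of(rng, 12)
        pmap = group_pmap(a, b)
        ks = sps.kstest(pmap.volume.values.ravel(), "uniform").statistic
        assert ks < 0.05

    def test_implanted_shift_detected_at_study_group_sizes(self, rng):
        """+2 SD mean shift, n = 20 vs 23, inside a known region."""
        region = np.zeros(SHAPE, dtype=bool)
        region[4:12, 4:12, 3:7] = True
        a = stack_of(rng, 20)
        b = []
        for _ in range(23):
            v = rng.normal(50.0, 5.0, SHAPE)
            v[region] += 10.0  # +2 SD
            b.append(make_volume(v))
        pmap = group_pmap(a, b)
        assert np.median(pmap.volume.values[region]) < 1e-3
        fpr = float((pmap.volume.values[~region] < 0.05).mean())
        assert 0.02 <= fpr <= 0.08

    def test_insufficient_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            group_pmap(stack_of(rng, 1), stack_of(rng, 5))


class TestRmap:
    def test_exactly_linear_gives_r_one(self, rng):
        cov = rng.uniform(0, 10, 8)
        vols = [make_volume(np.full(SHAPE, 2.0 * c + 1.0)) for c in cov]
        out = rmap(vols, cov)
        np.testing.assert_allclose(out.volume.values, 1.0, atol=1e-9)

    def test_independent_covariate_small_r(self, rng):
        vols = stack_of(rng, 60)
        cov = rng.normal(0, 1, 60)
        out = rmap(vols, cov)
        assert float(np.abs(out.volume.values).mean()) < 0.15

    def test_implanted_rho_recovered(self, rng):
        rho = 0.9
        n = 60
        z = rng.normal(0, 1, n)
        vols = [
            make_volume(50.0 + 10.0 * (rho * z[i] + np.sqrt(1 - rho**2) * rng.normal(0, 1, SHAPE)))
            for i in range(n)
        ]
        out = rmap(vols, z)
        assert 0.8 <= float(np.median(out.volume.values)) <= 0.97

    def test_invariant_to_voxelwise_affine_rescaling(self, rng):
        vols = stack_of(rng, 10)
        cov = rng.normal(0, 1, 10)
        r1 = rmap(vols, cov).volume.values
        scale = rng.uniform(0.5, 2.0, SHAPE)
        shift = rng.uniform(-10, 10, SHAPE)
        vols2 = [make_volume(v.values * scale + shift) for v in vols]
        r2 = rmap(vols2, cov).volume.values
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            rmap(stack_of(rng, 5), np.ones(5))

    def test_spearman_variant_monotone_invariance(self, rng):
        cov = rng.normal(0, 1, 12)
        vols = stack_of(rng, 12)
        r1 = rmap(vols, cov, method="spearman").volume.values
        r2 = rmap(vols, np.exp(cov), method="spearman").volume.values
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestLocalVolumeAndLongitudinal:
    def test_identity_gives_unit_jacobian(self):
        g = Grid((8, 8, 8), (2.0, 2.0, 4.0))
        out = local_volume_map(SimilarityTransform(), g)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_global_scale_closed_form(self):
        g = Grid((10, 10, 10), (2.0, 2.0, 4.0))
        center = np.array(g.origin) + np.array(g.spacing) * 4.5
        out = local_volume_map(SimilarityTransform(s=1.2, c=center), g)
        np.testing.assert_allclose(out.values[1:-1, 1:-1, 1:-1], 1.2**3, atol=1e-6)

    def test_identical_inputs_zero_difference(self, rng):
        v = make_volume(rng.uniform(0, 100, SHAPE))
        out = longitudinal_diff(v, v.copy())
        np.testing.assert_array_equal(out.volume.values, 0.0)

    def test_constant_offset(self, rng):
        v = make_volume(rng.uniform(0, 100, SHAPE))
        w = make_volume(v.values + 10.0)
        out = longitudinal_diff(v, w)
        np.testing.assert_allclose(out.volume.values, -10.0, atol=1e-12)


class TestMaskingAndAdjustment:
    def test_mask_marks_outside_as_nan(self, rng):
        vols = stack_of(rng, 6)
        mask = np.zeros(SHAPE)
        mask[2:10] = 1
        pmap = group_pmap(vols[:3], vols[3:], mask=BinaryMask(mask, (1, 1, 1)))
        assert np.isnan(pmap.volume.values[0, 0, 0])
        assert np.isfinite(pmap.volume.values[5, 5, 5])

    def test_bh_adjustment_is_monotone_and_larger(self, rng):
        a = stack_of(rng, 6)
        b = stack_of(rng, 6)
        pmap = group_pmap(a, b)
        adj = bh_adjust(pmap)
        p = pmap.volume.values.ravel()
        q = adj.volume.values.ravel()
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
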