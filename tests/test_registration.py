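import numpy as np
import pytest

from imiomics.imagecore import BinaryMask, LabelVolume, ScalarVolume
from imiomics.phantom import generate_subject
from imiomics.registration import (
    CostTerm,
    OptimizerSettings,
    RegistrationConfig,
    _AffineParams,
    combined_cost,
    gaussian_pyramid,
    landmark_cost,
    optimize_step,
    register_water,
    sample_bone_pairs,
    ssd_cost,
)
from imiomics.transforms import PointPairs, SimilarityTransform

from conftest import SMALL_SPEC, make_volume


def full_domain(shape, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.ones(shape), spacing)


class TestCosts:
    def test_ssd_zero_for_identical(self, rng):
        v = make_volume(rng.uniform(0, 100, (6, 6, 6)))
        assert ssd_cost(None, v, v, full_domain(v.shape)) == pytest.approx(0.0)

    def test_ssd_constant_offset(self):
        f = make_volume(np.full((5, 5, 5), 10.0))
        m = make_volume(np.full((5, 5, 5), 13.0))
        assert ssd_cost(None, f, m, full_domain((5, 5, 5))) == pytest.approx(9.0)

    def test_ssd_matches_voxel_loop(self, rng):
        f = make_volume(rng.uniform(0, 100, (8, 8, 8)))
        m = make_volume(rng.uniform(0, 100, (8, 8, 8)))
        loop = np.mean([(f.values[i] - m.values[i]) ** 2 for i in np.ndindex(8, 8, 8)])
        assert ssd_cost(None, f, m, full_domain((8, 8, 8))) == pytest.approx(loop, abs=1e-9)

    def test_ssd_empty_domain_rejected(self, rng):
        v = make_volume(rng.uniform(0, 1, (4, 4, 4)))
        with pytest.raises(ValueError):
            CostTerm("ssd", fixed=v, moving=v, domain=BinaryMask(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_landmark_zero_when_exact(self, rng):
        pts = rng.uniform(-10, 10, (6, 3))
        t = SimilarityTransform(s=1.2, t=np.array([1.0, 2.0, 3.0]))
        assert landmark_cost(t, PointPairs(pts, t(pts))) == pytest.approx(0.0, abs=1e-12)

    def test_landmark_mean_of_norms_not_squared(self):
        fixed = np.zeros((2, 3))
        moving = np.array([[3.0, 0, 0], [0, 5.0, 0]])
        assert landmark_cost(None, PointPairs(fixed, moving)) == pytest.approx(4.0)

    def test_landmark_matches_loop(self, rng):
        fixed = rng.uniform(-10, 10, (50, 3))
        moving = rng.uniform(-10, 10, (50, 3))
        loop = np.mean([np.linalg.norm(m - f) for f, m in zip(fixed, moving)])
        assert landmark_cost(None, PointPairs(fixed, moving)) == pytest.approx(loop, abs=1e-12)

    def test_combined_single_term_normalization(self, rng):
        f = make_volume(np.full((4, 4, 4), 10.0))
        m = make_volume(np.full((4, 4, 4), 13.0))
        term = CostTerm("ssd", fixed=f, moving=m, domain=full_domain((4, 4, 4)))
        assert combined_cost([term], [0.37], None) == pytest.approx(9.0)

    def test_combined_hand_computation(self):
        # terms valued 0.3 and 0.9 with weights (2, 1) -> 0.5
        f1 = make_volume(np.full((3, 3, 3), 0.0))
        m1 = make_volume(np.full((3, 3, 3), np.sqrt(0.3)))
        pairs = PointPairs(np.zeros((1, 3)), np.array([[0.9, 0.0, 0.0]]))
        terms = [
            CostTerm("ssd", fixed=f1, moving=m1, domain=full_domain((3, 3, 3))),
            CostTerm("landmark", pairs=pairs),
        ]
        assert combined_cost(terms, [2.0, 1.0], None) == pytest.approx(0.5)

    def test_combined_all_zero_weights_rejected(self):
        pairs = PointPairs(np.zeros((1, 3)), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            combined_cost([CostTerm("landmark", pairs=pairs)], [0.0], None)


class TestPyramid:
    def test_factor_one_level_is_original(self, rng):
        v = make_volume(rng.uniform(0, 100, (16, 16, 16)))
        levels = gaussian_pyramid(v, (4, 2, 1))
        assert levels[-1] is v

    def test_constant_volume_stays_constant(self):
        v = make_volume(np.full((16, 16, 16), 55.0))
        for lv in gaussian_pyramid(v, (4, 2, 1)):
            np.testing.assert_allclose(lv.values, 55.0, atol=1e-9)

    def test_level_sizes(self, rng):
        v = make_volume(rng.uniform(0, 1, (16, 16, 16)))
        sizes = [lv.shape for lv in gaussian_pyramid(v, (4, 2, 1))]
        assert sizes == [(4, 4, 4), (8, 8, 8), (16, 16, 16)]

    def test_volume_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            gaussian_pyramid(make_volume(rng.uniform(0, 1, (3, 3, 3))), (4, 2, 1))


def blob_volume(rng, shape=(24, 24, 24), spacing=(2.0, 2.0, 2.0), offset=(0.0, 0.0, 0.0)):
    """Smooth asymmetric blob with a known translation offset (mm)."""
    g = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    )
    c1 = np.array([20.0, 24.0, 20.0]) + offset
    c2 = np.array([30.0, 18.0, 28.0]) + offset
    v = 80 * np.exp(-np.sum((g - c1) ** 2, axis=-1) / 200.0)
    v += 50 * np.exp(-np.sum((g - c2) ** 2, axis=-1) / 80.0)
    return ScalarVolume(v, spacing)


class TestOptimizeStep:
    def test_zero_iterations_keeps_identity(self, rng):
        v = blob_volume(rng)
        term = CostTerm("ssd", fixed=v, moving=v, domain=full_domain(v.shape, v.spacing))
        cfg = RegistrationConfig(
            optimizer=OptimizerSettings(iterations_per_level=0, polish_maxiter=0)
        )
        params = _AffineParams(np.zeros(3), 10.0)
        res = optimize_step([term], [1.0], params, cfg, np.random.default_rng(0))
        assert res.final_cost == pytest.approx(res.initial_cost)
        x = rng.uniform(0, 40, (10, 3))
        np.testing.assert_allclose(res.transform(x), x, atol=1e-12)

    def test_recovers_six_mm_translation(self, rng):
        fixed = blob_volume(rng)
        moving = blob_volume(rng, offset=(6.0, 0.0, 0.0))
        term = CostTerm("ssd", fixed=fixed, moving=moving, domain=full_domain(fixed.shape, fixed.spacing))
        params = _AffineParams(np.array([23.0, 23.0, 23.0]), 20.0)
        cfg = RegistrationConfig()
        res = optimize_step([term], [1.0], params, cfg, np.random.default_rng(3))
        probe = rng.uniform(10, 36, (20, 3))
        shift = res.transform(probe) - probe
        np.testing.assert_allclose(shift.mean(axis=0), [6.0, 0.0, 0.0], atol=1.0)
        assert res.final_cost <= res.initial_cost

    def test_final_cost_never_exceeds_initial(self, rng):
        fixed = blob_volume(rng)
        moving = blob_volume(rng, offset=(4.0, -3.0, 5.0))
        term = CostTerm("ssd", fixed=fixed, moving=moving, domain=full_domain(fixed.shape, fixed.spacing))
        for seed in range(3):
            params = _AffineParams(np.array([23.0, 23.0, 23.0]), 20.0)
            res = optimize_step([term], [1.0], params, RegistrationConfig(), np.random.default_rng(seed))
            assert res.final_cost <= res.initial_cost + 1e-12


class TestBonePairSampling:
    def make_segments(self):
        lab = np.zeros((10, 10, 10))
        lab[:3] = 1
        lab[4:6] = 2
        lab[8:] = 3
        return LabelVolume(lab, (2.0, 2.0, 2.0))

    def test_identity_transforms_give_equal_pairs(self):
        seg = self.make_segments()
        trs = {k: SimilarityTransform() for k in (1, 2, 3)}
        pairs = sample_bone_pairs(seg, trs, 100, np.random.default_rng(0))
        np.testing.assert_allclose(pairs.fixed, pairs.moving)
        assert pairs.provenance == "LM_BONE"

    def test_pair_count(self):
        seg = self.make_segments()
        trs = {k: SimilarityTransform() for k in (1, 2, 3)}
        pairs = sample_bone_pairs(seg, trs, 1000, np.random.default_rng(0))
        assert len(pairs) == 3000

    def test_seed_reproducibility(self):
        seg = self.make_segments()
        trs = {k: SimilarityTransform() for k in (1, 2, 3)}
        a = sample_bone_pairs(seg, trs, 50, np.random.default_rng(7))
        b = sample_bone_pairs(seg, trs, 50, np.random.default_rng(7))
        np.testing.assert_array_equal(a.fixed, b.fixed)
        np.testing.assert_array_equal(a.moving, b.moving)

    def test_points_lie_in_their_segment(self):
        seg = self.make_segments()
        trs = {k: SimilarityTransform() for k in (1, 2, 3)}
        pairs = sample_bone_pairs(seg, trs, 200, np.random.default_rng(1))
        # first 200 points come from segment 1 (x index < 3)
        assert np.all(pairs.fixed[:200, 0] <= 3 * 2.0)


class TestConfigValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(w_bone=(1.0, -0.1))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(w_water=(0.0, 0.0))

    def test_factors_must_decrease_to_one(self):
        with pytest.raises(ValueError):
            RegistrationConfig(pyramid_factors=(4, 2))
        with pytest.raises(ValueError):
            RegistrationConfig(pyramid_factors=(2, 4, 1))


@pytest.mark.filterwarnings("ignore:bone segment")
@pytest.mark.filterwarnings("ignore:only")
class TestWaterStep:
    def test_lm_water_points_have_high_water_signal(self):
        a = generate_subject(SMALL_SPEC, seed=3)
        b = generate_subject(SMALL_SPEC, seed=4)
        cfg = RegistrationConfig(
            seed=0,
            n_water_pairs=500,
            optimizer=OptimizerSettings(iterations_per_level=10, polish_maxiter=0),
        )
        from imiomics.registration import register_bone

        _, lm_bone = register_bone(a.record, b.record, cfg)
        res, lm_water = register_water(a.record, b.record, lm_bone, cfg)
        from imiomics.imagecore import interpolate

        vals = interpolate(a.record.water, lm_water.fixed, mode="nearest")
        assert np.all(vals > 50.0)
        assert lm_water.provenance == "LM_WATER"
        assert res.final_cost <= res.initial_cost + 1e-12
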