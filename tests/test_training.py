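"""Training machinery: the beta-binomial likelihood against an integration
oracle, pixel BCE, the joint loss, augmentation consistency, and early
stopping."""

import numpy as np
import pytest
from scipy import integrate, stats

from cxrcad.model import CasePrediction, CategoryPosterior
from cxrcad.synthdata import CATEGORIES, CaseLabels
from cxrcad.training import (
    AugmentConfig,
    EarlyStopper,
    augment,
    beta_binomial_nll,
    beta_binomial_nll_grad,
    downsample_mask,
    ground_truth_masks,
    joint_loss,
    pixel_bce,
)


def integration_nll_oracle(alpha, beta, k, n):
    """Independent oracle: numerically integrate Binom(k|n,p) Beta(p|a,b)."""
    val, _ = integrate.quad(
        lambda p: stats.binom.pmf(k, n, p) * stats.beta.pdf(p, alpha, beta),
        0.0, 1.0, epsabs=1e-12, epsrel=1e-12)
    return -np.log(val)


class TestBetaBinomialNll:
    @pytest.mark.parametrize("alpha,beta,n,k,expected", [
        (1.0, 1.0, 1, 1, np.log(2)),          # uniform prior, P = 1/2
        (1.0, 1.0, 3, 0, np.log(4)),          # Beta(1,1): k uniform on 0..3
        (1.0, 1.0, 3, 1, np.log(4)),
        (1.0, 1.0, 3, 2, np.log(4)),
        (1.0, 1.0, 3, 3, np.log(4)),
        (5.0, 1.0, 1, 1, -np.log(5 / 6)),     # mean of Beta(5,1) = 5/6
    ])
    def test_closed_form_examples(self, alpha, beta, n, k, expected):
        assert beta_binomial_nll(alpha, beta, k, n) == \
            pytest.approx(expected, abs=1e-12)
        assert integration_nll_oracle(alpha, beta, k, n) == \
            pytest.approx(expected, abs=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_nll(1.0, 1.0, 4, 3)
        with pytest.raises(ValueError):
            beta_binomial_nll(-1.0, 1.0, 1, 3)
        with pytest.raises(ValueError):
            beta_binomial_nll(1.0, 0.0, 1, 3)

    def test_finite_on_extreme_parameters(self):
        vals = beta_binomial_nll(
            np.array([1e-4, 1e4, 1e-4]), np.array([1e4, 1e-4, 1e-4]),
            np.array([0, 3, 2]), np.array([3, 3, 3]))
        assert np.all(np.isfinite(vals))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.uniform(0.1, 20, 2)
            n = int(rng.integers(1, 8))
            k = int(rng.integers(0, n + 1))
            da, db = beta_binomial_nll_grad(a, b, k, n)
            eps = 1e-6
            num_a = (beta_binomial_nll(a + eps, b, k, n)
                     - beta_binomial_nll(a - eps, b, k, n)) / (2 * eps)
            num_b = (beta_binomial_nll(a, b + eps, k, n)
                     - beta_binomial_nll(a, b - eps, k, n)) / (2 * eps)
            assert da == pytest.approx(num_a, rel=1e-5, abs=1e-7)
            assert db == pytest.approx(num_b, rel=1e-5, abs=1e-7)


class TestPixelBce:
    def test_perfect_prediction_bounded_by_clipping(self):
        y = (np.random.default_rng(0).random((6, 7)) > 0.5).astype(float)
        assert pixel_bce(y, y) <= 1.2e-7

    def test_uniform_half_is_ln2(self):
        y = (np.random.default_rng(1).random((5, 5)) > 0.3).astype(float)
        assert pixel_bce(np.full((5, 5), 0.5), y) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_constant_confidence_on_all_positive(self):
        y = np.ones((4, 4))
        assert pixel_bce(np.full((4, 4), 0.9), y) == \
            pytest.approx(-np.log(0.9), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_bce(np.zeros((2, 2)), np.zeros((3, 3)))


def _make_prediction(alphas, betas, maps):
    posts = {c: CategoryPosterior(alphas[i], betas[i])
             for i, c in enumerate(CATEGORIES)}
    return CasePrediction(posteriors=posts, prob_maps=maps)


class TestJointLoss:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(2)
        maps = [np.clip(rng.random((8, 4, 5)), 0.01, 0.99)]
        truth = [(rng.random((8, 4, 5)) > 0.7).astype(float)]
        pred = _make_prediction(rng.uniform(0.5, 5, 8),
                                rng.uniform(0.5, 5, 8), maps)
        labels = CaseLabels(k=np.array([1, 2, 0, 3, 1, 0, 2, 1]),
                            n=np.full(8, 3), boxes=[[] for _ in range(8)])
        return pred, labels, truth

    def test_zero_localization_weight_leaves_pure_nll(self, setup):
        pred, labels, truth = setup
        out = joint_loss(pred, labels, truth, weights=0.0)
        expected = sum(
            float(beta_binomial_nll(pred.posteriors[c].alpha,
                                    pred.posteriors[c].beta,
                                    int(labels.k[i]), int(labels.n[i])))
            for i, c in enumerate(CATEGORIES))
        assert out["total"] == pytest.approx(expected, rel=1e-12)
        assert out["bce"] == 0.0

    def test_breakdown_sums_to_total(self, setup):
        pred, labels, truth = setup
        out = joint_loss(pred, labels, truth, weights=2.5)
        assert out["total"] == pytest.approx(out["bce"] + out["nll"])
        assert out["total"] == pytest.approx(
            sum(v["weighted"] for v in out["per_category"].values()))

    def test_perfect_predictions_reach_nll_grid_minimum(self):
        """With exact maps and (alpha, beta) at the NLL minimizer found by a
        grid-search oracle, the joint loss is within epsilon of the summed
        minima."""
        k, n = 2, 3
        grid = np.linspace(0.05, 60, 400)
        nll_grid = beta_binomial_nll(grid[:, None], grid[None, :], k, n)
        best = float(nll_grid.min())
        ia, ib = np.unravel_index(nll_grid.argmin(), nll_grid.shape)
        truth = [(np.random.default_rng(3).random((8, 4, 5)) > 0.5
                  ).astype(float)]
        pred = _make_prediction(np.full(8, grid[ia]), np.full(8, grid[ib]),
                                [truth[0].copy()])
        labels = CaseLabels(k=np.full(8, k), n=np.full(8, n),
                            boxes=[[] for _ in range(8)])
        out = joint_loss(pred, labels, truth, weights=1.0)
        assert out["nll"] == pytest.approx(8 * best, abs=1e-6)
        assert out["bce"] <= 8 * 1.2e-7


class TestAugment:
    @pytest.fixture
    def sample(self):
        rng = np.random.default_rng(4)
        img = rng.random((32, 40))
        masks = np.zeros((8, 32, 40))
        masks[2, 5:12, 8:20] = 1.0
        return img, masks

    def test_all_probabilities_zero_is_identity(self, sample):
        img, masks = sample
        out_img, out_masks = augment(img, masks, 0, AugmentConfig.disabled())
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_masks, masks)

    def test_horizontal_flip_mirrors_masks(self, sample):
        img, masks = sample
        cfg = AugmentConfig(p_hflip=1.0, p_vflip=0, p_rotate=0, p_gamma=0,
                            p_contrast=0, p_crop=0)
        out_img, out_masks = augment(img, masks, 0, cfg)
        np.testing.assert_array_equal(out_img, img[:, ::-1])
        np.testing.assert_array_equal(out_masks, masks[:, :, ::-1])

    def test_identity_intensity_parameters(self, sample):
        img, masks = sample
        cfg = AugmentConfig(p_hflip=0, p_vflip=0, p_rotate=0, p_crop=0,
                            p_gamma=1.0, gamma_range=(1.0, 1.0),
                            p_contrast=1.0, contrast_range=(1.0, 1.0))
        out_img, _ = augment(img, masks, 0, cfg)
        np.testing.assert_allclose(out_img, img, atol=1e-12)

    def test_geometry_applies_identically_to_image_and_mask(self, sample):
        img, masks = sample
        # use the mask itself as the image: they must stay aligned
        cfg = AugmentConfig(p_hflip=0.5, p_vflip=0.5, p_rotate=1.0,
                            p_gamma=0, p_contrast=0, p_crop=1.0)
        out_img, out_masks = augment(masks[2], masks, 12, cfg)
        overlap = (out_img > 0.5) == (out_masks[2] > 0.5)
        assert overlap.mean() > 0.98  # interpolation-order edge effects only

    def test_output_shape_preserved_under_crop(self, sample):
        img, masks = sample
        cfg = AugmentConfig(p_hflip=0, p_vflip=0, p_rotate=0, p_gamma=0,
                            p_contrast=0, p_crop=1.0)
        out_img, out_masks = augment(img, masks, 3, cfg)
        assert out_img.shape == img.shape
        assert out_masks.shape == masks.shape

    def test_reference_standard_untouched_by_augmentation(self, sample):
        """Augmentation changes pixels, never the k-of-n labels."""
        labels = CaseLabels(k=np.array([0, 0, 2, 0, 0, 0, 0, 0]),
                            n=np.full(8, 3), boxes=[[] for _ in range(8)])
        before = labels.reference.copy()
        augment(*sample, 5)
        np.testing.assert_array_equal(labels.reference, before)


class TestGroundTruthMasks:
    def test_positive_pixels_exactly_inside_boxes(self):
        labels = CaseLabels(
            k=np.array([1, 0, 0, 0, 0, 0, 0, 0]), n=np.full(8, 3),
            boxes=[[(0, (2, 3, 5, 9))]] + [[] for _ in range(7)])
        masks = ground_truth_masks(labels, [(16, 16)])
        expected = np.zeros((16, 16))
        expected[2:5, 3:9] = 1
        np.testing.assert_array_equal(masks[0][0], expected)
        assert masks[0][1:].sum() == 0

    def test_downsample_is_block_max(self):
        mask = np.zeros((1, 16, 16))
        mask[0, 3, 3] = 1
        out = downsample_mask(mask, (4, 4))
        assert out[0, 0, 0] == 1 and out.sum() == 1


class TestEarlyStopper:
    def test_monotone_degrading_stops_after_patience(self):
        """Best at epoch 1, ten non-improving epochs => stop at epoch 11."""
        stopper = EarlyStopper(patience=10)
        stopped_at = None
        for epoch in range(1, 100):
            if stopper.update(epoch, 1.0 - 0.01 * epoch):
                stopped_at = epoch
                break
        assert stopped_at == 11
        assert stopper.best_epoch == 1

    def test_improvement_resets_the_clock(self):
        stopper = EarlyStopper(patience=3)
        seq = [0.5, 0.4, 0.6, 0.55, 0.5, 0.45]  # best at epoch 3
        stops = [stopper.update(e + 1, m) for e, m in enumerate(seq)]
        assert stops == [False, False, False, False, False, True]
        assert stopper.best_metric == 0.6
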