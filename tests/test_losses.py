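"""Loss functions: analytic endpoints, decompositions, and gradient checks."""

import numpy as np
import pytest

from bladderseg import losses as L
from bladderseg.losses import LossWeights
from bladderseg.networks import LatentParams
from bladderseg.patching import PretrainPair


@pytest.fixture
def w():
    return LossWeights()


def one_hot(label, c=4):
    return (label[None] == np.arange(c)[:, None, None]).astype(np.float64)


class TestSelfSupervisedLosses:
    def test_contrast_zero_at_identity_and_symmetric(self, rng):
        r = rng.random((16, 16))
        assert L.contrast_consistency_loss(r, r) == 0.0
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert L.contrast_consistency_loss(a, b) == pytest.approx(
            L.contrast_consistency_loss(b, a))

    def test_contrast_mean_convention(self):
        r1, r2 = np.ones((8, 8)), np.zeros((8, 8))
        assert L.contrast_consistency_loss(r1, r2) == pytest.approx(1.0)
        assert L.contrast_consistency_loss(r1, r2, reduction="sum") == pytest.approx(64.0)

    def test_reconstruction_observation_values(self, rng):
        x = rng.random((8, 8))
        assert L.reconstruction_observation_loss(x, x, x) == 0.0
        assert L.reconstruction_observation_loss(x, x + 0.5, x) == pytest.approx(0.5)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert L.reconstruction_observation_loss(a, b, x) == pytest.approx(
            L.reconstruction_observation_loss(b, a, x))

    def test_self_supervised_decomposes(self, rng):
        x, r1, r2 = (rng.random((8, 8)) for _ in range(3))
        pair = PretrainPair(original=x, view1=x, view2=x, holes1=[], holes2=[])
        total = L.self_supervised_loss(pair, r1, r2)
        assert total == pytest.approx(L.contrast_consistency_loss(r1, r2)
                                      + L.reconstruction_observation_loss(r1, r2, x))
        assert total >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            L.contrast_consistency_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestFocalLoss:
    def test_perfect_one_hot_prediction_is_zero(self, w, rng):
        label = rng.integers(0, 4, (8, 8))
        assert L.focal_loss(one_hot(label), label, w) == pytest.approx(0.0, abs=1e-6)

    def test_single_wall_pixel_closed_form(self, w):
        # -alpha_wall * (1-p)^gamma * ln p at p=0.5: 0.6 * 0.25 * ln 2
        label = np.array([[2]])
        prob = np.array([[[0.5]], [[0.0]], [[0.5]], [[0.0]]])
        expected = 0.6 * 0.25 * np.log(2.0)
        assert L.focal_loss(prob, label, w) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.10397, abs=1e-5)

    def test_linear_in_alpha(self, rng):
        label = np.full((6, 6), 2)
        prob = np.full((4, 6, 6), 0.25)
        l1 = L.focal_loss(prob, label, LossWeights(alpha_wall=0.3))
        l2 = L.focal_loss(prob, label, LossWeights(alpha_wall=0.6))
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_zero_probability_clamped_not_nan(self, w):
        label = np.array([[1]])
        prob = np.zeros((4, 1, 1))
        prob[0] = 1.0
        val = L.focal_loss(prob, label, w)
        assert np.isfinite(val) and val > 0

    def test_gamma_zero_unit_alpha_is_cross_entropy(self, rng):
        label = rng.integers(0, 4, (8, 8))
        prob = rng.dirichlet(np.ones(4), size=(8, 8)).transpose(2, 0, 1)
        weights = LossWeights(alpha_background=1.0, alpha_urine=1.0,
                              alpha_wall=1.0, alpha_tumor=1.0, gamma=0.0)
        pt = np.take_along_axis(prob, label[None], axis=0)[0]
        assert L.focal_loss(prob, label, weights) == pytest.approx(
            float(-np.log(pt).mean()), rel=1e-9)


class TestDiceLoss:
    def test_perfect_match_is_zero(self, rng):
        label = rng.integers(0, 4, (10, 10))
        assert L.dice_loss(one_hot(label), label, epsilon=1e-9) == pytest.approx(0.0, abs=1e-7)

    def test_disjoint_masks_approach_one(self):
        label = np.zeros((4, 4), dtype=int)
        label[:2] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[2:] = 1
        assert L.dice_loss(pred, label, epsilon=1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap(self):
        # 1 px overlap, |x| = |y| = 2 -> 1 - 2*1/4 = 0.5
        label = np.zeros((1, 4), dtype=int)
        label[0, :2] = 1
        pred = np.zeros((1, 4), dtype=int)
        pred[0, 1:3] = 1
        assert L.dice_loss(pred, label, epsilon=1e-12) == pytest.approx(0.5, abs=1e-6)

    def test_agrees_with_one_minus_dsc_on_binary_masks(self, rng):
        from bladderseg.metrics import dsc
        for _ in range(200):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            if not a.any() or not b.any():
                continue
            dl = L.dice_loss(a.astype(int), b.astype(int), epsilon=1e-12, classes=(1,))
            assert dl == pytest.approx(1.0 - dsc(a, b), abs=1e-6)

    def test_absent_class_skipped(self):
        label = np.zeros((4, 4), dtype=int)
        label[0, 0] = 1  # no wall, no tumor present
        assert L.dice_loss(one_hot(label), label, epsilon=1e-9) == pytest.approx(0.0, abs=1e-7)


class TestComposites:
    def test_dice_focal_is_exact_sum(self, w, rng):
        label = rng.integers(0, 4, (8, 8))
        prob = rng.dirichlet(np.ones(4), size=(8, 8)).transpose(2, 0, 1)
        assert L.dice_focal_loss(prob, label, w) == pytest.approx(
            L.focal_loss(prob, label, w)
            + L.dice_loss(prob, label, w.epsilon, w.foreground_classes), rel=1e-12)

    def test_kl_closed_form(self):
        assert L.kl_standard_normal(LatentParams(np.zeros(3), np.zeros(3))) == 0.0
        assert L.kl_standard_normal(
            LatentParams(np.array([1.0]), np.array([0.0]))) == pytest.approx(0.5)

    def test_kl_matches_monte_carlo(self, rng):
        # independent oracle: E_q[log q(z) - log p(z)] by simulation
        mu, sigma = 0.7, 1.3
        z = rng.normal(mu, sigma, size=200_000)
        logq = -0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        logp = -0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)
        mc = float((logq - logp).mean())
        closed = L.kl_standard_normal(
            LatentParams(np.array([mu]), np.array([2 * np.log(sigma)])))
        assert closed == pytest.approx(mc, abs=0.02)

    def test_kl_nonnegative(self, rng):
        for _ in range(50):
            lat = LatentParams(rng.normal(size=5), rng.normal(size=5))
            assert L.kl_standard_normal(lat) >= 0.0

    def test_vae_loss_decomposes(self, rng):
        t, r = rng.random((4, 4)), rng.random((4, 4))
        lat = LatentParams(rng.normal(size=3), rng.normal(size=3))
        assert L.vae_loss(t, r, lat) == pytest.approx(
            float(((t - r) ** 2).mean()) + L.kl_standard_normal(lat), rel=1e-12)
        assert L.vae_loss(t, t, LatentParams(np.zeros(3), np.zeros(3))) == 0.0


class TestSemiLoss:
    def _outputs(self, rng, n):
        probs = rng.dirichlet(np.ones(4), size=(n, 8, 8)).transpose(0, 3, 1, 2)
        return {
            "probs": probs,
            "latent": LatentParams(rng.normal(size=(n, 3)), rng.normal(size=(n, 3))),
            "vae_recon": rng.random((n, 2, 2, 2)),
            "vae_target": rng.random((n, 2, 2, 2)),
        }

    def test_all_labeled_equals_dfl_plus_val(self, w, rng):
        labels = [rng.integers(0, 4, (8, 8)) for _ in range(3)]
        batch = [(None, lab) for lab in labels]
        out = self._outputs(rng, 3)
        expected_dfl = np.mean([L.dice_focal_loss(out["probs"][i], labels[i], w)
                                for i in range(3)])
        expected_val = L.vae_loss(out["vae_target"], out["vae_recon"], out["latent"])
        assert L.semi_loss(batch, out, w) == pytest.approx(expected_dfl + expected_val)

    def test_all_unlabeled_is_vae_only(self, w, rng):
        batch = [(None, None)] * 3
        out = self._outputs(rng, 3)
        assert L.semi_loss(batch, out, w) == pytest.approx(
            L.vae_loss(out["vae_target"], out["vae_recon"], out["latent"]))

    def test_empty_batch_rejected(self, w, rng):
        with pytest.raises(ValueError, match="empty"):
            L.semi_loss([], self._outputs(rng, 0), w)


class TestGradients:
    """Finite-difference checks of the training-loop gradient helpers."""

    def test_dice_focal_grad_matches_finite_differences(self, w, rng):
        probs = rng.dirichlet(np.ones(4), size=(2, 4, 4)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 4, (2, 4, 4))
        mask = np.array([True, True])
        loss0, grad = L.dice_focal_grad(probs, labels, w, mask)
        eps = 1e-6
        for _ in range(20):
            i, c, y, x = (rng.integers(0, s) for s in probs.shape)
            p = probs.copy()
            p[i, c, y, x] += eps
            loss1, _ = L.dice_focal_grad(p, labels, w, mask)
            fd = (loss1 - loss0) / eps
            assert grad[i, c, y, x] == pytest.approx(fd, rel=2e-3, abs=1e-6)

    def test_dice_focal_grad_zero_at_unlabeled_rows(self, w, rng):
        probs = rng.dirichlet(np.ones(4), size=(2, 4, 4)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 4, (2, 4, 4))
        _, grad = L.dice_focal_grad(probs, labels, w, np.array([True, False]))
        assert (grad[1] == 0).all() and (grad[0] != 0).any()

    def test_vae_grad_matches_finite_differences(self, rng):
        t = rng.random((2, 3, 2, 2)).astype(np.float64)
        r = rng.random((2, 3, 2, 2)).astype(np.float64)
        mu = rng.normal(size=(2, 4))
        lv = rng.normal(size=(2, 4))
        loss0, d_r, d_mu, d_lv = L.vae_grad(t, r, mu, lv)
        eps = 1e-6
        r2 = r.copy()
        r2[1, 2, 0, 1] += eps
        assert d_r[1, 2, 0, 1] == pytest.approx(
            (L.vae_grad(t, r2, mu, lv)[0] - loss0) / eps, rel=1e-4)
        mu2 = mu.copy()
        mu2[0, 3] += eps
        assert d_mu[0, 3] == pytest.approx(
            (L.vae_grad(t, r, mu2, lv)[0] - loss0) / eps, rel=1e-4)
        lv2 = lv.copy()
        lv2[1, 0] += eps
        assert d_lv[1, 0] == pytest.approx(
            (L.vae_grad(t, r, mu, lv2)[0] - loss0) / eps, rel=1e-4)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(alpha_wall=0.0)
    with pytest.raises(ValueError):
        LossWeights(gamma=-1.0)
    with pytest.raises(ValueError):
        LossWeights(reduction="median")
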