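"""Loss identities, formula oracles, and gradient routing."""

import numpy as np
import pytest

from isorestore.autodiff import Tensor
from isorestore.losses import (LossWeights, charbonnier, cycle_loss,
                               deblur_loss, degrade_objective,
                               gaussian_window, lsgan_losses, ssim, ssim_loss)
from isorestore.nets import (DiscriminatorSpec, RestorerSpec, build_bundle,
                             frozen)


class _ConstMap:
    """Stub discriminator returning a constant map."""

    def __init__(self, value):
        self.value = value

    def __call__(self, t):
        n, _, h, w = t.data.shape
        return Tensor(np.full((n, 1, h // 2, w // 2), self.value,
                              dtype=np.float32))


class _Identity:
    def __call__(self, t):
        return t * 1.0


class _Scale:
    def __init__(self, k):
        self.k = k

    def __call__(self, t):
        return t * self.k


class TestCharbonnier:
    def test_equal_inputs_give_exactly_eps(self, rng):
        a = rng.uniform(0, 1, (2, 1, 8, 8)).astype(np.float32)
        val = float(charbonnier(a, a.copy(), eps=1e-3).data)
        assert val == pytest.approx(1e-3, rel=1e-6)

    def test_zero_eps_is_mean_absolute_difference(self, rng):
        a = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        b = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        assert float(charbonnier(a, b, eps=0.0).data) == pytest.approx(
            np.abs(a - b).mean(), rel=1e-6)

    def test_matches_elementwise_oracle(self, rng):
        eps = 1e-3
        a = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        b = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        ref = np.mean(np.sqrt((a.astype(np.float64) - b) ** 2 + eps**2))
        assert float(charbonnier(a, b, eps).data) == pytest.approx(ref, rel=1e-6)

    def test_floor_attained_only_at_equality(self, rng):
        a = rng.uniform(0, 1, (4, 4)).astype(np.float32)
        b = a.copy()
        b[0, 0] += 0.1
        assert float(charbonnier(a, b, 1e-3).data) > 1e-3


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        a = rng.uniform(0, 1, (16, 16)).astype(np.float32)
        assert float(ssim(a, a).data) == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_scores_near_zero(self, rng):
        a = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        b = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        assert float(ssim(a, b).data) < 0.1

    def test_single_window_matches_direct_formula(self, rng):
        """One 8x8 uniform window: the windowed statistics collapse to plain
        means/covariance, so the value equals the closed-form expression."""
        a = rng.uniform(0, 1, (8, 8)).astype(np.float64)
        b = rng.uniform(0, 1, (8, 8)).astype(np.float64)
        win = np.ones((8, 8), dtype=np.float32) / 64.0
        got = float(ssim(a.astype(np.float32), b.astype(np.float32),
                         window=win).data)
        c1, c2 = 0.01**2, 0.03**2
        mu_a, mu_b = a.mean(), b.mean()
        var_a, var_b = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        ref = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
               / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)))
        assert got == pytest.approx(ref, abs=1e-5)

    def test_matches_skimage_oracle(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.uniform(0, 1, (32, 32)).astype(np.float32)
        b = np.clip(a + rng.normal(0, 0.1, (32, 32)), 0, 1).astype(np.float32)
        ref = structural_similarity(a, b, gaussian_weights=True,
                                    use_sample_covariance=False,
                                    data_range=1.0)
        assert float(ssim(a, b).data) == pytest.approx(ref, abs=1e-5)

    def test_window_is_unit_sum(self):
        assert gaussian_window().sum() == pytest.approx(1.0, abs=1e-7)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.uniform(0, 1, (16, 16)), rng.uniform(0, 1, (16, 17)))


class TestLSGAN:
    def _batches(self, rng, n=2, size=16):
        y = Tensor(rng.uniform(0, 1, (n, 1, size, size)).astype(np.float32))
        z = Tensor(rng.uniform(0, 1, (n, 1, size, size)).astype(np.float32))
        return y, z

    def test_perfect_discriminator_zeroes_l_d(self, rng):
        y, z = self._batches(rng)

        class PerfectD:
            def __init__(self):
                self.real = {id(y.data), id(z.data)}

            def __call__(self, t):
                n, _, h, w = t.data.shape
                val = 1.0 if id(t.data) in self.real else 0.0
                return Tensor(np.full((n, 1, h, w), val, dtype=np.float32))

        _, l_d = lsgan_losses(PerfectD(), PerfectD(), _Identity(), _Identity(),
                              y, z)
        assert float(l_d.data) == pytest.approx(0.0, abs=1e-12)

    def test_fooled_discriminator_zeroes_l_g(self, rng):
        y, z = self._batches(rng)
        l_g, _ = lsgan_losses(_ConstMap(1.0), _ConstMap(1.0), _Identity(),
                              _Identity(), y, z)
        assert float(l_g.data) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computation(self, rng):
        """Fixed tiny tensors and affine stub networks against the explicit
        four-term least-squares expression."""
        y, z = self._batches(rng, n=1, size=4)
        d_val = 0.3
        l_g, l_d = lsgan_losses(_ConstMap(d_val), _ConstMap(d_val),
                                _Scale(0.5), _Scale(2.0), y, z)
        assert float(l_g.data) == pytest.approx(2 * (d_val - 1) ** 2, rel=1e-5)
        # fakes and reals all score 0.3: two (0.3)^2 and two (0.3-1)^2 terms
        assert float(l_d.data) == pytest.approx(
            2 * d_val**2 + 2 * (d_val - 1) ** 2, rel=1e-5)

    def test_empty_batch_rejected(self):
        y = Tensor(np.empty((0, 1, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            lsgan_losses(_ConstMap(1), _ConstMap(1), _Identity(), _Identity(),
                         y, y)


class TestCycleAndDeblur:
    def test_identity_generators_hit_charbonnier_floor(self, rng):
        y = Tensor(rng.uniform(0, 1, (2, 1, 8, 8)).astype(np.float32))
        z = Tensor(rng.uniform(0, 1, (2, 1, 8, 8)).astype(np.float32))
        val = float(cycle_loss(_Identity(), _Identity(), y, z, eps=1e-3).data)
        assert val == pytest.approx(2e-3, rel=1e-5)

    def test_cycle_uses_charbonnier_not_l1(self, rng):
        """With eps > 0 the loss exceeds plain L1 of the same residuals."""
        y = Tensor(rng.uniform(0.2, 0.8, (1, 1, 8, 8)).astype(np.float32))
        z = Tensor(rng.uniform(0.2, 0.8, (1, 1, 8, 8)).astype(np.float32))
        g_a, g_b = _Scale(1.1), _Scale(0.9)
        val = float(cycle_loss(g_a, g_b, y, z, eps=1e-2).data)
        l1 = (np.abs(0.99 * y.data - y.data).mean()
              + np.abs(0.99 * z.data - z.data).mean())
        assert val > l1

    def test_cycle_matches_formula_oracle(self, rng):
        eps = 1e-3
        y = rng.uniform(0, 1, (1, 1, 6, 6)).astype(np.float32)
        z = rng.uniform(0, 1, (1, 1, 6, 6)).astype(np.float32)
        val = float(cycle_loss(_Scale(2.0), _Scale(0.25), Tensor(y), Tensor(z),
                               eps).data)
        # G_B(G_A(y)) = 0.5 y ; G_A(G_B(z)) = 0.5 z
        ref = (np.mean(np.sqrt((0.5 * y - y) ** 2 + eps**2))
               + np.mean(np.sqrt((0.5 * z - z) ** 2 + eps**2)))
        assert val == pytest.approx(ref, rel=1e-5)

    def test_perfect_deblurrer_scores_eps(self, rng):
        x = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        w = LossWeights(charbonnier_eps=1e-3)
        val = float(deblur_loss(_Identity(), x, x, w).data)
        assert val == pytest.approx(1e-3, rel=1e-4)

    def test_zero_sigma_reduces_to_pure_charbonnier(self, rng):
        d = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        t = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        w0 = LossWeights(sigma_ssim=0.0)
        assert float(deblur_loss(_Identity(), d, t, w0).data) == pytest.approx(
            float(charbonnier(d, t, w0.charbonnier_eps).data), rel=1e-6)

    def test_deblur_matches_composed_oracle(self, rng):
        d = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        t = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        w = LossWeights()
        got = float(deblur_loss(_Identity(), d, t, w).data)
        ref = (float(charbonnier(d, t, w.charbonnier_eps).data)
               + 0.1 * (1 - float(ssim(d, t).data)))
        assert got == pytest.approx(ref, rel=1e-5)


class TestDegradeObjective:
    def test_zero_components_give_zero(self):
        assert float(degrade_objective(0.0, 0.0, 0.0).data) == 0.0

    def test_quoted_coefficients(self):
        w = LossWeights()
        assert float(degrade_objective(1.0, 0.0, 0.0, w).data) == pytest.approx(1.0)
        assert float(degrade_objective(0.0, 1.0, 0.0, w).data) == pytest.approx(0.1)
        assert float(degrade_objective(0.0, 0.0, 1.0, w).data) == pytest.approx(0.1)

    def test_matches_weighted_sum_oracle(self, rng):
        for _ in range(5):
            c, g, f = rng.uniform(0, 2, 3)
            got = float(degrade_objective(c, g, f).data)
            assert got == pytest.approx(c + 0.1 * g + 0.1 * f, rel=1e-5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_gan=-0.1)


class TestGradientRouting:
    @staticmethod
    def _bundle():
        return build_bundle(RestorerSpec(features=4, n_resblocks=1),
                            DiscriminatorSpec(features=(4, 4, 4, 1)), seed=0)

    def test_feedback_loss_freezes_deblurnet(self, rng):
        """The feedback term trains G_A through a frozen H: H receives no
        parameter gradient while G_A does."""
        b = self._bundle()
        y = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        x = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        fake_z = b.g_a(y)
        with frozen(b.h):
            loss = charbonnier(b.h(fake_z), x) + 0.1 * ssim_loss(b.h(fake_z), x)
        loss.backward()
        assert all(p.grad is None for p in b.h.parameters())
        assert any(p.grad is not None and np.abs(p.grad).sum() > 0
                   for p in b.g_a.parameters())

    def test_deblur_loss_freezes_degrader(self, rng):
        """Stage 2 detaches G_A's output: H gets gradients, G_A none."""
        b = self._bundle()
        y = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        x = Tensor(rng.uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        degraded = b.g_a(y).detach()
        deblur_loss(b.h, degraded, x).backward()
        assert all(p.grad is None for p in b.g_a.parameters())
        assert any(p.grad is not None for p in b.h.parameters())
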