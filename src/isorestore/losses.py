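"""Training objectives of the two-stage scheme.

Stage 1 (degradation modelling) minimizes

    L_degrade = L_cycle + lambda * L_GAN + rho * L_feedback

with least-squares adversarial terms, Charbonnier cycle consistency, and a
feedback term that has the form of the deblurring loss but with the
DeblurNet's weights held fixed.  Stage 2 (isotropic recovery) minimizes

    L_deblur = Charbonnier(H(G_A(y)), x) + sigma * (1 - SSIM(H(G_A(y)), x))

All weights default to the published settings (lambda = rho = sigma = 0.1).
Every function accepts ``Tensor`` inputs (differentiable) or plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d


@dataclass
class LossWeights:
    lambda_gan: float = 0.1
    rho_feedback: float = 0.1
    sigma_ssim: float = 0.1
    charbonnier_eps: float = 1e-3

    def __post_init__(self):
        if min(self.lambda_gan, self.rho_feedback, self.sigma_ssim,
               self.charbonnier_eps) < 0:
            raise ValueError("loss weights must be nonnegative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def charbonnier(a, b, eps: float = 1e-3) -> Tensor:
    """Mean over pixels of sqrt((a - b)^2 + eps^2); a smooth, robust L1."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    d = a - b
    return ((d * d + eps * eps).sqrt()).mean()


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Unit-sum 2D Gaussian window used by the windowed SSIM."""
    r = np.arange(size) - size // 2
    g = np.exp(-0.5 * (r / sigma) ** 2)
    w = np.outer(g, g)
    return (w / w.sum()).astype(np.float32)


_DEFAULT_WINDOW = gaussian_window()


def ssim(a, b, c1: float = 0.01**2, c2: float = 0.03**2,
         window: np.ndarray | None = None) -> Tensor:
    """Mean windowed structural similarity, differentiable.

    Inputs are expected on a [0, 1] scale (dynamic range 1), as (H, W),
    (N, H, W) or (N, 1, H, W).  Local statistics use an 11x11 Gaussian window
    (sigma 1.5) and 'valid' coverage, so images must be at least window-sized.
    """
    a4 = _to_nchw(a)
    b4 = _to_nchw(b)
    if a4.shape != b4.shape:
        raise ValueError(f"shape mismatch {a4.shape} vs {b4.shape}")
    win = _DEFAULT_WINDOW if window is None else np.asarray(window, np.float32)
    wk = Tensor(win[None, None])
    mu_a = conv2d(a4, wk)
    mu_b = conv2d(b4, wk)
    ex2 = conv2d(a4 * a4, wk)
    ey2 = conv2d(b4 * b4, wk)
    exy = conv2d(a4 * b4, wk)
    var_a = ex2 - mu_a * mu_a
    var_b = ey2 - mu_b * mu_b
    cov = exy - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    return (num / den).mean()


def _to_nchw(x) -> Tensor:
    t = _as_tensor(x)
    if t.ndim == 2:
        return _reshape(t, (1, 1, *t.shape))
    if t.ndim == 3:
        return _reshape(t, (t.shape[0], 1, *t.shape[1:]))
    return t


def _reshape(t: Tensor, shape) -> Tensor:
    out = Tensor(t.data.reshape(shape), _prev=(t,))

    def _bw(g):
        if t.requires_grad or t._prev:
            t._accumulate(g.reshape(t.data.shape))

    out._backward = _bw
    return out


def ssim_loss(a, b, **kw) -> Tensor:
    return 1.0 - ssim(a, b, **kw)


def _sq_mean(t: Tensor) -> Tensor:
    return (t * t).mean()


def lsgan_losses(d_a, d_b, g_a, g_b, y, z) -> tuple[Tensor, Tensor]:
    """Least-squares adversarial generator and discriminator losses.

    L_G pushes D(G(.)) toward 1; L_D pushes D on fakes toward 0 and on real
    samples toward 1.  Means are taken over the batch and the discriminator
    map pixels.  Fakes are detached inside L_D so discriminator training does
    not back-propagate into the generators.
    """
    y4, z4 = _to_nchw(y), _to_nchw(z)
    if y4.data.shape[0] < 1 or z4.data.shape[0] < 1:
        raise ValueError("empty batch")
    fake_z = g_a(y4)
    fake_y = g_b(z4)
    loss_g = _sq_mean(d_a(fake_z) - 1.0) + _sq_mean(d_b(fake_y) - 1.0)
    loss_d = (
        _sq_mean(d_a(fake_z.detach()))
        + _sq_mean(d_a(z4) - 1.0)
        + _sq_mean(d_b(fake_y.detach()))
        + _sq_mean(d_b(y4) - 1.0)
    )
    return loss_g, loss_d


def cycle_loss(g_a, g_b, y, z, eps: float = 1e-3) -> Tensor:
    """Charbonnier cycle-consistency of both round trips."""
    y4, z4 = _to_nchw(y), _to_nchw(z)
    return charbonnier(g_b(g_a(y4)), y4, eps) + charbonnier(g_a(g_b(z4)), z4, eps)


def deblur_loss(h, degraded, target, weights: LossWeights = LossWeights()) -> Tensor:
    """Charbonnier + sigma * (1 - SSIM) between H(degraded) and the target."""
    d4, t4 = _to_nchw(degraded), _to_nchw(target)
    restored = h(d4)
    out = charbonnier(restored, t4, weights.charbonnier_eps)
    if weights.sigma_ssim > 0:
        out = out + weights.sigma_ssim * ssim_loss(restored, t4)
    return out


def degrade_objective(l_cycle, l_gan_g, l_feedback,
                      weights: LossWeights = LossWeights()) -> Tensor:
    """Full stage-1 objective: L_cycle + lambda*L_GAN + rho*L_feedback."""
    return (_as_tensor(l_cycle) + weights.lambda_gan * _as_tensor(l_gan_g)
            + weights.rho_feedback * _as_tensor(l_feedback))
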