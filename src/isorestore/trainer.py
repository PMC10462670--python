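"""Two-stage alternating optimization.

Each iteration performs:

* stage 1 (degradation modelling): the generator objective
  ``L_cycle + lambda*L_GAN + rho*L_feedback`` is stepped **twice** (the
  feedback term runs the deblurring loss with the DeblurNet frozen), then the
  discriminators are stepped **once** on the least-squares loss;
* stage 2 (isotropic recovery): the DeblurNet is stepped once on the
  Charbonnier + SSIM deblurring loss with the degrader frozen, pairing the
  synthesized degraded lateral patch ``G_A(y_i)`` with its sharp original
  ``x_i``.

Adam (beta1=0.5, beta2=0.999) with lr 1e-4 halved every 20 epochs; batches of
eight 64x64 patches; one epoch is a fixed budget of 600 randomly sampled
iterations (40 epochs ~ 24,000 iterations at the published scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor
from .losses import LossWeights, charbonnier, deblur_loss, ssim_loss
from .nets import (DiscriminatorSpec, NetworkBundle, RestorerSpec,
                   build_bundle, build_restorer, frozen)
from .restore import RestoreRequest, restore_volume, rl_deconvolve
from .volio import SliceSets, normalize, sample_patches
from .volume import PSFKernel, Volume3D


@dataclass
class TrainConfig:
    """Optimization schedule and problem sizes; published defaults."""

    lr: float = 1e-4
    lr_halflife_epochs: int = 20
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 40
    iterations_per_epoch: int = 600
    batch: int = 8
    patch: int = 64
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    augment: bool = True
    features: int = 64
    n_resblocks: int = 6
    disc_features: tuple[int, ...] = (64, 128, 256, 1)
    log_every: int = 50
    rl_iters: int = 5

    def __post_init__(self):
        if min(self.epochs, self.iterations_per_epoch, self.batch,
               self.patch) < 1:
            raise ValueError("counts must be positive")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index (halved every 20 epochs)."""
        return self.lr * 0.5 ** (epoch // self.lr_halflife_epochs)

    def restorer_spec(self) -> RestorerSpec:
        return RestorerSpec(features=self.features, n_resblocks=self.n_resblocks)

    def disc_spec(self) -> DiscriminatorSpec:
        return DiscriminatorSpec(features=tuple(self.disc_features))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["betas"] = list(self.betas)
        d["disc_features"] = list(self.disc_features)
        return d


def _check_finite(value: float, name: str, iteration: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"training diverged: {name} became non-finite at iteration "
            f"{iteration}; lower the learning rate or check normalization"
        )


def _sq_mean(t: Tensor) -> Tensor:
    return (t * t).mean()


def train_selfnet(sets: SliceSets, cfg: TrainConfig,
                  stage1_only: bool = False) -> tuple[NetworkBundle, list[dict]]:
    """Alternate degradation modelling and isotropic recovery; see module doc.

    Returns the trained bundle and a per-iteration loss history.  With
    ``stage1_only`` the DeblurNet is never updated (used to probe what the
    degradation stage learns on its own).
    """
    bundle = build_bundle(cfg.restorer_spec(), cfg.disc_spec(), seed=cfg.seed)
    w = cfg.weights
    opt_g = Adam(bundle.g_a.parameters() + bundle.g_b.parameters(),
                 lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(bundle.d_a.parameters() + bundle.d_b.parameters(),
                 lr=cfg.lr, betas=cfg.betas)
    opt_h = Adam(bundle.h.parameters(), lr=cfg.lr, betas=cfg.betas)
    stream = sample_patches(sets, cfg.patch, cfg.batch, cfg.augment, cfg.seed)
    history: list[dict] = []
    it = 0
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        opt_g.lr = opt_d.lr = opt_h.lr = lr
        for _ in range(cfg.iterations_per_epoch):
            batch = next(stream)
            x = Tensor(batch["x"])
            y = Tensor(batch["y"])
            z = Tensor(batch["z"])

            # --- stage 1: generators stepped twice ---
            fake_z_data = None
            fake_y_data = None
            l_degrade_val = 0.0
            for _g in range(2):
                opt_g.zero_grad()
                fake_z = bundle.g_a(y)
                rec_y = bundle.g_b(fake_z)
                fake_y = bundle.g_b(z)
                rec_z = bundle.g_a(fake_y)
                l_cycle = (charbonnier(rec_y, y, w.charbonnier_eps)
                           + charbonnier(rec_z, z, w.charbonnier_eps))
                with frozen(bundle.d_a, bundle.d_b):
                    l_gan_g = (_sq_mean(bundle.d_a(fake_z) - 1.0)
                               + _sq_mean(bundle.d_b(fake_y) - 1.0))
                l_degrade = l_cycle + w.lambda_gan * l_gan_g
                if w.rho_feedback > 0:
                    with frozen(bundle.h):
                        restored = bundle.h(fake_z)
                        l_fb = charbonnier(restored, x, w.charbonnier_eps)
                        if w.sigma_ssim > 0:
                            l_fb = l_fb + w.sigma_ssim * ssim_loss(restored, x)
                    l_degrade = l_degrade + w.rho_feedback * l_fb
                l_degrade.backward()
                opt_g.step()
                l_degrade_val = float(l_degrade.data)
                fake_z_data = fake_z.data
                fake_y_data = fake_y.data

            # --- stage 1: discriminators stepped once ---
            opt_d.zero_grad()
            l_d = (_sq_mean(bundle.d_a(Tensor(fake_z_data)))
                   + _sq_mean(bundle.d_a(z) - 1.0)
                   + _sq_mean(bundle.d_b(Tensor(fake_y_data)))
                   + _sq_mean(bundle.d_b(y) - 1.0))
            l_d.backward()
            opt_d.step()

            # --- stage 2: DeblurNet stepped once, degrader frozen ---
            l_h_val = float("nan")
            if not stage1_only:
                opt_h.zero_grad()
                l_h = deblur_loss(bundle.h, Tensor(fake_z_data), x, w)
                l_h.backward()
                opt_h.step()
                l_h_val = float(l_h.data)
                _check_finite(l_h_val, "L_deblur", it)

            _check_finite(l_degrade_val, "L_degrade", it)
            _check_finite(float(l_d.data), "L_D", it)
            history.append({
                "iteration": it, "epoch": epoch, "lr": lr,
                "l_degrade": l_degrade_val, "l_d": float(l_d.data),
                "l_deblur": l_h_val,
                "steps_g": opt_g.step_count, "steps_d": opt_d.step_count,
                "steps_h": opt_h.step_count,
            })
            it += 1
    return bundle, history


def train_supervised(pairs: tuple[np.ndarray, np.ndarray], cfg: TrainConfig):
    """Train a lone DeblurNet on aligned (degraded, target) slices.

    This is the supervised baseline: the degradation is modelled analytically
    (semisynthetic pairs) rather than learned, and only the deblurring loss is
    optimized.  Returns (network, history).
    """
    degraded, target = pairs
    degraded = np.asarray(degraded, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if degraded.shape != target.shape:
        raise ValueError("pairs must be aligned with equal shapes")
    sets = SliceSets(X=target, Y=degraded, Z=[target[0]],
                     aniso_factor=1.0)
    stream = sample_patches(sets, cfg.patch, cfg.batch, cfg.augment, cfg.seed)
    net = build_restorer(cfg.restorer_spec(), np.random.default_rng(cfg.seed))
    opt = Adam(net.parameters(), lr=cfg.lr, betas=cfg.betas)
    history: list[dict] = []
    it = 0
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        for _ in range(cfg.iterations_per_epoch):
            batch = next(stream)
            opt.zero_grad()
            loss = deblur_loss(net, Tensor(batch["y"]), Tensor(batch["x"]),
                               cfg.weights)
            loss.backward()
            opt.step()
            val = float(loss.data)
            _check_finite(val, "L_deblur", it)
            history.append({"iteration": it, "epoch": epoch, "lr": opt.lr,
                            "l_deblur": val, "steps": opt.step_count})
            it += 1
    return net, history


def selfnetplus_pairs(vol: Volume3D, bundle: NetworkBundle, psf: PSFKernel,
                      rl_iters: int = 5, norm_record=None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Build the deconvolution-stage training pairs.

    Index-aligned (raw axial slice, RL-deconvolved DeblurNet output) images:
    the raw volume is axially interpolated to isotropic sampling, restored by
    the trained DeblurNet, deconvolved slice-wise with the PSF, and each raw
    interpolated axial slice is paired with its processed counterpart.
    """
    if psf is None:
        raise ValueError(
            "a PSF is required; crop one from an isolated point source with "
            "restore.crop_psf_from_slice"
        )
    if norm_record is None:
        vol01, norm_record = normalize(vol)
    else:
        vol01 = Volume3D(norm_record.apply(vol.data), vol.spacing)
    req = RestoreRequest(volume=vol01, net=bundle.h, orientation="xz")
    restored = restore_volume(req)
    # the network input (axially interpolated raw data), recomputed for pairing
    from .resample import upsample_axis

    new_nz = int(round(vol01.shape[0] * vol01.anisotropy_factor))
    raw_up = (upsample_axis(vol01.data, 0, new_nz).astype(np.float32)
              if new_nz != vol01.shape[0] else vol01.data.copy())
    raw_slices = raw_up.transpose(1, 0, 2)       # (ny, nz', nx) xz slices
    rest_slices = restored.data.transpose(1, 0, 2)
    targets = np.stack([
        rl_deconvolve(np.clip(s, 0.0, None), psf, rl_iters).astype(np.float32)
        for s in rest_slices
    ])
    return raw_slices.astype(np.float32), targets


def train_selfnetplus(vol: Volume3D, bundle: NetworkBundle, psf: PSFKernel,
                      cfg: TrainConfig, norm_record=None):
    """Train DeconvNet to map raw axial slices straight to deconvolved,
    restored slices (one-pass replacement for DeblurNet + RL at inference).

    Returns (deconv_net, history); the net is also attached to the bundle.
    """
    raw_slices, targets = selfnetplus_pairs(vol, bundle, psf,
                                            rl_iters=cfg.rl_iters,
                                            norm_record=norm_record)
    net, history = train_supervised((raw_slices, targets), cfg)
    bundle.deconv = net
    return net, history
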