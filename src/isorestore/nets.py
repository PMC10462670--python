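"""Network architectures for the two-stage restoration scheme.

All restoration networks (the two generators of the degradation-modelling
stage, the DeblurNet and the optional DeconvNet) share one fully convolutional
residual architecture that preserves the input size: a three-conv head, six
residual blocks, and a three-conv tail; 7x7 kernels at the very first and last
layer, 3x3 elsewhere, LeakyReLU(0.2) activations, no normalization layers.
The discriminators follow the PatchGAN design: four 4x4 convolutions with
strides 2,2,1,1 and feature widths 64,128,256,1, instance-normalized after the
second and third, giving each output pixel a 34x34 receptive field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from contextlib import contextmanager
from pathlib import Path

import numpy as np

from .autodiff import Tensor, conv2d


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class RestorerSpec:
    in_channels: int = 1
    out_channels: int = 1
    features: int = 64
    n_resblocks: int = 6
    edge_kernel: int = 7   # first and last convolution
    inner_kernel: int = 3  # every other convolution
    slope: float = 0.2

    def __post_init__(self):
        if self.in_channels != 1 or self.out_channels != 1:
            raise ValueError("restorers are single-channel in and out")
        if self.edge_kernel % 2 == 0 or self.inner_kernel % 2 == 0:
            raise ValueError("kernels must be odd to preserve the image size")

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass(frozen=True)
class DiscriminatorSpec:
    features: tuple[int, ...] = (64, 128, 256, 1)
    kernel: int = 4
    strides: tuple[int, ...] = (2, 2, 1, 1)
    padding: int = 1
    slope: float = 0.2
    norm_layers: tuple[int, ...] = (1, 2)  # instance norm after these convs (0-based)

    def __post_init__(self):
        if len(self.features) != len(self.strides):
            raise ValueError("features and strides must align")

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------
class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """Zero-padded convolution; weights ~ N(0, 0.02), biases zero."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        self.w = Tensor(rng.normal(0.0, 0.02, (out_ch, in_ch, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        return self.gamma * (centered / (var + self.eps).sqrt()) + self.beta


class ResidualBlock(Module):
    """y = x + LeakyReLU(Conv2(LeakyReLU(Conv1(x))))"""

    def __init__(self, features: int, kernel: int, slope: float,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(features, features, kernel, rng=rng)
        self.conv2 = Conv2d(features, features, kernel, rng=rng)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).leaky_relu(self.slope)
        h = self.conv2(h).leaky_relu(self.slope)
        return x + h


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class IdentityRestorer(Module):
    """A parameter-free stand-in network that returns its input unchanged.

    Used to test inference plumbing (tiling, resampling, denormalization)
    independently of training.
    """

    def parameters(self) -> list[Tensor]:
        return []

    def forward(self, x: Tensor) -> Tensor:
        return x * 1.0


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------
def build_restorer(spec: RestorerSpec = RestorerSpec(),
                   rng: np.random.Generator | None = None) -> Sequential:
    """Head (3 convs) + residual blocks + tail (3 convs, last linear)."""
    rng = rng or np.random.default_rng(0)
    f, ek, ik, sl = spec.features, spec.edge_kernel, spec.inner_kernel, spec.slope
    layers: list[Module] = [
        Conv2d(spec.in_channels, f, ek, rng=rng), LeakyReLU(sl),
        Conv2d(f, f, ik, rng=rng), LeakyReLU(sl),
        Conv2d(f, f, ik, rng=rng), LeakyReLU(sl),
    ]
    layers += [ResidualBlock(f, ik, sl, rng) for _ in range(spec.n_resblocks)]
    layers += [
        Conv2d(f, f, ik, rng=rng), LeakyReLU(sl),
        Conv2d(f, f, ik, rng=rng), LeakyReLU(sl),
        Conv2d(f, spec.out_channels, ek, rng=rng),
    ]
    net = Sequential(*layers)
    net.spec = spec  # type: ignore[attr-defined]
    return net


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(),
                        rng: np.random.Generator | None = None) -> Sequential:
    """Fully convolutional PatchGAN discriminator emitting a real/fake map."""
    rng = rng or np.random.default_rng(0)
    layers: list[Module] = []
    in_ch = 1
    for i, (feat, stride) in enumerate(zip(spec.features, spec.strides)):
        layers.append(Conv2d(in_ch, feat, spec.kernel, stride=stride,
                             pad=spec.padding, rng=rng))
        last = i == len(spec.features) - 1
        if not last:
            if i in spec.norm_layers:
                layers.append(InstanceNorm2d(feat))
            layers.append(LeakyReLU(spec.slope))
        in_ch = feat
    net = Sequential(*layers)
    net.spec = spec  # type: ignore[attr-defined]
    return net


def receptive_field(kernels: list[int], strides: list[int]) -> int:
    """Receptive field of one output unit: r <- r + (k-1)*j, j <- j*s."""
    if not kernels or len(kernels) != len(strides):
        raise ValueError("kernels and strides must be non-empty and aligned")
    r, j = 1, 1
    for k, s in zip(kernels, strides):
        r += (k - 1) * j
        j *= s
    return r


def count_parameters(net: Module) -> int:
    return int(sum(p.data.size for p in net.parameters()))


@contextmanager
def frozen(*nets: Module):
    """Temporarily exclude the networks' parameters from gradient accumulation
    (gradients still flow *through* them to upstream networks)."""
    params = [p for net in nets for p in net.parameters()]
    old = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p, o in zip(params, old):
            p.requires_grad = o


# --------------------------------------------------------------------------
# bundle + checkpointing
# --------------------------------------------------------------------------
@dataclass
class NetworkBundle:
    """The five training networks plus the optional DeconvNet."""

    g_a: Module  # Y -> Z degrader
    g_b: Module  # Z -> Y
    d_a: Module
    d_b: Module
    h: Module    # DeblurNet
    deconv: Module | None = None
    restorer_spec: RestorerSpec = field(default_factory=RestorerSpec)
    disc_spec: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)

    def architectures_identical(self) -> bool:
        specs = [getattr(n, "spec", None) for n in (self.g_a, self.g_b, self.h)]
        if self.deconv is not None:
            specs.append(getattr(self.deconv, "spec", None))
        return all(s is not None and s.hash() == specs[0].hash() for s in specs)


def build_bundle(restorer_spec: RestorerSpec = RestorerSpec(),
                 disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
                 seed: int = 0, with_deconv: bool = False) -> NetworkBundle:
    rng = np.random.default_rng(seed)
    return NetworkBundle(
        g_a=build_restorer(restorer_spec, rng),
        g_b=build_restorer(restorer_spec, rng),
        d_a=build_discriminator(disc_spec, rng),
        d_b=build_discriminator(disc_spec, rng),
        h=build_restorer(restorer_spec, rng),
        deconv=build_restorer(restorer_spec, rng) if with_deconv else None,
        restorer_spec=restorer_spec,
        disc_spec=disc_spec,
    )


_NAMES = ("g_a", "g_b", "d_a", "d_b", "h", "deconv")


def save_bundle(bundle: NetworkBundle, directory, norm_record=None,
                train_config=None) -> None:
    """Self-describing checkpoint: weights + specs + NormRecord + config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name in _NAMES:
        net = getattr(bundle, name)
        if net is None:
            continue
        for i, p in enumerate(net.parameters()):
            arrays[f"{name}.{i}"] = p.data
    np.savez(directory / "weights.npz", **arrays)
    meta = {
        "restorer_spec": asdict(bundle.restorer_spec),
        "disc_spec": asdict(bundle.disc_spec),
        "has_deconv": bundle.deconv is not None,
        "norm_record": None if norm_record is None else vars(norm_record),
        "train_config": train_config,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_bundle(directory) -> tuple[NetworkBundle, dict]:
    """Load a checkpoint; returns (bundle, meta dict)."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    weights_path = directory / "weights.npz"
    if not meta_path.exists() or not weights_path.exists():
        raise FileNotFoundError(f"no checkpoint at {directory}")
    try:
        meta = json.loads(meta_path.read_text())
        rspec = RestorerSpec(**meta["restorer_spec"])
        dspec = DiscriminatorSpec(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in meta["disc_spec"].items()}
        )
        bundle = build_bundle(rspec, dspec, with_deconv=meta["has_deconv"])
        with np.load(weights_path) as arrays:
            for name in _NAMES:
                net = getattr(bundle, name)
                if net is None:
                    continue
                for i, p in enumerate(net.parameters()):
                    p.data = arrays[f"{name}.{i}"].astype(p.data.dtype)
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted checkpoint at {directory}: {exc}") from exc
    return bundle, meta
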