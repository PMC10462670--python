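"""Inference: apply a trained restoration network to every axial slice.

The volume is first resampled along z to the lateral pixel size (the same
interpolator the training pipeline uses, so the network sees the degradation
statistics it was trained on), then each axial slice is pushed through the
network — tiled with linearly feathered overlaps for large data — and the
result is mapped back to the input intensity scale.

Also implements the deconvolution extension's plumbing: cropping an
experimental PSF from an image of an isolated point source, and
Richardson–Lucy deconvolution with reflective edge handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .autodiff import Tensor
from .nets import Module
from .resample import upsample_axis
from .volio import NormRecord
from .volume import PSFKernel, Volume3D

ORIENTATIONS = ("xz", "yz", "both-average")


@dataclass
class RestoreRequest:
    volume: Volume3D
    net: Module
    orientation: str = "xz"
    tile: int = 256
    overlap: int = 16
    norm_record: NormRecord | None = None

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.tile < 7:
            raise ValueError("tile must be at least 7 px")
        if self.overlap >= self.tile:
            raise ValueError("overlap must be smaller than the tile size")


def _feather_weights(length: int, start: int, size: int, overlap: int) -> np.ndarray:
    """Linear ramp over the overlapping margins of one tile."""
    w = np.ones(size)
    if overlap > 0:
        ramp = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
        if start > 0:
            w[:overlap] = ramp
        if start + size < length:
            w[-overlap:] = ramp[::-1]
    return w


def _tile_starts(length: int, tile: int, overlap: int) -> list[int]:
    if length <= tile:
        return [0]
    step = tile - overlap
    starts = list(range(0, length - tile, step))
    starts.append(length - tile)
    return starts


def process_slice(net: Module, img: np.ndarray, tile: int = 256,
                  overlap: int = 16) -> np.ndarray:
    """Run one 2D image through the network, tiling with feathered overlaps."""
    h, w = img.shape
    if h <= tile and w <= tile:
        return net(Tensor(img[None, None].astype(np.float32))).data[0, 0]
    out = np.zeros((h, w), dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    for r in _tile_starts(h, tile, overlap):
        for c in _tile_starts(w, tile, overlap):
            patch = img[r:r + tile, c:c + tile].astype(np.float32)
            res = net(Tensor(patch[None, None])).data[0, 0]
            wr = _feather_weights(h, r, patch.shape[0], overlap)
            wc = _feather_weights(w, c, patch.shape[1], overlap)
            tw = np.outer(wr, wc)
            out[r:r + tile, c:c + tile] += res * tw
            weight[r:r + tile, c:c + tile] += tw
    return (out / weight).astype(np.float32)


def _restore_pass(data_up: np.ndarray, net: Module, orientation: str,
                  tile: int, overlap: int) -> np.ndarray:
    out = np.empty_like(data_up)
    if orientation == "xz":
        for y in range(data_up.shape[1]):
            out[:, y, :] = process_slice(net, data_up[:, y, :], tile, overlap)
    else:  # yz
        for x in range(data_up.shape[2]):
            out[:, :, x] = process_slice(net, data_up[:, :, x], tile, overlap)
    return out


def restore_volume(req: RestoreRequest) -> Volume3D:
    """Isotropize a volume with the trained network; see module docstring."""
    vol = req.volume
    dz, dy, dx = vol.spacing
    rec = req.norm_record
    if rec is not None:
        data = rec.apply(vol.data)
    else:
        data = np.asarray(vol.data, dtype=np.float32)
    factor = dz / dx
    new_nz = int(round(vol.shape[0] * factor))
    data_up = (upsample_axis(data, 0, new_nz).astype(np.float32)
               if new_nz != vol.shape[0] else data.copy())
    if req.orientation == "both-average":
        out = 0.5 * (_restore_pass(data_up, req.net, "xz", req.tile, req.overlap)
                     + _restore_pass(data_up, req.net, "yz", req.tile, req.overlap))
    else:
        out = _restore_pass(data_up, req.net, req.orientation, req.tile, req.overlap)
    if rec is not None:
        out = rec.invert(out)
    out = np.clip(out, 0.0, None)
    return Volume3D(out.astype(np.float32), (dx, dy, dx))


def crop_psf_from_slice(slice2d: np.ndarray, center: tuple[int, int],
                        size: int = 50) -> PSFKernel:
    """Extract an experimental 2D PSF from an isolated point source.

    A ``size`` x ``size`` window around ``center`` locates the intensity peak;
    an odd window is then re-extracted centred on the peak, the border median
    is subtracted as background, negatives are clipped, and the kernel is
    normalized to unit sum.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    half = size // 2
    r0, c0 = int(center[0]), int(center[1])
    if not (half <= r0 < img.shape[0] - half and half <= c0 < img.shape[1] - half):
        raise ValueError("window extends outside the slice")
    win = img[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1]
    if win.max() <= 0:
        raise ValueError("window contains no signal")
    pr, pc = np.unravel_index(np.argmax(win), win.shape)
    pr, pc = r0 - half + pr, c0 - half + pc  # peak in slice coordinates
    odd = size - 1 if size % 2 == 0 else size
    oh = odd // 2
    if not (oh <= pr < img.shape[0] - oh and oh <= pc < img.shape[1] - oh):
        raise ValueError("peak too close to the slice border for the window")
    kern = img[pr - oh:pr + oh + 1, pc - oh:pc + oh + 1].copy()
    border = np.concatenate([kern[0], kern[-1], kern[1:-1, 0], kern[1:-1, -1]])
    kern -= np.median(border)
    kern = np.clip(kern, 0.0, None)
    if kern.sum() <= 0:
        raise ValueError("window is background only")
    return PSFKernel(kern, (1.0, 1.0))


def _conv_reflect(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    halves = [s // 2 for s in kernel.shape]
    padded = np.pad(arr, [(h, h) for h in halves], mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


def rl_deconvolve(arr: np.ndarray, psf: PSFKernel, iters: int = 5,
                  init: np.ndarray | None = None) -> np.ndarray:
    """Richardson–Lucy deconvolution (Poisson model), reflective edges.

    2D input with a 2D PSF, 3D with a 3D PSF, or 3D input with a 2D PSF
    (applied slice-by-slice along axis 0).  The estimate starts from the
    observation itself unless ``init`` is given, so ``iters=0`` returns the
    input unchanged.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if iters < 0:
        raise ValueError("iters must be >= 0")
    if np.any(arr < 0):
        raise ValueError("negative input intensities violate the Poisson model")
    if arr.ndim == 3 and psf.data.ndim == 2:
        return np.stack([rl_deconvolve(s, psf, iters, init) for s in arr])
    if arr.ndim != psf.data.ndim:
        raise ValueError("input and PSF dimensionality mismatch")
    k = psf.data
    if not np.isclose(k.sum(), 1.0, atol=1e-6):
        raise ValueError("PSF must be unit-sum")
    k_mirror = k[tuple(slice(None, None, -1) for _ in range(k.ndim))]
    est = arr.copy() if init is None else np.array(init, dtype=np.float64)
    tiny = 1e-12
    for _ in range(iters):
        conv = _conv_reflect(est, k)
        ratio = arr / np.maximum(conv, tiny)
        est = est * np.clip(_conv_reflect(ratio, k_mirror), 0.0, None)
    return est
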