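"""Synthetic and semisynthetic volume generation with controlled anisotropy.

The generators emulate the statistical structure the restoration method
assumes: point-like (bead) or elongated tubular objects, blurred by an
anisotropic PSF and optionally subsampled along z.  Identical ``(SimSpec,
seed)`` yields bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .resample import downsample_axis, upsample_axis
from .volume import PSFKernel, Volume3D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Full-scale bead phantom: 512^3 voxels, 800 beads, radii 2-4 px,
#: intensities 150-255, 0.2 um pixels.  The desk-scale default used by the
#: test suite is 128^3 with 60 beads.
FULLSCALE_BEAD_SHAPE = (512, 512, 512)
FULLSCALE_BEAD_COUNT = 800
DESK_BEAD_SHAPE = (128, 128, 128)
DESK_BEAD_COUNT = 60
DESK_TUBE_COUNT = 30


@dataclass
class SimSpec:
    """Parameters of a synthetic scene.

    kind : "beads" or "tubes"
    shape : (nz, ny, nx) voxels
    n_objects : number of beads / tubes
    radius_range : (min, max) radius in voxels
    intensity_range : (min, max) peak gray value
    seed : RNG seed; identical (spec, seed) gives bit-identical volumes
    spacing : voxel size in um (isotropic ground truth)
    """

    kind: str
    shape: tuple[int, int, int] = DESK_BEAD_SHAPE
    n_objects: int = DESK_BEAD_COUNT
    radius_range: tuple[float, float] = (2.0, 4.0)
    intensity_range: tuple[float, float] = (150.0, 255.0)
    seed: int = 0
    spacing: float = 0.2

    def __post_init__(self):
        if self.kind not in ("beads", "tubes"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError(f"bad radius_range {self.radius_range}")
        if rmin < 1 or rmax > min(self.shape) / 4:
            raise ValueError(
                f"radius_range {self.radius_range} outside [1, min(shape)/4]"
            )
        imin, imax = self.intensity_range
        if not (0 <= imin <= imax):
            raise ValueError(f"bad intensity_range {self.intensity_range}")
        if self.n_objects > 0 and min(self.shape) < 2 * rmax:
            raise ValueError("shape too small to place an object")


def rasterize_sphere(vol: np.ndarray, center: np.ndarray, radius: float,
                     intensity: float) -> None:
    """Stamp a solid sphere into ``vol`` in place, combining by maximum."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, vol.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2
    box = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(box, np.where(mask, intensity, 0.0), out=box)


def generate_bead_volume(spec: SimSpec) -> Volume3D:
    """Spheres at uniform random positions with uniform radii and intensities.

    Background is zero; overlapping spheres combine by per-voxel maximum.
    """
    if spec.kind != "beads":
        raise ValueError("spec.kind must be 'beads'")
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape, dtype=np.float32)
    for _ in range(spec.n_objects):
        center = rng.uniform(0.0, np.array(spec.shape, dtype=float))
        radius = rng.uniform(*spec.radius_range)
        intensity = rng.uniform(*spec.intensity_range)
        rasterize_sphere(vol, center, radius, intensity)
    s = spec.spacing
    return Volume3D(vol, (s, s, s), value_range=(0.0, spec.intensity_range[1]))


def rasterize_tube(vol: np.ndarray, path: np.ndarray, radius: float,
                   intensity: float) -> None:
    """Stamp a constant-radius tube along a polyline of (z, y, x) points."""
    path = np.asarray(path, dtype=float)
    if len(path) == 0:
        return
    # densify so consecutive samples are < 0.5 voxel apart, then stamp spheres
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    pts = [path[0]]
    for p0, p1, d in zip(path[:-1], path[1:], seg):
        k = max(int(np.ceil(d / 0.5)), 1)
        for t in np.linspace(0, 1, k + 1)[1:]:
            pts.append(p0 + t * (p1 - p0))
    for c in pts:
        rasterize_sphere(vol, c, radius, intensity)


def _random_walk(rng: np.random.Generator, shape: tuple[int, int, int],
                 n_steps: int, curvature: float = 0.25,
                 step: float = 1.0) -> np.ndarray:
    """A smooth 3D random walk with bounded curvature, reflected at borders."""
    pos = rng.uniform(0.0, np.array(shape, dtype=float))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    path = [pos.copy()]
    for _ in range(n_steps):
        d = d + curvature * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pos = pos + step * d
        for ax in range(3):  # reflect at the volume boundary
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                d[ax] = -d[ax]
            elif pos[ax] > shape[ax] - 1:
                pos[ax] = 2 * (shape[ax] - 1) - pos[ax]
                d[ax] = -d[ax]
        path.append(pos.copy())
    return np.array(path)


def generate_tube_volume(spec: SimSpec) -> Volume3D:
    """Smooth random-walk curves rasterized as constant-radius tubes."""
    if spec.kind != "tubes":
        raise ValueError("spec.kind must be 'tubes'")
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape, dtype=np.float32)
    min_side = min(spec.shape)
    for _ in range(spec.n_objects):
        n_steps = int(rng.integers(min_side // 4, max(min_side // 2, min_side // 4 + 1)))
        path = _random_walk(rng, spec.shape, n_steps)
        radius = rng.uniform(*spec.radius_range)
        intensity = rng.uniform(*spec.intensity_range)
        rasterize_tube(vol, path, radius, intensity)
    s = spec.spacing
    return Volume3D(vol, (s, s, s), value_range=(0.0, spec.intensity_range[1]))


def gaussian_psf(fwhm_lateral: float, fwhm_axial: float, spacing: float,
                 support: int = 25) -> PSFKernel:
    """Separable anisotropic Gaussian PSF.

    Parameters are physical FWHMs in um (sigma = FWHM / (2 sqrt(2 ln 2)))
    and an isotropic voxel size in um; ``support`` is the odd kernel extent
    in voxels along every axis.
    """
    if fwhm_lateral <= 0 or fwhm_axial <= 0:
        raise ValueError("FWHMs must be positive")
    if support % 2 == 0:
        raise ValueError(f"support must be odd, got {support}")
    sig_ax = fwhm_axial * FWHM_TO_SIGMA / spacing
    sig_lat = fwhm_lateral * FWHM_TO_SIGMA / spacing
    if support < 6 * max(sig_ax, sig_lat) + 1:
        warnings.warn(
            f"support {support} truncates the Gaussian before +/-3 sigma "
            f"(sigma_vox={max(sig_ax, sig_lat):.2f})",
            stacklevel=2,
        )
    r = np.arange(support) - support // 2
    gz = np.exp(-0.5 * (r / sig_ax) ** 2)
    gl = np.exp(-0.5 * (r / sig_lat) ** 2)
    kernel = gz[:, None, None] * gl[None, :, None] * gl[None, None, :]
    return PSFKernel(kernel, (spacing,) * 3)


def degrade_volume(gt: Volume3D, psf: PSFKernel, z_factor: int = 1) -> Volume3D:
    """Convolve with the PSF (reflective edges), then keep every z_factor-th slice."""
    if z_factor < 1:
        raise ValueError("z_factor must be >= 1")
    if z_factor > gt.shape[0]:
        raise ValueError(f"z_factor {z_factor} exceeds z extent {gt.shape[0]}")
    k = psf.data if psf.data.ndim == 3 else psf.data[None]
    halves = [s // 2 for s in k.shape]
    padded = np.pad(gt.data.astype(np.float64),
                    [(h, h) for h in halves], mode="reflect")
    blurred = fftconvolve(padded, k, mode="valid")
    blurred = np.clip(blurred, 0.0, None)
    sub = blurred[::z_factor]
    dz, dy, dx = gt.spacing
    return Volume3D(sub.astype(np.float32), (dz * z_factor, dy, dx),
                    value_range=gt.value_range)


def make_semisynthetic_pairs(lateral_slices: np.ndarray, sigma: float = 2.0,
                             factor: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Pair each lateral slice with its vertically degraded counterpart.

    Degradation = vertical (y-axis) Gaussian blur of the stated sigma, then
    vertical downsampling by ``factor`` and cubic re-interpolation back to the
    original height, preserving pixel alignment.  Returns (degraded, targets).
    """
    slices = np.asarray(lateral_slices, dtype=np.float64)
    if slices.ndim == 2:
        slices = slices[None]
    if slices.size == 0 or slices.shape[0] == 0:
        raise ValueError("empty slice set")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h = slices.shape[1]
    blurred = (gaussian_filter1d(slices, sigma, axis=1, mode="reflect")
               if sigma > 0 else slices.copy())
    if factor > 1:
        low = downsample_axis(blurred, 1, max(int(round(h / factor)), 1))
        degraded = upsample_axis(low, 1, h)
    else:
        degraded = blurred
    return degraded.astype(np.float32), slices.astype(np.float32)


#: The supervised-baseline degradation recipe: vertical Gaussian sigma = 3 px,
#: vertical downsampling factor 5.
CARE_SIGMA = 3.0
CARE_FACTOR = 5


def make_care_pairs(lateral_slices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Semisynthetic pairs with the fixed supervised-baseline recipe (3 px, x5)."""
    return make_semisynthetic_pairs(lateral_slices, sigma=CARE_SIGMA,
                                    factor=CARE_FACTOR)
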