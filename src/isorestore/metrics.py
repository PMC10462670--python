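"""Evaluation suite: image quality, resolution, and skeleton accuracy.

Image quality: RMSE, windowed SSIM (shared with the training loss), and the
signal-to-background ratio SBR = peak(signal) / mean(background).

Resolution: sub-pixel FWHM of 1D intensity profiles, the per-skeleton-point
isotropy ratio (lateral FWHM / axial FWHM measured on cube MIPs orthogonal to
the local fibre direction), and a Fourier-spectrum isotropy score.

Skeleton accuracy: F1 = 2PR/(P+R) and the entire-structure average (ESA, the
mean nearest-neighbour distance) between two equal-spacing-resampled SWC
trees, with a configurable true-positive distance threshold (1-3 um typical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from . import losses
from .volume import Volume3D

log = logging.getLogger(__name__)

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


# --------------------------------------------------------------------------
# image quality
# --------------------------------------------------------------------------
def rmse(m: np.ndarray, n: np.ndarray) -> float:
    """Root mean squared difference between two equal-shape images."""
    m = np.asarray(m, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if m.shape != n.shape:
        raise ValueError(f"shape mismatch {m.shape} vs {n.shape}")
    return float(np.sqrt(np.mean((m - n) ** 2)))


def ssim_index(m: np.ndarray, n: np.ndarray) -> float:
    """Mean windowed SSIM on a [0, 1] scale (same kernel as the loss)."""
    return float(losses.ssim(np.asarray(m, np.float32),
                             np.asarray(n, np.float32)).data)


def sbr(image: np.ndarray, signal_region, background_region) -> float:
    """Peak of the signal region over the mean of the background region.

    Regions are boolean masks or index expressions; they must be disjoint
    and non-empty.
    """
    image = np.asarray(image, dtype=np.float64)
    sig_mask = np.zeros(image.shape, dtype=bool)
    sig_mask[signal_region] = True
    bg_mask = np.zeros(image.shape, dtype=bool)
    bg_mask[background_region] = True
    if not sig_mask.any() or not bg_mask.any():
        raise ValueError("signal and background regions must be non-empty")
    if (sig_mask & bg_mask).any():
        raise ValueError("signal and background regions must be disjoint")
    b = image[bg_mask].mean()
    if b <= 0:
        raise ValueError("background mean must be positive")
    return float(image[sig_mask].max() / b)


# --------------------------------------------------------------------------
# resolution
# --------------------------------------------------------------------------
def fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a 1D profile, sub-pixel.

    The profile minimum is subtracted as baseline; the two half-maximum
    crossings around the global peak are located by linear interpolation.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    p = p - p.min()
    peak = int(np.argmax(p))
    half = p[peak] / 2.0
    if half <= 0:
        raise ValueError("flat profile: FWHM undefined")

    left = None
    for i in range(peak, 0, -1):
        if p[i - 1] <= half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
            break
    right = None
    for i in range(peak, p.size - 1):
        if p[i + 1] <= half <= p[i]:
            right = i + (p[i] - half) / (p[i] - p[i + 1])
            break
    if left is None or right is None:
        raise ValueError("no half-maximum crossing found: FWHM undefined")
    return float((right - left) * spacing)


def effective_vertical_blur(apply_fn, images: np.ndarray,
                            sigmas: np.ndarray | None = None) -> float:
    """Effective vertical Gaussian blur sigma of an image operator.

    Fits ``apply_fn`` by comparing its output on ``images`` (one 2D array or
    a stack) against vertical Gaussian blurs of the input over a grid of
    candidate sigmas, returning the least-squares best match in pixels.
    Robust to operators that respond poorly to synthetic probe patterns,
    since it evaluates the blur on the data distribution itself.
    """
    from scipy.ndimage import gaussian_filter1d

    if sigmas is None:
        sigmas = np.arange(0.25, 5.01, 0.05)
    imgs = np.asarray(images, dtype=np.float32)
    if imgs.ndim == 2:
        imgs = imgs[None]
    outs = np.stack([np.asarray(apply_fn(im), dtype=np.float64) for im in imgs])
    errs = []
    for s in sigmas:
        blurred = gaussian_filter1d(imgs.astype(np.float64), s, axis=1,
                                    mode="reflect")
        # affine calibration (gain + offset) so intensity rescaling by the
        # operator does not bias the blur estimate
        bb = blurred.ravel()
        a = np.stack([bb, np.ones_like(bb)], axis=1)
        coef, *_ = np.linalg.lstsq(a, outs.ravel(), rcond=None)
        errs.append(np.mean((a @ coef - outs.ravel()) ** 2))
    return float(sigmas[int(np.argmin(errs))])


# --------------------------------------------------------------------------
# skeletons
# --------------------------------------------------------------------------
@dataclass
class SkeletonTree:
    """An SWC-style skeleton: nodes with positions (um), radius and parent."""

    nodes: pd.DataFrame  # columns: id, type, x, y, z, radius, parent

    def __post_init__(self):
        missing = set(SWC_COLUMNS) - set(self.nodes.columns)
        if missing:
            raise ValueError(f"missing SWC columns: {sorted(missing)}")
        ids = set(self.nodes["id"].astype(int))
        parents = self.nodes["parent"].astype(int)
        bad = set(parents) - ids - {-1}
        if bad:
            raise ValueError(f"parent ids not present in tree: {sorted(bad)}")
        if not np.all(np.isfinite(self.nodes[["x", "y", "z"]]
                                  .to_numpy(dtype=float))):
            raise ValueError("non-finite node positions")
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        parent_of = dict(zip(self.nodes["id"].astype(int),
                             self.nodes["parent"].astype(int)))
        state: dict[int, int] = {}
        for start in parent_of:
            node, chain = start, []
            while node != -1 and state.get(node, 0) == 0:
                state[node] = 1
                chain.append(node)
                node = parent_of.get(node, -1)
            if node != -1 and state.get(node) == 1:
                raise ValueError("skeleton contains a cycle")
            for n in chain:
                state[n] = 2

    def __len__(self) -> int:
        return len(self.nodes)

    def positions(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def chains(self) -> list[np.ndarray]:
        """Decompose into maximal unbranched polylines of (x, y, z) points."""
        ids = self.nodes["id"].astype(int).to_numpy()
        parents = self.nodes["parent"].astype(int).to_numpy()
        pos = {i: p for i, p in zip(ids, self.positions())}
        children: dict[int, list[int]] = {int(i): [] for i in ids}
        roots = []
        for i, par in zip(ids, parents):
            if par == -1:
                roots.append(int(i))
            else:
                children[int(par)].append(int(i))
        junctions = set(roots) | {i for i, ch in children.items() if len(ch) != 1}
        out = []
        for start in sorted(junctions):
            for child in children[start]:
                chain = [pos[start], pos[child]]
                node = child
                while node not in junctions and len(children[node]) == 1:
                    node = children[node][0]
                    chain.append(pos[node])
                out.append(np.array(chain))
        if not out and len(self.nodes):  # single node, no edges
            out = [self.positions()[:1]]
        return out

    def resample(self, step: float = 1.0) -> np.ndarray:
        """Equal-arclength resampling of every chain; returns (n, 3) points."""
        if step <= 0:
            raise ValueError("step must be positive")
        points = []
        for chain in self.chains():
            if len(chain) == 1:
                points.append(chain)
                continue
            seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            total = arc[-1]
            n = max(int(np.floor(total / step)) + 1, 2)
            targets = np.linspace(0.0, total, n)
            points.append(np.stack([
                np.interp(targets, arc, chain[:, k]) for k in range(3)
            ], axis=1))
        if not points:
            raise ValueError("empty skeleton")
        return np.concatenate(points)


def read_swc(path) -> SkeletonTree:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=SWC_COLUMNS)
    return SkeletonTree(df)


def write_swc(tree: SkeletonTree, path) -> None:
    lines = ["# id type x y z radius parent"]
    for row in tree.nodes.itertuples(index=False):
        lines.append(f"{int(row.id)} {int(row.type)} {row.x:.4f} {row.y:.4f} "
                     f"{row.z:.4f} {row.radius:.4f} {int(row.parent)}")
    Path(path).write_text("\n".join(lines) + "\n")


def skeleton_f1_esa(test: SkeletonTree, gt: SkeletonTree,
                    threshold: float = 2.0, step: float = 1.0
                    ) -> tuple[float, float, float, float]:
    """Node-matching accuracy of a reconstruction against a gold standard.

    Both trees are resampled to equal spacing; each test node's nearest-
    neighbour distance to the gold standard is its reciprocal minimal spatial
    distance; nodes closer than ``threshold`` (um) are true positives.
    Precision = TP/|test|, recall = TP/|gt|, F1 = 2PR/(P+R); ESA is the mean
    of the test-to-gt distances.
    """
    if len(test) == 0 or len(gt) == 0:
        raise ValueError("both skeletons must be non-empty")
    pts_test = test.resample(step)
    pts_gt = gt.resample(step)
    dists, _ = cKDTree(pts_gt).query(pts_test)
    tp = int(np.sum(dists < threshold))
    precision = tp / len(pts_test)
    recall = tp / len(pts_gt)
    f1 = 0.0 if precision + recall == 0 else (
        2 * precision * recall / (precision + recall)
    )
    return float(f1), float(dists.mean()), float(precision), float(recall)


# --------------------------------------------------------------------------
# isotropy ratio
# --------------------------------------------------------------------------
def _line_profile(img: np.ndarray, direction: np.ndarray, radius: int
                  ) -> np.ndarray:
    """Intensity profile through the image centre along a 2D direction."""
    c = (np.array(img.shape, dtype=float) - 1) / 2.0
    t = np.arange(-radius, radius + 1, dtype=float)
    coords = c[:, None] + direction[:, None] * t
    return map_coordinates(img.astype(np.float64), coords, order=1,
                           mode="nearest")


@dataclass
class IsotropyResult:
    ratios: np.ndarray          # ratios that survived the outlier rule
    mean: float
    n_discarded: int
    n_skipped: int


def isotropy_ratio(vol: Volume3D, skeleton: SkeletonTree, cube: int = 23,
                   step_um: float | None = None) -> IsotropyResult:
    """Lateral/axial FWHM ratio along a traced fibre.

    At each equal-spacing-resampled skeleton point, a ``cube``-sized block is
    extracted; the local forward direction comes from the four nearest
    neighbouring points (a line fit through the 5-point window); profiles are
    taken along the normal's projections onto the lateral (xy) and axial (xz
    or zy) maximum-intensity projections of the cube, and their FWHMs are
    ratioed (lateral / axial).  Ratios deviating from the median by more than
    half of it are discarded; points too close to the border are skipped.
    """
    dz, dy, dx = vol.spacing
    half = cube // 2
    step = dx if step_um is None else step_um
    nz, ny, nx = vol.shape
    ratios = []
    n_skipped = 0
    for chain in skeleton.chains():
        if len(chain) < 5:
            n_skipped += len(chain)
            continue
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(np.floor(arc[-1] / step)) + 1, 2)
        targets = np.linspace(0.0, arc[-1], n)
        pts = np.stack([np.interp(targets, arc, chain[:, k])
                        for k in range(3)], axis=1)
        for i in range(2, len(pts) - 2):
            # voxel coordinates (z, y, x) of the point
            vz = pts[i, 2] / dz
            vy = pts[i, 1] / dy
            vx = pts[i, 0] / dx
            iz, iy, ix = int(round(vz)), int(round(vy)), int(round(vx))
            if not (half <= iz < nz - half and half <= iy < ny - half
                    and half <= ix < nx - half):
                n_skipped += 1
                log.debug("isotropy point %d skipped: too near border", i)
                continue
            window = pts[i - 2:i + 3]  # the point and its 4 nearest neighbours
            centred = (window - window.mean(axis=0)) / np.array([dx, dy, dz])
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            fwd = vt[0]  # (x, y, z) components in voxel units
            fwd = fwd / np.linalg.norm(fwd)
            # normal in the lateral plane; undefined if the fibre is axial
            n_lat = np.cross(fwd, [0.0, 0.0, 1.0])
            if np.linalg.norm(n_lat) < 0.2:
                n_skipped += 1
                continue
            n_lat /= np.linalg.norm(n_lat)
            n_ax = np.cross(fwd, n_lat)  # completes the orthogonal frame
            n_ax /= np.linalg.norm(n_ax)
            block = vol.data[iz - half:iz + half + 1,
                             iy - half:iy + half + 1,
                             ix - half:ix + half + 1]
            lat_mip = block.max(axis=0)  # (y, x)
            d_lat = np.array([n_lat[1], n_lat[0]])
            ax_mip = block.max(axis=1)   # (z, x)
            d_ax = np.array([n_ax[2], n_ax[0]])
            if np.linalg.norm(d_ax) < 0.2:  # normal ~ parallel to y: use (z, y)
                ax_mip = block.max(axis=2)
                d_ax = np.array([n_ax[2], n_ax[1]])
            if np.linalg.norm(d_lat) < 1e-6 or np.linalg.norm(d_ax) < 1e-6:
                n_skipped += 1
                continue
            d_lat /= np.linalg.norm(d_lat)
            d_ax /= np.linalg.norm(d_ax)
            try:
                w_lat = fwhm(_line_profile(lat_mip, d_lat, half))
                w_ax = fwhm(_line_profile(ax_mip, d_ax, half))
            except ValueError:
                n_skipped += 1
                continue
            ratios.append(w_lat / w_ax)
    if not ratios:
        raise ValueError("no usable skeleton points for the isotropy ratio")
    ratios = np.array(ratios)
    med = np.median(ratios)
    keep = np.abs(ratios - med) <= 0.5 * med
    kept = ratios[keep]
    return IsotropyResult(ratios=kept, mean=float(kept.mean()),
                          n_discarded=int((~keep).sum()),
                          n_skipped=n_skipped)


# --------------------------------------------------------------------------
# Fourier spectrum
# --------------------------------------------------------------------------
@dataclass
class SpectrumReport:
    lateral_logmag: np.ndarray
    axial_logmag: np.ndarray
    score: float  # axial/lateral cutoff-frequency ratio; 1 = isotropic
    cutoff_axial: float
    cutoff_lateral: float


def _cutoff_frequency(profile: np.ndarray, energy_fraction: float = 0.9
                      ) -> float:
    """Normalized frequency radius enclosing ``energy_fraction`` of the
    non-DC spectral power of a half-axis magnitude profile.

    A fixed-energy radius is stable on both noisy (flat) and smooth
    (blur-decayed) spectra, unlike threshold crossings of a noise floor.
    """
    power = np.asarray(profile, dtype=float) ** 2
    power = power[1:]  # drop the DC bin
    cum = np.cumsum(power)
    total = cum[-1]
    if total <= 0:
        return 1.0 / (power.size + 1)
    idx = int(np.searchsorted(cum, energy_fraction * total))
    return float(idx + 1) / (power.size + 1)


def fourier_spectrum(vol: Volume3D) -> SpectrumReport:
    """Centred log-magnitude spectra of the central lateral and axial slices,
    plus a spectral isotropy score (axial over lateral cutoff radius)."""
    data = np.asarray(vol.data, dtype=np.float64)
    lateral = data[data.shape[0] // 2]          # (y, x)
    axial = data[:, data.shape[1] // 2, :]      # (z, x)
    lat_mag = np.abs(np.fft.fftshift(np.fft.fft2(lateral)))
    ax_mag = np.abs(np.fft.fftshift(np.fft.fft2(axial)))
    lat_log = np.log1p(lat_mag)
    ax_log = np.log1p(ax_mag)

    def _half_profile(mag: np.ndarray, axis: int) -> np.ndarray:
        ctr = np.array(mag.shape) // 2
        if axis == 0:
            band = mag[ctr[0]:, max(ctr[1] - 2, 0):ctr[1] + 3].mean(axis=1)
        else:
            band = mag[max(ctr[0] - 2, 0):ctr[0] + 3, ctr[1]:].mean(axis=0)
        return band

    # lateral resolution: kx profile of the lateral slice
    cut_lat = _cutoff_frequency(_half_profile(lat_mag, 1))
    # axial resolution: kz profile of the axial slice
    cut_ax = _cutoff_frequency(_half_profile(ax_mag, 0))
    return SpectrumReport(lateral_logmag=lat_log, axial_logmag=ax_log,
                          score=float(cut_ax / cut_lat),
                          cutoff_axial=cut_ax, cutoff_lateral=cut_lat)


# --------------------------------------------------------------------------
# aggregate report
# --------------------------------------------------------------------------
@dataclass
class MetricReport:
    rmse: float | None = None
    ssim: float | None = None
    sbr: float | None = None
    fwhm_lateral: list[float] = field(default_factory=list)
    fwhm_axial: list[float] = field(default_factory=list)
    isotropy_mean: float | None = None
    f1: float | None = None
    esa: float | None = None
    precision: float | None = None
    recall: float | None = None
    spectral_isotropy: float | None = None

    def __post_init__(self):
        if self.ssim is not None and not 0 <= self.ssim <= 1 + 1e-9:
            raise ValueError("SSIM must lie in [0, 1]")
        if self.f1 is not None and not 0 <= self.f1 <= 1 + 1e-9:
            raise ValueError("F1 must lie in [0, 1]")
        if self.esa is not None and self.esa < 0:
            raise ValueError("ESA must be nonnegative")

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v not in (None, [])}
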