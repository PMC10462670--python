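"""Volume I/O and the training data contract.

The self-learning scheme slices one anisotropic stack into three 2D sets:

* ``X`` — high-resolution lateral (xy) slices,
* ``Y`` — each ``x_i`` vertically downsampled by the anisotropy factor
  ``dz/dx`` and re-interpolated to the original size (pixel-aligned to
  ``x_i``), emulating the axial sampling loss,
* ``Z`` — axial slices (both xz and yz orientations), with the z axis
  interpolated to the lateral pixel size; unpaired with X/Y.

Volumes travel as multi-page TIFF plus a YAML sidecar holding the voxel
spacing (and, for checkpoints, the normalization record).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .resample import downsample_axis, upsample_axis
from .volume import Volume3D


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_volume(vol: Volume3D, path) -> None:
    """Write a multi-page TIFF (one page per z slice) plus a spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    meta = {"spacing": [float(s) for s in vol.spacing],
            "value_range": [float(v) for v in vol.value_range]}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_volume(path, spacing=None) -> Volume3D:
    """Read a multi-page TIFF; spacing comes from the sidecar unless given."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {page.shape for page in tf.pages}
        if len(shapes) > 1:
            raise ValueError(
                f"format error: mixed page shapes {sorted(shapes)} in {path}"
            )
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grayscale stack, got shape {data.shape}")
    value_range = None
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no voxel spacing for {path}: provide --spacing dz,dy,dx "
                f"or a sidecar {sidecar.name}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        spacing = tuple(meta["spacing"])
        if "value_range" in meta:
            value_range = tuple(meta["value_range"])
    return Volume3D(data, tuple(float(s) for s in spacing), value_range=value_range)


@dataclass
class NormRecord:
    """Record of the percentile normalization so it can be inverted/replayed."""

    p_low: float
    p_high: float
    low_value: float
    high_value: float
    clip: bool = True

    def apply(self, data: np.ndarray) -> np.ndarray:
        out = (np.asarray(data, dtype=np.float32) - self.low_value) / (
            self.high_value - self.low_value
        )
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def invert(self, data01: np.ndarray) -> np.ndarray:
        return np.asarray(data01, dtype=np.float32) * (
            self.high_value - self.low_value
        ) + self.low_value


def normalize(vol: Volume3D, p_low: float = 0.1, p_high: float = 99.9,
              clip: bool = True) -> tuple[Volume3D, NormRecord]:
    """Affine map sending the p_low percentile to 0 and p_high to 1."""
    if p_high <= p_low:
        raise ValueError("p_high must exceed p_low")
    lo, hi = np.percentile(vol.data, [p_low, p_high])
    if hi <= lo:
        raise ValueError(
            "degenerate input: zero dynamic range between the chosen percentiles"
        )
    rec = NormRecord(p_low, p_high, float(lo), float(hi), clip)
    out = Volume3D(rec.apply(vol.data), vol.spacing, value_range=(0.0, 1.0))
    return out, rec


def denormalize(vol01: Volume3D, rec: NormRecord) -> Volume3D:
    data = np.clip(rec.invert(vol01.data), 0.0, None)
    return Volume3D(data, vol01.spacing)


@dataclass
class SliceSets:
    """The training triad (X, Y, Z); see module docstring."""

    X: np.ndarray  # (n, h, w) HR lateral slices
    Y: np.ndarray  # (n, h, w) degraded lateral slices, index-paired with X
    Z: list[np.ndarray] = field(default_factory=list)  # axial slices, any shapes
    aniso_factor: float = 1.0

    def __post_init__(self):
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must be index-paired with equal shapes")


def degrade_lateral(slices: np.ndarray, factor: float) -> np.ndarray:
    """The Y-construction operator: vertical area-downsample by ``factor``
    then cubic re-interpolation to the original height."""
    if factor <= 1.0:
        return np.asarray(slices, dtype=np.float32).copy()
    h = slices.shape[1]
    low = downsample_axis(np.asarray(slices, dtype=np.float64), 1,
                          max(int(round(h / factor)), 2))
    return upsample_axis(low, 1, h).astype(np.float32)


def extract_slice_sets(vol: Volume3D, orientations: tuple[str, ...] = ("xz", "yz")
                       ) -> SliceSets:
    """Build the X/Y/Z slice sets from one anisotropic volume."""
    dz, _, dx = vol.spacing
    if dz < dx - 1e-9:
        raise ValueError(
            f"dz ({dz}) < dx ({dx}): the method assumes the axial direction "
            "is the poorly sampled one"
        )
    factor = dz / dx
    data = np.asarray(vol.data, dtype=np.float32)
    nz, ny, nx = data.shape
    X = data.copy()
    Y = degrade_lateral(data, factor)
    new_nz = int(round(nz * factor))
    Z: list[np.ndarray] = []
    if "xz" in orientations:
        xz = data.transpose(1, 0, 2)  # (ny, nz, nx): vertical axis is z
        Z.extend(np.ascontiguousarray(s) for s in
                 (upsample_axis(xz, 1, new_nz) if new_nz != nz else xz))
    if "yz" in orientations:
        yz = data.transpose(2, 0, 1)  # (nx, nz, ny)
        Z.extend(np.ascontiguousarray(s) for s in
                 (upsample_axis(yz, 1, new_nz) if new_nz != nz else yz))
    if not Z:
        raise ValueError("at least one axial orientation is required")
    return SliceSets(X=X, Y=Y, Z=[z.astype(np.float32) for z in Z],
                     aniso_factor=factor)


_DIHEDRAL = 8  # 4 rotations x optional flip


def _apply_dihedral(img: np.ndarray, k: int) -> np.ndarray:
    out = np.rot90(img, k % 4)
    if k >= 4:
        out = np.flipud(out)
    return out


def sample_patches(sets: SliceSets, patch: int = 64, batch: int = 8,
                   augment: bool = True, seed: int = 0):
    """Yield training minibatches forever (caller bounds the iteration count).

    Each batch is a dict with pixel-aligned ``x``/``y`` patch stacks and an
    unpaired ``z`` stack, each of shape (batch, 1, patch, patch).
    Augmentation applies the same random rotation/flip to an (x, y) pair.
    Deterministic under ``seed``.
    """
    n, h, w = sets.X.shape
    if h < patch or w < patch:
        raise ValueError(
            f"lateral slices ({h}x{w}) smaller than patch {patch}; "
            "pad the data or choose a smaller patch"
        )
    z_ok = [z for z in sets.Z if z.shape[0] >= patch and z.shape[1] >= patch]
    if not z_ok:
        raise ValueError("no axial slice large enough for the patch size")
    rng = np.random.default_rng(seed)
    while True:
        xb = np.empty((batch, 1, patch, patch), dtype=np.float32)
        yb = np.empty_like(xb)
        zb = np.empty_like(xb)
        for b in range(batch):
            i = rng.integers(n)
            r = rng.integers(h - patch + 1)
            c = rng.integers(w - patch + 1)
            xp = sets.X[i, r:r + patch, c:c + patch]
            yp = sets.Y[i, r:r + patch, c:c + patch]
            if augment:
                k = int(rng.integers(_DIHEDRAL))
                xp = _apply_dihedral(xp, k)
                yp = _apply_dihedral(yp, k)
            xb[b, 0] = xp
            yb[b, 0] = yp
            zs = z_ok[rng.integers(len(z_ok))]
            zr = rng.integers(zs.shape[0] - patch + 1)
            zc = rng.integers(zs.shape[1] - patch + 1)
            zp = zs[zr:zr + patch, zc:zc + patch]
            if augment:
                zb[b, 0] = _apply_dihedral(zp, int(rng.integers(_DIHEDRAL)))
            else:
                zb[b, 0] = zp
        yield {"x": xb, "y": yb, "z": zb}
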