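"""Core containers: 3D intensity volumes and blur kernels.

Axis order is (z, y, x) everywhere in the package; "vertical" in a 2D lateral
slice means the y axis, and in an axial slice it means the z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Nonnegative, finite intensities.
    spacing : tuple of float
        Voxel sizes ``(dz, dy, dx)`` in micrometres.  Lateral pixels must be
        square (``dy == dx``); the anisotropy factor is ``dz / dx``.
    value_range : tuple of float, optional
        Semantic (min, max) of the stored dtype; defaults to the data range.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    value_range: tuple[float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        dz, dy, dx = self.spacing
        if not np.isclose(dy, dx):
            raise ValueError(f"lateral pixels must be square, got dy={dy}, dx={dx}")
        if min(dz, dy, dx) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.size and self.data.min() < 0:
            raise ValueError("volume contains negative intensities")
        if self.value_range is None:
            lo = float(self.data.min()) if self.data.size else 0.0
            hi = float(self.data.max()) if self.data.size else 1.0
            self.value_range = (lo, hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def anisotropy_factor(self) -> float:
        dz, _, dx = self.spacing
        return dz / dx


@dataclass
class PSFKernel:
    """A nonnegative, unit-sum blur kernel with odd extent along every axis.

    ``center`` is the peak index; after :meth:`normalize` the kernel sums to 1
    and the peak sits at the geometric centre.
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    center: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError("PSF must be 2D or 3D")
        if any(s % 2 == 0 for s in self.data.shape):
            raise ValueError(f"all PSF dims must be odd, got {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("PSF must be nonnegative")
        total = self.data.sum()
        if total <= 0:
            raise ValueError("PSF must have positive mass")
        self.data = self.data / total
        if self.center is None:
            self.center = tuple(
                int(i) for i in np.unravel_index(np.argmax(self.data), self.data.shape)
            )

    @property
    def is_centered(self) -> bool:
        return self.center == tuple(s // 2 for s in self.data.shape)
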