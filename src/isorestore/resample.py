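"""Single-axis resampling primitives shared by the data pipeline.

Downsampling is exact area averaging (each output cell is the mean of the
source signal over its footprint, computed from a linearly interpolated
cumulative integral), which is alias-free for the blur-then-subsample
degradation being modelled.  Upsampling is cubic-spline interpolation with the
cell-centre grid convention, clipped to the source range so interpolation
never manufactures intensities outside the data.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def downsample_axis(arr: np.ndarray, axis: int, new_len: int) -> np.ndarray:
    """Area-average ``arr`` along ``axis`` to ``new_len`` samples."""
    n = arr.shape[axis]
    if new_len == n:
        return arr.copy()
    if not 1 <= new_len <= n:
        raise ValueError(f"new_len {new_len} outside [1, {n}]")
    a = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, -1)
    cum = np.concatenate(
        [np.zeros(a.shape[:-1] + (1,)), np.cumsum(a, axis=-1)], axis=-1
    )
    edges = np.linspace(0.0, float(n), new_len + 1)
    idx = np.floor(edges).astype(int).clip(0, n)
    frac = edges - idx
    # linear interpolation of the cumulative integral at fractional edges
    nxt = np.clip(idx + 1, 0, n)
    cum_at = cum[..., idx] + frac * (cum[..., nxt] - cum[..., idx])
    out = np.diff(cum_at, axis=-1) / np.diff(edges)
    return np.moveaxis(out, -1, axis)


def upsample_axis(arr: np.ndarray, axis: int, new_len: int) -> np.ndarray:
    """Cubic interpolation of ``arr`` along ``axis`` to ``new_len`` samples."""
    n = arr.shape[axis]
    if new_len == n:
        return arr.copy()
    if new_len < 1:
        raise ValueError("new_len must be positive")
    a = np.moveaxis(np.asarray(arr, dtype=np.float64), axis, -1)
    # cell-centre convention: output sample k sits at source position
    # (k + 0.5) * n / new_len - 0.5
    coords = (np.arange(new_len) + 0.5) * (n / new_len) - 0.5
    coords = np.clip(coords, 0.0, n - 1.0)
    if n >= 4:
        spline = CubicSpline(np.arange(n), a, axis=-1)
        out = spline(coords)
    else:  # too few samples for a cubic; fall back to linear
        out = np.stack(
            [np.interp(coords, np.arange(n), row) for row in a.reshape(-1, n)]
        ).reshape(a.shape[:-1] + (new_len,))
    out = np.clip(out, a.min(), a.max())
    return np.moveaxis(out, -1, axis)


def resample_axis(arr: np.ndarray, axis: int, new_len: int) -> np.ndarray:
    """Area-average when shrinking, cubic-interpolate when enlarging."""
    if new_len <= arr.shape[axis]:
        return downsample_axis(arr, axis, new_len)
    return upsample_axis(arr, axis, new_len)
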