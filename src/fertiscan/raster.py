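"""Raster data model, I/O, grayscale conversion and resampling.

All imagery is held in memory as float64 intensities in [0, 1], row-major
with the origin at the top-left pixel. Files (8/16-bit PNG or TIFF) are
rescaled on read and quantized on write, so the fusion arithmetic downstream
is always performed on a well-defined real-valued domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Raster",
    "ScaleSpec",
    "FormatError",
    "read_raster",
    "write_raster",
    "to_grayscale",
    "resample",
    "RESAMPLING_METHODS",
]

# ITU-R BT.601 luma weights (sum to 1, so grayscale stays in [0, 1])
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

RESAMPLING_METHODS = ("nearest", "bilinear", "cubic")


class FormatError(ValueError):
    """Raised for files whose layout the raster model does not support."""


@dataclass(frozen=True)
class Raster:
    """A 1- or 3-band pixel grid with intensities in [0, 1].

    ``data`` has shape (height, width) for single-band images or
    (height, width, 3) for RGB; dtype is float64.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            pass
        elif arr.ndim == 3 and arr.shape[2] == 3:
            pass
        else:
            raise FormatError(
                f"raster must be (H, W) or (H, W, 3); got shape {arr.shape}"
            )
        if arr.size == 0:
            raise FormatError("raster must contain at least one pixel")
        if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0 or np.isnan(arr).any():
            raise ValueError("raster intensities must lie in [0, 1]")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return 1 if self.data.ndim == 2 else 3


# 1 acre in square metres (exact, international yard)
ACRE_M2 = 4046.8564224
_M_PER_YARD = 0.9144


@dataclass(frozen=True)
class ScaleSpec:
    """Ground sampling distance of an image, in metres per pixel."""

    ground_m_per_px: float

    def __post_init__(self) -> None:
        if not self.ground_m_per_px > 0:
            raise ValueError("ground_m_per_px must be positive")

    @classmethod
    def from_map_scale(
        cls, yards_per_cm: float = 126.0, pixels_per_cm: float = 37.795
    ) -> "ScaleSpec":
        """Build a scale from a printed-map convention.

        A map viewed at ``yards_per_cm`` ground distance per on-screen
        centimetre, rendered at ``pixels_per_cm`` (default 96 dpi), has
        ground_m_per_px = yards_per_cm * 0.9144 / pixels_per_cm.
        """
        if yards_per_cm <= 0 or pixels_per_cm <= 0:
            raise ValueError("map-scale parameters must be positive")
        return cls(yards_per_cm * _M_PER_YARD / pixels_per_cm)


def read_raster(path: str | Path) -> Raster:
    """Read an 8- or 16-bit PNG/TIFF as a [0, 1]-scaled :class:`Raster`."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read raster {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise FormatError(
            f"{path}: unsupported channel count {arr.shape[2]} (need 1 or 3)"
        )
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: unsupported raster layout {arr.shape}")
    if arr.dtype == np.uint8:
        data = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        data = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        data = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise FormatError(f"{path}: unsupported sample type {arr.dtype}")
    return Raster(data)


def write_raster(img: Raster, path: str | Path, bit_depth: int = 8) -> None:
    """Quantize to ``bit_depth`` bits and write PNG or TIFF by extension."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    maxval = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantized = np.rint(img.data * maxval).astype(dtype)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, quantized)
        else:
            iio.imwrite(path, quantized, extension=path.suffix or ".png")
    except Exception as exc:
        raise IOError(f"could not write raster {path}: {exc}") from exc


def to_grayscale(img: Raster) -> Raster:
    """Collapse RGB to luminance: 0.299 R + 0.587 G + 0.114 B."""
    if img.bands != 3:
        raise ValueError("to_grayscale requires a 3-band raster")
    gray = img.data @ LUMA_WEIGHTS
    return Raster(np.clip(gray, 0.0, 1.0))


def _keys_cubic(x: np.ndarray) -> np.ndarray:
    # Cubic-convolution kernel of Keys with a = -0.5; interpolates
    # constants and linear ramps exactly.
    x = np.abs(x)
    out = np.zeros_like(x)
    near = x <= 1.0
    mid = (x > 1.0) & (x < 2.0)
    out[near] = 1.5 * x[near] ** 3 - 2.5 * x[near] ** 2 + 1.0
    out[mid] = -0.5 * x[mid] ** 3 + 2.5 * x[mid] ** 2 - 4.0 * x[mid] + 2.0
    return out


def _interp_axis(arr: np.ndarray, n_out: int, method: str) -> np.ndarray:
    """Interpolate ``arr`` along axis 0 to ``n_out`` samples.

    Pixel-centre convention: output pixel i samples the source coordinate
    (i + 0.5) * n_in / n_out - 0.5; border pixels are replicated. The sum
    is accumulated as nearest-tap + sum_k w_k * (tap_k - nearest-tap) —
    algebraically identical to the plain weighted sum (the weights total 1)
    but bit-exact on constant inputs for every method.
    """
    n_in = arr.shape[0]
    x = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    near = np.clip(np.floor(x + 0.5).astype(int), 0, n_in - 1)
    if method == "nearest":
        return arr[near]
    i0 = np.floor(x).astype(int)
    t = x - i0
    if method == "bilinear":
        taps = [(0, 1.0 - t), (1, t)]
    elif method == "cubic":
        taps = [(off, _keys_cubic(t - off)) for off in (-1, 0, 1, 2)]
    else:
        raise ValueError(
            f"unknown resampling method {method!r}; expected one of {RESAMPLING_METHODS}"
        )
    ref = arr[near]
    shape = (n_out,) + (1,) * (arr.ndim - 1)
    out = ref.astype(np.float64).copy()
    for off, wt in taps:
        idx = np.clip(i0 + off, 0, n_in - 1)
        out += wt.reshape(shape) * (arr[idx] - ref)
    return out


def resample(img: Raster, target_w: int, target_h: int, method: str = "bilinear") -> Raster:
    """Resize to (target_w, target_h) by separable interpolation.

    ``method`` is one of ``nearest``, ``bilinear`` or ``cubic`` (cubic
    convolution, Keys kernel a = -0.5). Results are clipped to [0, 1];
    constant images are reproduced exactly under every method.
    """
    if target_w < 1 or target_h < 1:
        raise ValueError("target dimensions must be positive")
    out = _interp_axis(img.data, target_h, method)
    out = np.swapaxes(_interp_axis(np.swapaxes(out, 0, 1), target_w, method), 0, 1)
    return Raster(np.clip(out, 0.0, 1.0))
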