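"""HSV conversion, green-hue masking and acreage estimation.

Vegetation is segmented in HSV space: a pixel counts as green when its hue
falls inside a configurable window (default 70-170 degrees) and its
saturation and value clear small floors that reject gray rooftops and dark
asphalt. The resulting binary mask, combined with the image's ground
sampling distance, yields the green area in square metres and acres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, morphology

from .raster import ACRE_M2, Raster, ScaleSpec

__all__ = [
    "HSVGrid",
    "HueWindow",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "green_mask",
    "apply_negation_mask",
    "area_acres",
    "GreenAreaReport",
    "green_area_report",
]


@dataclass(frozen=True)
class HSVGrid:
    """Per-pixel hue (degrees in [0, 360)), saturation and value in [0, 1]."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray


@dataclass(frozen=True)
class HueWindow:
    """Closed hue interval plus saturation/value floors defining 'green'."""

    hue_lo: float = 70.0
    hue_hi: float = 170.0
    sat_min: float = 0.15
    val_min: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.hue_lo < self.hue_hi < 360):
            raise ValueError("need 0 <= hue_lo < hue_hi < 360")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_min <= 1):
            raise ValueError("sat_min and val_min must lie in [0, 1]")


def rgb_to_hsv(img: Raster) -> HSVGrid:
    """Convert an RGB raster to HSV with hue in degrees.

    V = max(R,G,B); S = (max-min)/max (0 where V = 0); H follows the
    standard max-branch formulas with achromatic pixels assigned H = 0.
    """
    if img.bands != 3:
        raise ValueError("rgb_to_hsv requires a 3-band raster")
    hsv = color.rgb2hsv(img.data)
    return HSVGrid(h=hsv[:, :, 0] * 360.0, s=hsv[:, :, 1], v=hsv[:, :, 2])


def hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> Raster:
    """Inverse conversion; hue in degrees."""
    hsv = np.stack([np.asarray(h) / 360.0, s, v], axis=2)
    return Raster(np.clip(color.hsv2rgb(hsv), 0.0, 1.0))


def green_mask(hsv: HSVGrid, window: HueWindow = HueWindow(),
               min_blob_px: int = 0) -> np.ndarray:
    """Binary vegetation mask: 1 where hue/saturation/value pass the window.

    ``min_blob_px`` optionally removes connected components smaller than
    that many pixels (off by default; the base method is pure thresholding).
    """
    mask = (
        (hsv.h >= window.hue_lo)
        & (hsv.h <= window.hue_hi)
        & (hsv.s >= window.sat_min)
        & (hsv.v >= window.val_min)
    )
    if min_blob_px > 0:
        mask = morphology.remove_small_objects(mask, max_size=min_blob_px - 1)
    return mask.astype(np.uint8)


def apply_negation_mask(img: Raster, mask: np.ndarray) -> Raster:
    """Black out every pixel outside the mask, isolating the green regions."""
    if img.bands != 3:
        raise ValueError("apply_negation_mask expects a 3-band raster")
    mask = np.asarray(mask)
    if mask.shape != img.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.data.shape[:2]}"
        )
    return Raster(img.data * (mask > 0)[:, :, None])


def area_acres(mask: np.ndarray, scale: ScaleSpec) -> tuple[float, int]:
    """Green area in acres plus the raw pixel count.

    acres = n_green * ground_m_per_px**2 / 4046.8564224
    """
    n = int(np.count_nonzero(mask))
    return n * scale.ground_m_per_px**2 / ACRE_M2, n


@dataclass(frozen=True)
class GreenAreaReport:
    green_pixels: int
    total_pixels: int
    green_fraction: float
    area_m2: float
    area_acres: float

    def to_dict(self) -> dict:
        return {
            "green_pixels": self.green_pixels,
            "total_pixels": self.total_pixels,
            "green_fraction": self.green_fraction,
            "area_m2": self.area_m2,
            "area_acres": self.area_acres,
        }


def green_area_report(img: Raster, window: HueWindow, scale: ScaleSpec,
                      min_blob_px: int = 0) -> tuple[GreenAreaReport, np.ndarray]:
    """Segment an RGB image and quantify its green area."""
    mask = green_mask(rgb_to_hsv(img), window, min_blob_px)
    acres, n = area_acres(mask, scale)
    total = mask.size
    report = GreenAreaReport(
        green_pixels=n,
        total_pixels=total,
        green_fraction=n / total,
        area_m2=n * scale.ground_m_per_px**2,
        area_acres=acres,
    )
    return report, mask
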