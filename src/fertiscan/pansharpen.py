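"""Pan-sharpening: high-pass-filter fusion and the Brovey ratio transform.

Two classic fusions of a high-resolution panchromatic band P with a
lower-resolution multispectral image:

* HPF fusion: ``sharpened = clip(M + lambda * F(P))`` where M is the
  grayscale multispectral image and F is a zero-sum high-pass kernel
  (3x3 Laplacian or a difference of Gaussians).
* Brovey transform: each band is modulated by the panchromatic intensity
  divided by the sum of the three bands,
  ``Y_k = X_k * X_p / (X_R + X_G + X_B)``, which preserves band ratios
  (hue) while injecting the pan band's spatial detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import Raster, resample, to_grayscale

__all__ = [
    "FusionConfig",
    "LAPLACIAN3",
    "high_pass",
    "hpf_sharpen",
    "brovey",
    "sharpen_pipeline",
]

logger = logging.getLogger(__name__)

LAPLACIAN3 = np.array([[0.0, -1.0, 0.0], [-1.0, 4.0, -1.0], [0.0, -1.0, 0.0]])

KERNELS = ("laplacian3", "dog")


@dataclass(frozen=True)
class FusionConfig:
    """Parameters of the fusion stage.

    lambda_weight scales the high-pass detail added in HPF fusion;
    epsilon guards the Brovey denominator against all-black pixels;
    dog_sigmas are the two Gaussian widths of the DoG kernel.
    """

    lambda_weight: float = 1.0
    kernel: str = "laplacian3"
    dog_sigmas: tuple[float, float] = (1.0, 2.0)
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        s1, s2 = self.dog_sigmas
        if not (0 < s1 < s2):
            raise ValueError("dog_sigmas must satisfy 0 < sigma1 < sigma2")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; expected one of {KERNELS}")


def high_pass(img: Raster, kernel: str = "laplacian3",
              dog_sigmas: tuple[float, float] = (1.0, 2.0)) -> np.ndarray:
    """High-pass response F(P) of a single-band image.

    Returns an unclipped signed field with the image's shape. Both kernels
    have zero DC gain, so constant images map to an identically zero field.
    Boundaries are handled by reflect padding.
    """
    if img.bands != 1:
        raise ValueError("high_pass requires a single-band raster")
    if kernel == "laplacian3":
        return ndimage.convolve(img.data, LAPLACIAN3, mode="reflect")
    if kernel == "dog":
        s1, s2 = dog_sigmas
        narrow = ndimage.gaussian_filter(img.data, s1, mode="reflect")
        wide = ndimage.gaussian_filter(img.data, s2, mode="reflect")
        return narrow - wide
    raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


def hpf_sharpen(m: Raster, p: Raster, cfg: FusionConfig = FusionConfig()) -> Raster:
    """Add lambda-weighted high-pass detail of P to M, clipped to [0, 1]."""
    if m.bands != 1 or p.bands != 1:
        raise ValueError("hpf_sharpen operates on single-band rasters")
    if m.data.shape != p.data.shape:
        raise ValueError(
            f"dimension mismatch: M is {m.data.shape}, P is {p.data.shape}"
        )
    detail = high_pass(p, cfg.kernel, cfg.dog_sigmas)
    return Raster(np.clip(m.data + cfg.lambda_weight * detail, 0.0, 1.0))


def brovey(ms: Raster, pan: Raster, cfg: FusionConfig = FusionConfig(),
           clip: bool = True) -> Raster | np.ndarray:
    """Brovey ratio fusion of an RGB image with a panchromatic band.

    Per pixel and band k: ``Y_k = X_k * X_p / max(X_R + X_G + X_B, eps)``.
    With ``clip=False`` the raw (possibly > 1) field is returned as an
    ndarray, which satisfies the conservation identity
    ``sum_k Y_k == X_p`` wherever the band sum exceeds eps.
    """
    if ms.bands != 3:
        raise ValueError("brovey requires a 3-band multispectral raster")
    if pan.bands != 1:
        raise ValueError("brovey requires a single-band panchromatic raster")
    if ms.data.shape[:2] != pan.data.shape:
        raise ValueError(
            f"dimension mismatch: MS is {ms.data.shape[:2]}, pan is {pan.data.shape}"
        )
    band_sum = ms.data.sum(axis=2)
    ratio = pan.data / np.maximum(band_sum, cfg.epsilon)
    fused = ms.data * ratio[:, :, None]
    if not clip:
        return fused
    return Raster(np.clip(fused, 0.0, 1.0))


def _hsv_value_replace(rgb: Raster, luminance: Raster) -> Raster:
    # Optional route: keep hue/saturation of the fused image but carry the
    # fused luminance in the HSV value channel.
    from .greenmask import hsv_to_rgb, rgb_to_hsv

    hsv = rgb_to_hsv(rgb)
    return hsv_to_rgb(hsv.h, hsv.s, np.clip(luminance.data, 0.0, 1.0))


def sharpen_pipeline(
    ms_lowres: Raster,
    pan: Raster,
    method: str = "brovey",
    resampling: str = "bilinear",
    cfg: FusionConfig = FusionConfig(),
    hsv_route: bool = False,
) -> Raster:
    """Full sharpening chain: resample to the pan grid, then fuse.

    ``method='brovey'`` returns a 3-band image; ``method='hpf'`` converts
    the multispectral image to grayscale first and returns a single band.
    ``hsv_route`` (Brovey only) converts the upsampled RGB to HSV, replaces
    the value channel with the Brovey-fused luminance and converts back.
    """
    if pan.bands != 1:
        raise ValueError("pan input must be single-band")
    if pan.width < ms_lowres.width or pan.height < ms_lowres.height:
        raise ValueError("pan resolution must be >= multispectral resolution")
    ms_up = resample(ms_lowres, pan.width, pan.height, resampling)
    logger.info(
        "sharpen: ms %dx%d -> %dx%d (%s), method=%s",
        ms_lowres.width, ms_lowres.height, pan.width, pan.height, resampling, method,
    )
    if method == "brovey":
        fused = brovey(ms_up, pan, cfg)
        if hsv_route:
            return _hsv_value_replace(ms_up, to_grayscale(fused))
        return fused
    if method == "hpf":
        if ms_up.bands == 3:
            ms_up = to_grayscale(ms_up)
        return hpf_sharpen(ms_up, pan, cfg)
    raise ValueError(f"unknown fusion method {method!r}; expected 'brovey' or 'hpf'")
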