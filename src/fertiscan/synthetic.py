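"""Seeded generators for satellite-like test scenes and attribute suites.

No public imagery ships with the package; instead, scenes with *known*
green-pixel ground truth are rendered on demand: a tan soil background, gray
rectangular buildings, dark road polylines, and elliptical vegetation
patches painted last with hues drawn from [80, 150] degrees. The exact
vegetation pixel set is recorded before additive noise is applied, so
segmentation accuracy can be scored against truth. A matching panchromatic
band (grayscale of the high-resolution scene) and a blurred, downsampled
multispectral image give the fusion stage realistic work to do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .geoattrs import GeoAttributes
from .greenmask import hsv_to_rgb
from .raster import Raster, to_grayscale

__all__ = ["SceneSpec", "SceneBundle", "generate_scene", "generate_attribute_suite"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene."""

    width: int = 256
    height: int = 256
    n_green_patches: int = 4
    n_buildings: int = 5
    n_roads: int = 2
    noise_sigma: float = 0.0
    seed: int = 0
    downsample: int = 4
    blur_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


@dataclass(frozen=True)
class SceneBundle:
    """A rendered scene plus its derived inputs and ground truth."""

    hires_rgb: Raster
    pan: Raster
    ms_lowres: Raster
    truth_mask: np.ndarray
    truth_green_px: int


# Scene palette (RGB in [0, 1])
_SOIL = np.array([0.82, 0.71, 0.55])
_BUILDING_GRAY = (0.45, 0.75)  # value range; zero saturation
_ROAD = np.array([0.04, 0.04, 0.05])  # dark asphalt, below the mask's value floor

# Vegetation paint: hue range with >=10 degrees margin inside the default
# green window, saturation and value well above the mask floors.
_VEG_HUE = (80.0, 150.0)
_VEG_SAT = (0.5, 0.9)
_VEG_VAL = (0.4, 0.8)


def _ellipse_mask(h: int, w: int, cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Render one scene deterministically from its spec.

    Vegetation is painted last, so the recorded truth mask reflects final
    pixel ownership even where patches overlap buildings or roads. Noise
    (clipped additive Gaussian) is applied after truth is recorded.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3))
    img[:] = _SOIL
    # slight soil mottling keeps the background off a single RGB value
    img += rng.normal(0.0, 0.01, size=(h, w, 1))
    img = np.clip(img, 0.0, 1.0)

    for _ in range(spec.n_buildings):
        bh = rng.integers(max(2, h // 32), max(3, h // 8))
        bw = rng.integers(max(2, w // 32), max(3, w // 8))
        r0 = rng.integers(0, max(1, h - bh))
        c0 = rng.integers(0, max(1, w - bw))
        img[r0:r0 + bh, c0:c0 + bw, :] = rng.uniform(*_BUILDING_GRAY)

    for _ in range(spec.n_roads):
        if rng.random() < 0.5:
            r0, r1 = rng.integers(0, h, size=2)
            c0, c1 = 0, w - 1
        else:
            r0, r1 = 0, h - 1
            c0, c1 = rng.integers(0, w, size=2)
        rr, cc = draw.line(int(r0), int(c0), int(r1), int(c1))
        road = np.zeros((h, w), dtype=bool)
        road[rr, cc] = True
        road = ndimage.binary_dilation(road, iterations=1)
        img[road] = _ROAD

    truth = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_green_patches):
        ry = rng.uniform(h / 32, h / 8)
        rx = rng.uniform(w / 32, w / 8)
        cy = rng.uniform(ry, h - 1 - ry)
        cx = rng.uniform(rx, w - 1 - rx)
        patch = _ellipse_mask(h, w, cy, cx, ry, rx)
        hue = rng.uniform(*_VEG_HUE)
        sat = rng.uniform(*_VEG_SAT)
        val = rng.uniform(*_VEG_VAL)
        rgb = hsv_to_rgb(
            np.full((1, 1), hue), np.full((1, 1), sat), np.full((1, 1), val)
        ).data[0, 0]
        img[patch] = rgb
        truth |= patch

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    hires = Raster(np.clip(img, 0.0, 1.0))

    pan = to_grayscale(hires)
    blurred = ndimage.gaussian_filter(
        hires.data, sigma=(spec.blur_sigma, spec.blur_sigma, 0), mode="reflect"
    )
    step = spec.downsample
    ms_lowres = Raster(np.clip(blurred[::step, ::step, :], 0.0, 1.0))
    return SceneBundle(
        hires_rgb=hires,
        pan=pan,
        ms_lowres=ms_lowres,
        truth_mask=truth.astype(np.uint8),
        truth_green_px=int(truth.sum()),
    )


# Sampling ranges for each category level (matches ThresholdConfig defaults)
_TEMP_BAND = {"hot": (31.0, 42.0), "moderate": (20.0, 30.0), "cool": (5.0, 19.0)}
_HUMIDITY_BAND = {"low": (10.0, 40.0), "moderate": (41.0, 69.0), "high": (70.0, 98.0)}
_WIND_BAND = {"low": (0.0, 19.0), "high": (20.0, 60.0)}
_PRECIP_BAND = {"low": (0.0, 9.0), "high": (10.0, 40.0)}
_UV_BAND = {"low": (0.0, 5.0), "high": (6.0, 11.0)}
_SOIL_BAND = {"low": (0.02, 0.29), "high": (0.30, 0.60)}


def generate_attribute_suite(seed: int = 0) -> list[GeoAttributes]:
    """One record per category combination, values sampled inside each band.

    Covers the full cartesian product of temperature band, humidity level,
    wind, precipitation, UV, soil level and terrain (288 records), so every
    branch of the rule engine is reachable from the suite. Deterministic in
    the seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    for temp in _TEMP_BAND:
        for hum in _HUMIDITY_BAND:
            for wind in _WIND_BAND:
                for precip in _PRECIP_BAND:
                    for uv in _UV_BAND:
                        for soil in _SOIL_BAND:
                            for terrain in ("plain", "hilly"):
                                records.append(
                                    GeoAttributes(
                                        temperature_c=rng.uniform(*_TEMP_BAND[temp]),
                                        humidity_pct=rng.uniform(*_HUMIDITY_BAND[hum]),
                                        wind_kmh=rng.uniform(*_WIND_BAND[wind]),
                                        precip_mm_day=rng.uniform(*_PRECIP_BAND[precip]),
                                        uv_index=rng.uniform(*_UV_BAND[uv]),
                                        soil_moisture_vwc=rng.uniform(*_SOIL_BAND[soil]),
                                        terrain=terrain,
                                        location_name=(
                                            f"{temp}-{hum}-w{wind}-p{precip}"
                                            f"-u{uv}-s{soil}-{terrain}"
                                        ),
                                    )
                                )
    return records
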