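"""Environmental attribute records and their discretization.

The recommendation engine reasons over coarse categories (hot/moderate/cool
temperature, low/moderate/high humidity, ...) rather than raw measurements.
This module defines the record schema, file loading with validation, and the
thresholding that maps measurements onto those categories. Only the 30 °C
"hot" cut-point and the 20-30 °C moderate band are fixed by the decision
procedure being modelled; every other cut-point is a configurable default
(UV >= 6 is "high" per the WHO UV-index convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "GeoAttributes",
    "CategoricalAttrs",
    "ThresholdConfig",
    "SchemaError",
    "load_attributes",
    "categorize",
    "thresholds_from_yaml",
]

TERRAINS = ("plain", "hilly")


class SchemaError(ValueError):
    """Raised when an attribute file is missing required columns."""


@dataclass(frozen=True)
class GeoAttributes:
    """One location's environmental record."""

    temperature_c: float
    humidity_pct: float
    wind_kmh: float
    precip_mm_day: float
    uv_index: float
    soil_moisture_vwc: float
    terrain: str = "plain"
    location_name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.humidity_pct <= 100:
            raise ValueError(
                f"humidity_pct must lie in [0, 100]; got {self.humidity_pct}"
            )
        if not 0 <= self.soil_moisture_vwc <= 1:
            raise ValueError(
                f"soil_moisture_vwc must lie in [0, 1]; got {self.soil_moisture_vwc}"
            )
        if self.uv_index < 0:
            raise ValueError(f"uv_index must be >= 0; got {self.uv_index}")
        if self.wind_kmh < 0 or self.precip_mm_day < 0:
            raise ValueError("wind_kmh and precip_mm_day must be >= 0")
        if self.terrain not in TERRAINS:
            raise ValueError(f"terrain must be one of {TERRAINS}; got {self.terrain!r}")


@dataclass(frozen=True)
class CategoricalAttrs:
    """Discrete levels the rule engine branches on."""

    temp_band: str  # hot | moderate | cool
    humidity_level: str  # low | moderate | high
    wind_level: str  # low | high
    precip_level: str  # low | high
    uv_level: str  # low | high
    soil_level: str  # low | high
    terrain: str  # plain | hilly

    _LEVELS = {
        "temp_band": ("hot", "moderate", "cool"),
        "humidity_level": ("low", "moderate", "high"),
        "wind_level": ("low", "high"),
        "precip_level": ("low", "high"),
        "uv_level": ("low", "high"),
        "soil_level": ("low", "high"),
        "terrain": TERRAINS,
    }

    def __post_init__(self) -> None:
        for name, levels in self._LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValueError(
                    f"{name} must be one of {levels}; got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class ThresholdConfig:
    """Cut-points mapping measurements to categories.

    Temperature above ``temp_hot_c`` is hot; the closed band
    [temp_moderate_lo_c, temp_hot_c] is moderate; below is cool.
    Humidity at or below ``humidity_low_pct`` is low, at or above
    ``humidity_high_pct`` high, else moderate. The remaining dimensions are
    binary: at or above the threshold is high.
    """

    temp_hot_c: float = 30.0
    temp_moderate_lo_c: float = 20.0
    humidity_low_pct: float = 40.0
    humidity_high_pct: float = 70.0
    wind_high_kmh: float = 20.0
    precip_high_mm_day: float = 10.0
    uv_high: float = 6.0
    soil_high_vwc: float = 0.30

    def __post_init__(self) -> None:
        if not self.temp_moderate_lo_c < self.temp_hot_c:
            raise ValueError("temp_moderate_lo_c must be < temp_hot_c")
        if not self.humidity_low_pct < self.humidity_high_pct:
            raise ValueError("humidity_low_pct must be < humidity_high_pct")


_REQUIRED = [
    "temperature_c",
    "humidity_pct",
    "wind_kmh",
    "precip_mm_day",
    "uv_index",
    "soil_moisture_vwc",
]
_OPTIONAL = {"terrain": "plain", "location_name": ""}


def _record_from_row(row: dict, index: int) -> GeoAttributes:
    kwargs = {}
    for name in _REQUIRED:
        kwargs[name] = float(row[name])
    for name, default in _OPTIONAL.items():
        value = row.get(name, default)
        if value is None or (isinstance(value, float) and pd.isna(value)):
            value = default
        kwargs[name] = str(value)
    try:
        return GeoAttributes(**kwargs)
    except ValueError as exc:
        raise ValueError(f"record {index}: {exc}") from exc


def load_attributes(path: str | Path) -> list[GeoAttributes]:
    """Load attribute records from a JSON array or CSV file.

    Every record is validated; the first invariant violation is reported
    with its row index.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: expected a JSON array of records")
    else:
        rows = pd.read_csv(path).to_dict("records")
    records = []
    for i, row in enumerate(rows):
        missing = [c for c in _REQUIRED if c not in row or pd.isna(row[c])]
        if missing:
            raise SchemaError(f"{path}: record {i} missing columns {missing}")
        records.append(_record_from_row(row, i))
    return records


def categorize(attrs: GeoAttributes, cfg: ThresholdConfig = ThresholdConfig()) -> CategoricalAttrs:
    """Map one record onto the engine's discrete levels.

    Total: every finite record maps to exactly one level per dimension.
    """
    t = attrs.temperature_c
    if t > cfg.temp_hot_c:
        temp_band = "hot"
    elif t >= cfg.temp_moderate_lo_c:
        temp_band = "moderate"
    else:
        temp_band = "cool"
    if attrs.humidity_pct <= cfg.humidity_low_pct:
        humidity = "low"
    elif attrs.humidity_pct >= cfg.humidity_high_pct:
        humidity = "high"
    else:
        humidity = "moderate"
    return CategoricalAttrs(
        temp_band=temp_band,
        humidity_level=humidity,
        wind_level="high" if attrs.wind_kmh >= cfg.wind_high_kmh else "low",
        precip_level="high" if attrs.precip_mm_day >= cfg.precip_high_mm_day else "low",
        uv_level="high" if attrs.uv_index >= cfg.uv_high else "low",
        soil_level="high" if attrs.soil_moisture_vwc >= cfg.soil_high_vwc else "low",
        terrain=attrs.terrain,
    )


def thresholds_from_yaml(path: str | Path) -> ThresholdConfig:
    """Read threshold overrides from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(ThresholdConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown threshold keys: {sorted(unknown)}")
    return ThresholdConfig(**data)
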