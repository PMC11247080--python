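"""Deterministic rule engine for crop suitability.

The engine transcribes a staged decision narrative — temperature with
humidity first, then wind, precipitation, UV index and soil moisture — into
an explicit, auditable rulebase. Additive rules vote (weight 1 by default)
for the crops their branch names; restrictive stages (high wind, high UV)
halve the score of crops outside the corresponding tolerant set rather than
adding votes. Crops are ranked by total score with ties broken by a fixed
canonical order, so identical inputs always yield identical rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geoattrs import CategoricalAttrs, GeoAttributes, ThresholdConfig, categorize

__all__ = [
    "CropRule",
    "Recommendation",
    "CROP_CANON",
    "builtin_rulebase",
    "recommend",
    "recommend_for_location",
    "rules_to_yaml",
    "rules_from_yaml",
]

logger = logging.getLogger(__name__)

# Canonical crop order: rule crops in order of first appearance in the
# decision narrative, then the extra crops of the reference calendar.
CROP_CANON = [
    "Groundnut",
    "Sunflower",
    "Millets",
    "Cotton",
    "Rice",
    "Sugarcane",
    "Ragi",
    "Maize",
    "Pigeon pea",
    "Chickpea",
    "Tomato",
    "Brinjal",
    "Okra",
    "Mango",
    "Banana",
    "Guava",
    "Coffee",
    "Tea",
    "Wheat",
    "Mustard",
    "Soybean",
]

MODERATE_BAND_CROPS = [
    "Rice",
    "Ragi",
    "Maize",
    "Pigeon pea",
    "Chickpea",
    "Tomato",
    "Brinjal",
    "Okra",
    "Mango",
    "Banana",
    "Guava",
]

# Editorial memberships: the narrative names the properties (wind-resistant,
# UV-tolerant) but not the crops; these defaults are configuration.
WIND_RESISTANT = ["Millets", "Ragi", "Sugarcane", "Groundnut"]
UV_TOLERANT = ["Millets", "Groundnut", "Sunflower", "Cotton", "Sugarcane"]

STAGES = ("temperature_humidity", "wind", "precipitation", "uv", "soil_moisture")


@dataclass(frozen=True)
class CropRule:
    """One branch of the decision procedure.

    ``when`` maps :class:`CategoricalAttrs` field names to required levels;
    the rule fires when all of them match. Additive rules add ``weight`` to
    each crop in ``crops``; restrictive rules multiply the score of every
    crop *outside* ``crops`` by ``penalty``.
    """

    stage: str
    when: dict
    crops: tuple[str, ...]
    weight: float = 1.0
    kind: str = "additive"  # additive | restrictive
    penalty: float = 0.5

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}; got {self.stage!r}")
        if not self.crops:
            raise ValueError("crops must be non-empty")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.kind not in ("additive", "restrictive"):
            raise ValueError(f"kind must be additive or restrictive; got {self.kind!r}")
        object.__setattr__(self, "crops", tuple(self.crops))
        object.__setattr__(self, "when", dict(self.when))

    def fires(self, cat: CategoricalAttrs) -> bool:
        return all(getattr(cat, k) == v for k, v in self.when.items())


@dataclass(frozen=True)
class Recommendation:
    """Ranked (crop, score) list with per-crop rule provenance."""

    ranked_crops: list[tuple[str, float]]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def crops(self) -> list[str]:
        return [c for c, _ in self.ranked_crops]


def builtin_rulebase() -> list[CropRule]:
    """The default rulebase, one rule per branch of the narrative."""
    th = "temperature_humidity"
    return [
        CropRule(th, {"temp_band": "hot", "humidity_level": "low"},
                 ("Groundnut", "Sunflower", "Millets", "Cotton")),
        CropRule(th, {"temp_band": "hot", "humidity_level": "high"},
                 ("Rice", "Sugarcane")),
        CropRule(th, {"temp_band": "moderate"}, tuple(MODERATE_BAND_CROPS)),
        CropRule(th, {"temp_band": "moderate", "terrain": "hilly"},
                 ("Coffee", "Tea")),
        CropRule("wind", {"wind_level": "high"}, tuple(WIND_RESISTANT),
                 kind="restrictive"),
        CropRule("precipitation", {"precip_level": "high"}, ("Rice", "Sugarcane")),
        CropRule("precipitation", {"precip_level": "low"},
                 ("Millets", "Groundnut", "Sunflower")),
        CropRule("uv", {"uv_level": "high"}, tuple(UV_TOLERANT),
                 kind="restrictive"),
        CropRule("soil_moisture", {"soil_level": "high"},
                 ("Rice", "Sugarcane", "Mango", "Guava", "Banana")),
        CropRule("soil_moisture", {"soil_level": "low"},
                 ("Millets", "Groundnut", "Sunflower")),
    ]


def _canon_index(crop: str) -> tuple[int, str]:
    try:
        return (CROP_CANON.index(crop), crop)
    except ValueError:
        return (len(CROP_CANON), crop)


def recommend(cat: CategoricalAttrs, rules: list[CropRule] | None = None,
              k: int = 5) -> Recommendation:
    """Rank crops for one categorized location.

    Deterministic: scores are summed additive votes, scaled by restrictive
    penalties; ties break by canonical crop order; the list is truncated to
    the top ``k``. If no additive rule fires (possible only with custom
    rulebases or under cool temperatures combined with neutral stages), the
    moderate-band crop list is returned as a fallback with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rules is None:
        rules = builtin_rulebase()
    if not rules:
        raise ValueError("rules must be non-empty")
    scores: dict[str, float] = {}
    provenance: dict[str, list[str]] = {}
    for rule in rules:
        if rule.kind != "additive" or not rule.fires(cat):
            continue
        for crop in rule.crops:
            scores[crop] = scores.get(crop, 0.0) + rule.weight
            provenance.setdefault(crop, []).append(rule.stage)
    if not scores:
        logger.warning(
            "no additive rule fired for %s; falling back to the moderate-band crops",
            cat,
        )
        for crop in MODERATE_BAND_CROPS:
            scores[crop] = 1.0
            provenance.setdefault(crop, []).append("fallback")
    for rule in rules:
        if rule.kind != "restrictive" or not rule.fires(cat):
            continue
        tolerant = set(rule.crops)
        for crop in scores:
            if crop not in tolerant:
                scores[crop] *= rule.penalty
                provenance.setdefault(crop, []).append(f"{rule.stage}-penalty")
    ranked = sorted(scores.items(), key=lambda cs: (-cs[1], _canon_index(cs[0])))
    ranked = ranked[:k]
    kept = {c for c, _ in ranked}
    return Recommendation(
        ranked_crops=ranked,
        provenance={c: provenance[c] for c in provenance if c in kept},
    )


def recommend_for_location(attrs: GeoAttributes,
                           cfg: ThresholdConfig = ThresholdConfig(),
                           rules: list[CropRule] | None = None,
                           k: int = 5) -> Recommendation:
    """Categorize a raw attribute record and rank crops for it."""
    return recommend(categorize(attrs, cfg), rules, k)


def rules_to_yaml(rules: list[CropRule], path: str | Path) -> None:
    """Serialize a rulebase so users can edit rules without code."""
    payload = [
        {
            "stage": r.stage,
            "when": dict(r.when),
            "crops": list(r.crops),
            "weight": r.weight,
            "kind": r.kind,
            "penalty": r.penalty,
        }
        for r in rules
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def rules_from_yaml(path: str | Path) -> list[CropRule]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, list) or not payload:
        raise ValueError(f"{path}: expected a non-empty YAML list of rules")
    return [CropRule(**entry) for entry in payload]
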