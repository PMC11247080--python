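"""Rule-engine branch outputs, totality, determinism and score conservation."""

import itertools

import pytest

from fertiscan.geoattrs import CategoricalAttrs, GeoAttributes, ThresholdConfig
from fertiscan.suitability import (
    CROP_CANON,
    CropRule,
    builtin_rulebase,
    recommend,
    recommend_for_location,
    rules_from_yaml,
    rules_to_yaml,
)

LEVELS = dict(
    temp_band=("hot", "moderate", "cool"),
    humidity_level=("low", "moderate", "high"),
    wind_level=("low", "high"),
    precip_level=("low", "high"),
    uv_level=("low", "high"),
    soil_level=("low", "high"),
    terrain=("plain", "hilly"),
)


def make_cat(**overrides):
    base = dict(
        temp_band="moderate",
        humidity_level="moderate",
        wind_level="low",
        precip_level="low",
        uv_level="low",
        soil_level="low",
        terrain="plain",
    )
    base.update(overrides)
    return CategoricalAttrs(**base)


def all_combinations():
    names = list(LEVELS)
    for values in itertools.product(*(LEVELS[n] for n in names)):
        yield CategoricalAttrs(**dict(zip(names, values)))


class TestRulebase:
    def _crops_for(self, stage, when):
        for rule in builtin_rulebase():
            if rule.stage == stage and rule.when == when:
                return set(rule.crops)
        raise AssertionError(f"no rule for {stage} {when}")

    def test_hot_low_humidity_crops(self):
        assert self._crops_for(
            "temperature_humidity", {"temp_band": "hot", "humidity_level": "low"}
        ) == {"Groundnut", "Sunflower", "Millets", "Cotton"}

    def test_hot_high_humidity_crops(self):
        assert self._crops_for(
            "temperature_humidity", {"temp_band": "hot", "humidity_level": "high"}
        ) == {"Rice", "Sugarcane"}

    def test_moderate_band_crops(self):
        crops = self._crops_for("temperature_humidity", {"temp_band": "moderate"})
        assert crops == {
            "Rice", "Ragi", "Maize", "Pigeon pea", "Chickpea",
            "Tomato", "Brinjal", "Okra", "Mango", "Banana", "Guava",
        }

    def test_hilly_moderate_adds_coffee_tea(self):
        assert self._crops_for(
            "temperature_humidity", {"temp_band": "moderate", "terrain": "hilly"}
        ) == {"Coffee", "Tea"}

    def test_precipitation_rules(self):
        assert self._crops_for("precipitation", {"precip_level": "high"}) == {
            "Rice", "Sugarcane",
        }
        assert self._crops_for("precipitation", {"precip_level": "low"}) == {
            "Millets", "Groundnut", "Sunflower",
        }

    def test_soil_moisture_rules(self):
        assert self._crops_for("soil_moisture", {"soil_level": "high"}) == {
            "Rice", "Sugarcane", "Mango", "Guava", "Banana",
        }
        assert self._crops_for("soil_moisture", {"soil_level": "low"}) == {
            "Millets", "Groundnut", "Sunflower",
        }

    def test_restrictive_stages(self):
        kinds = {r.stage: r.kind for r in builtin_rulebase()}
        assert kinds["wind"] == "restrictive"
        assert kinds["uv"] == "restrictive"

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            CropRule("wind", {}, ())
        with pytest.raises(ValueError):
            CropRule("bogus", {}, ("Rice",))
        with pytest.raises(ValueError):
            CropRule("wind", {}, ("Rice",), weight=0.0)


class TestRecommend:
    def test_hot_dry_ranking_puts_drought_crops_first(self):
        cat = make_cat(temp_band="hot", humidity_level="low")
        rec = recommend(cat, k=10)
        # Groundnut/Millets/Sunflower collect votes from the heat, rain and
        # soil stages; Cotton only from the heat stage
        top3 = set(rec.crops[:3])
        assert top3 == {"Groundnut", "Millets", "Sunflower"}
        assert rec.crops[3] == "Cotton" or rec.ranked_crops[3][1] >= 1.0

    def test_hilly_moderate_includes_coffee_and_tea(self):
        rec = recommend(make_cat(terrain="hilly"), k=20)
        assert "Coffee" in rec.crops and "Tea" in rec.crops

    def test_high_soil_moisture_ranks_rice_first(self):
        cat = make_cat(
            temp_band="hot", humidity_level="high",
            precip_level="high", soil_level="high",
        )
        rec = recommend(cat, k=5)
        assert rec.crops[0] == "Rice"

    def test_cool_neutral_falls_back_to_moderate_band(self, caplog):
        rules = [
            r for r in builtin_rulebase()
            if r.stage in ("temperature_humidity", "wind", "uv")
        ]
        cat = make_cat(temp_band="cool")
        with caplog.at_level("WARNING", logger="fertiscan.suitability"):
            rec = recommend(cat, rules=rules, k=20)
        assert rec.crops  # non-empty despite no branch matching
        assert "Rice" in rec.crops

    def test_totality_over_all_288_combinations(self):
        count = 0
        for cat in all_combinations():
            rec = recommend(cat, k=25)
            assert rec.crops, cat
            assert len(rec.crops) == len(set(rec.crops))
            count += 1
        assert count == 288

    def test_determinism(self):
        cat = make_cat(temp_band="hot", humidity_level="high", wind_level="high")
        a = recommend(cat, k=8)
        b = recommend(cat, k=8)
        assert a.ranked_crops == b.ranked_crops

    def test_restriction_soundness_under_high_wind(self):
        # equal base votes: a wind-resistant crop must not be outranked by a
        # penalized one
        for cat in all_combinations():
            if cat.wind_level != "high":
                continue
            rec = recommend(cat, k=25)
            scores = dict(rec.ranked_crops)
            resistant = {"Millets", "Ragi", "Sugarcane", "Groundnut"}
            base = _brute_force_votes(cat)
            for crop, score in scores.items():
                if crop in resistant:
                    continue
                for rcrop in resistant & set(scores):
                    if base.get(rcrop, 0) == base.get(crop, 0):
                        assert scores[rcrop] >= score

    def test_score_conservation_against_brute_force(self):
        # re-tally every combination independently of the engine
        for cat in all_combinations():
            rec = recommend(cat, k=25)
            expected = _apply_penalties(cat, _brute_force_votes(cat))
            assert dict(rec.ranked_crops) == pytest.approx(expected)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            recommend(make_cat(), k=0)

    def test_ties_break_by_canonical_order(self):
        rec = recommend(make_cat(), k=20)
        scores = dict(rec.ranked_crops)
        for (c1, s1), (c2, s2) in zip(rec.ranked_crops, rec.ranked_crops[1:]):
            if s1 == s2:
                assert CROP_CANON.index(c1) < CROP_CANON.index(c2)
        assert scores


def _brute_force_votes(cat):
    """Independent re-statement of the additive branches as literal ifs."""
    votes = {}

    def add(crops):
        for c in crops:
            votes[c] = votes.get(c, 0) + 1

    if cat.temp_band == "hot" and cat.humidity_level == "low":
        add(["Groundnut", "Sunflower", "Millets", "Cotton"])
    if cat.temp_band == "hot" and cat.humidity_level == "high":
        add(["Rice", "Sugarcane"])
    if cat.temp_band == "moderate":
        add(["Rice", "Ragi", "Maize", "Pigeon pea", "Chickpea", "Tomato",
             "Brinjal", "Okra", "Mango", "Banana", "Guava"])
        if cat.terrain == "hilly":
            add(["Coffee", "Tea"])
    if cat.precip_level == "high":
        add(["Rice", "Sugarcane"])
    if cat.precip_level == "low":
        add(["Millets", "Groundnut", "Sunflower"])
    if cat.soil_level == "high":
        add(["Rice", "Sugarcane", "Mango", "Guava", "Banana"])
    if cat.soil_level == "low":
        add(["Millets", "Groundnut", "Sunflower"])
    return votes


def _apply_penalties(cat, votes):
    scores = {c: float(v) for c, v in votes.items()}
    if cat.wind_level == "high":
        for c in scores:
            if c not in {"Millets", "Ragi", "Sugarcane", "Groundnut"}:
                scores[c] *= 0.5
    if cat.uv_level == "high":
        for c in scores:
            if c not in {"Millets", "Groundnut", "Sunflower", "Cotton", "Sugarcane"}:
                scores[c] *= 0.5
    return scores


class TestComposition:
    def test_raw_attrs_equal_categorized_path(self):
        attrs = GeoAttributes(
            temperature_c=32, humidity_pct=35, wind_kmh=5,
            precip_mm_day=2, uv_index=3, soil_moisture_vwc=0.1,
        )
        direct = recommend_for_location(attrs, k=6)
        via_cat = recommend(
            make_cat(temp_band="hot", humidity_level="low"), k=6
        )
        assert direct.ranked_crops == via_cat.ranked_crops

    def test_district_fixture_high_soil_location_ranks_rice_first(self):
        from importlib import resources

        from fertiscan.geoattrs import load_attributes

        with resources.as_file(
            resources.files("fertiscan.data").joinpath(
                "district_attributes_synthetic.csv"
            )
        ) as p:
            records = load_attributes(p)
        thrissur = next(
            r for r in records if r.location_name.startswith("Thrissur")
        )
        assert thrissur.soil_moisture_vwc >= ThresholdConfig().soil_high_vwc
        rec = recommend_for_location(thrissur, k=5)
        assert rec.crops[0] == "Rice"


class TestYamlRoundtrip:
    def test_rules_survive_serialization(self, tmp_path):
        p = tmp_path / "rules.yaml"
        rules = builtin_rulebase()
        rules_to_yaml(rules, p)
        back = rules_from_yaml(p)
        assert back == rules

    def test_empty_rule_file_rejected(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("[]\n")
        with pytest.raises(ValueError):
            rules_from_yaml(p)
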