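# fertiscan

Identify cultivable land in satellite-style imagery and rank the crops that
suit it. `fertiscan` is a deterministic, fully offline toolkit for a
workflow common in agricultural remote sensing:

1. **Pan-sharpening** — fuse a low-resolution RGB (multispectral, MS) image
   with a high-resolution single-band panchromatic (PAN) image;
2. **Green-area segmentation** — find vegetation by hue-window thresholding
   in HSV space and convert the masked pixel count into acreage using the
   image's ground scale;
3. **Crop suitability** — a rule engine ranks crops from a location's
   environmental attributes (temperature, humidity, wind, precipitation,
   UV index, soil moisture, terrain);
4. **Evaluation** — score ranked predictions against a district-level
   dominant-crop reference with a confusion matrix and a per-class
   precision/recall/F1 report.

It is aimed at people prototyping land-suitability pipelines who need every
stage to be reproducible and testable without live imagery or weather APIs:
a seeded scene generator provides satellite-like images with exact
green-pixel ground truth, and an attribute generator covers every branch of
the rule engine.

## The core methods

**Brovey transform.** Each fused band modulates the MS band by the PAN
intensity over the band sum:

$$Y_k = \frac{X_k \, X_p}{X_R + X_G + X_B}, \qquad k \in \{R, G, B\}$$

so band *ratios* (hue) are preserved while spatial detail comes from the PAN
band; the band sum of the output equals $X_p$ wherever the denominator is
nonzero. An $\varepsilon$-guard (default $10^{-6}$) handles black pixels.

**High-pass-filter fusion.** With $M$ the grayscale MS image, $P$ the
resampled PAN band and $F$ a zero-sum high-pass kernel (3×3 Laplacian or
difference of Gaussians):

$$\text{sharpened} = \operatorname{clip}\left(M + \lambda\, F(P)\right)$$

**Green masking.** RGB is converted to HSV ($V=\max$, $S=(\max-\min)/\max$,
$H$ by the standard max-branch formulas); a pixel is vegetation iff
$H \in [h_{lo}, h_{hi}]$ (default $[70°, 170°]$), $S \ge 0.15$ and
$V \ge 0.10$. The area is

$$\text{acres} = n_{\text{green}} \cdot \frac{g^2}{4046.8564224}$$

with $g$ the ground distance per pixel in metres. A map-scale helper
converts the *126 yards per screen centimetre* viewing convention at 96 dpi
into $g = 126 \times 0.9144 / 37.795 \approx 3.048$ m/px.

**Rule engine.** Each branch of the decision procedure (hot & dry → 
Groundnut, Sunflower, Millets, Cotton; hot & humid → Rice, Sugarcane;
moderate 20–30 °C → a broad list plus Coffee/Tea on hilly terrain; wet or
moist soil → Rice, Sugarcane, fruits; dry → drought-resistant crops) adds a
vote to its crops; high wind and high UV act as restrictions that halve the
score of non-tolerant crops. Ties break by a fixed canonical crop order, so
the ranking is deterministic.

**Evaluation.** Top-1 predictions against dominant crops give a confusion
matrix; per class, precision $= TP/(TP+FP)$, recall $= TP/(TP+FN)$,
$F_1 = 2PR/(P+R)$, with $0/0 := 0$. A separate top-*k* hit rate counts
records whose dominant crop appears lower in the ranking.

## Worked example

```bash
# render a 256x256 synthetic scene with known vegetation ground truth
fertiscan simulate scene --out-dir scene --seed 42
# -> INFO fertiscan: scene written to scene (4754 green px)

# measure its green area at the default map scale
fertiscan greenarea --image scene/hires.png
```

```json
{
  "green_area": {
    "area_acres": 10.916570067813993,
    "area_m2": 44177.79168951266,
    "green_fraction": 0.072540283203125,
    "green_pixels": 4754,
    "total_pixels": 65536
  },
  "ground_m_per_px": 3.0484032279402036,
  "schema_version": 1
}
```

The mask found exactly the 4 754 vegetation pixels the generator painted
(`scene/truth.json`); at ≈3.05 m/px those cover ≈10.9 acres.

```bash
# rank crops for a hot, dry, low-rain location
cat > loc.json <<'EOF'
[{"location_name": "Demo district", "temperature_c": 32, "humidity_pct": 35,
  "wind_kmh": 8, "precip_mm_day": 2, "uv_index": 4, "soil_moisture_vwc": 0.12}]
EOF
fertiscan recommend --attrs loc.json --top-k 4
```

```json
"ranked_crops": [
  {"crop": "Groundnut", "score": 3.0},
  {"crop": "Sunflower", "score": 3.0},
  {"crop": "Millets", "score": 3.0},
  {"crop": "Cotton", "score": 1.0}
]
```

Groundnut, Sunflower and Millets each collected votes from the heat, low
rainfall and dry soil stages (see `provenance` in the full output); Cotton
only from the heat stage.

Other subcommands: `fertiscan sharpen` (Brovey or HPF fusion),
`fertiscan evaluate` (score a prediction CSV/JSON), `fertiscan run`
(end-to-end with a YAML config), `fertiscan export-rules` (dump the
rulebase as editable YAML).

## Attribute file schema

CSV or JSON array with columns `temperature_c`, `humidity_pct` (0–100),
`wind_kmh`, `precip_mm_day`, `uv_index` (≥ 0), `soil_moisture_vwc` (0–1),
and optional `terrain` (`plain`/`hilly`) and `location_name`. Category
cut-points can be overridden with `--thresholds thresholds.yaml`.

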