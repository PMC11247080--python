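# Methods

This note records the models implemented in `fertiscan`, the parameters
that matter, the numerical conventions, and what the synthetic-data tests
do and do not demonstrate.

## Raster model and resampling

All imagery is held as float64 intensities in [0, 1], row-major, origin
top-left. 8/16-bit PNG/TIFF files are divided by their dtype maximum on
read and rounded back on write, so a write/read round-trip is exact to half
a quantization step (1/510 for 8-bit).

Resampling uses pixel-centre coordinate mapping — output pixel *i* samples
source coordinate (i + 0.5)·n_in/n_out − 0.5 — with border replication.
Three methods are provided: nearest neighbour, bilinear, and cubic
convolution with the Keys kernel (a = −0.5). Cubic convolution is
implemented in-package because the SciPy/scikit-image `order=3` resamplers
are B-spline interpolants, a different cubic. The interpolation sum is
accumulated as `nearest_tap + Σ w·(tap − nearest_tap)`; since the weights
sum to one this is algebraically the plain weighted sum, but it makes
constant images reproduce bit-exactly under every method — an invariant the
test suite relies on. Interpolated values are clipped to [0, 1] (cubic
overshoots near edges).

Grayscale conversion uses the ITU-R BT.601 luma weights
0.299/0.587/0.114 — the conventional "human-eye" weighting; any convex
weighting would preserve the [0, 1] range.

## Pan-sharpening

Two fusions of a high-resolution panchromatic band P with a lower-resolution
RGB image:

* **HPF fusion**: `clip(M + λ·F(P))`, with M the grayscale multispectral
  image resampled to P's grid and F a zero-DC high-pass filter. Kernels:
  the 3×3 Laplacian `[[0,−1,0],[−1,4,−1],[0,−1,0]]` (default) or a
  difference of Gaussians with σ = (1.0, 2.0). λ defaults to 1.0.
  Convolution uses reflect padding, so a constant P contributes nothing and
  the interior response to a linear ramp is zero.
* **Brovey transform**: `Y_k = X_k·X_p / max(ΣX_j, ε)` over the three
  bands, ε = 1e−6 guarding all-black pixels. Two exact identities are
  enforced by tests: band-sum conservation (Σ_k Y_k = X_p wherever
  Σ X_j > ε, before clipping) and 1-homogeneity in the pan band. Outputs
  are clipped to [0, 1]; clipping is the package's choice — overflow
  handling is not standardized across implementations.

An optional HSV route (off by default) converts the upsampled RGB to HSV,
replaces the value channel with the grayscale of the Brovey output, and
converts back. It is one concrete reading of "sharpen via HSV" and is
exposed as a flag rather than a default because the operation has no single
established definition.

## Green-area segmentation

RGB→HSV uses the standard max/min branch formulas (via scikit-image), hue
in degrees. Achromatic pixels (max = min) take H = 0; S = 0 where V = 0.
A pixel is vegetation iff H ∈ [hue_lo, hue_hi] ∧ S ≥ sat_min ∧ V ≥ val_min.
Defaults: [70°, 170°], 0.15, 0.10. The hue window is a closed interval with
no wrap-around (green hues never straddle 0°). The saturation floor rejects
gray roofs and concrete; the value floor rejects dark asphalt and shadow.
No published threshold values exist for this workflow, so all four are
explicit configuration. No morphological clean-up is applied by default; a
`--min-blob-px` speckle filter is available but defaults to 0, keeping the
base method pure thresholding.

Acreage: `acres = n_green · g² / 4046.8564224` with g in m/px. The map-scale
helper converts a screen-map viewing scale (default 126 yards per
centimetre at 96 dpi, i.e. 37.795 px/cm) to g ≈ 3.048 m/px; the screen
density behind such viewing scales is not standardized, so it is a
parameter, not a constant.

## Attribute categorization

Measurements map to the levels the rule engine branches on. Fixed by the
modelled procedure: temperature strictly above 30 °C is *hot*; the closed
band [20, 30] °C is *moderate* (so exactly 30 °C is moderate); below 20 °C
is *cool*. The remaining cut-points are package defaults, configurable via
YAML: humidity ≤ 40 % low / ≥ 70 % high; wind ≥ 20 km/h high;
precipitation ≥ 10 mm/day high; UV index ≥ 6 high (WHO convention); soil
moisture ≥ 0.30 VWC high. Binary dimensions treat the threshold itself as
high. Categorization is total and monotone in temperature.

## Rule engine

The decision narrative is transcribed into ten rules. Eight are *additive*
(temperature×humidity branches, hilly-terrain Coffee/Tea, precipitation
high/low, soil moisture high/low): each fired rule adds its weight
(default 1) to each of its crops. Two are *restrictive* (high wind, high
UV): they multiply the score of every crop outside their tolerant set by
0.5 instead of voting. The narrative gives no combination scheme; additive
voting with a multiplicative penalty was chosen because it reproduces each
branch's qualitative outcome, composes across stages, and is trivially
auditable (a crop's score is the sum of its fired weights times applied
penalties — a property the tests re-tally by brute force). Ties break by a
canonical crop order (order of first appearance in the narrative), making
rankings fully deterministic.

The wind-resistant set {Millets, Ragi, Sugarcane, Groundnut} and
UV-tolerant set {Millets, Groundnut, Sunflower, Cotton, Sugarcane} are
editorial defaults — the narrative names the properties, not the members —
and ship in the YAML-serializable rulebase so users can edit them. The
cool band (< 20 °C) has no rules; if no additive rule fires the engine
returns the moderate-band list with a logged warning rather than an empty
ranking. An LLM could in principle replace the engine (the original
procedure was attributed to one); here the rule engine is the reference
backend and no language model is called.

## Evaluation

Top-1 semantics: a record matches iff the rank-1 prediction equals the
dominant crop. The confusion matrix is built over the union of observed
labels in canonical order. Per class: precision TP/(TP+FP), recall
TP/(TP+FN), F1 = 2PR/(P+R), support = TP+FN, with every 0/0 defined as
0.0 — this convention is required to reproduce the all-zero rows of the
reference report. The F1 uses the standard factor-2 form; the
factor-free form sometimes seen in print is inconsistent with its own
worked values (P = R = 0.80 must give F1 = 0.80, not 0.40). Accuracy is the
diagonal sum over the total and provably equals the mean of per-record
top-1 matches (both paths are computed and compared in tests). A top-k hit
rate is reported separately and never mixed into accuracy. Macro and micro
averages are computed for completeness.

The packaged 20-district reference table yields 15/20 = 75 % top-1
accuracy. Two cells of the published per-class report are *not* derivable
from that table: Rice (table gives precision 6/9 ≈ 0.667 and recall
6/8 = 0.75) and Wheat precision (table gives 4/6 ≈ 0.667). The package
reports the table-derived values; the discrepancy is an inconsistency in
the source material, not in the computation.

## Synthetic scenes

`generate_scene` paints a tan soil background with slight mottling, gray
rectangular buildings (zero saturation, value 0.45–0.75), dark asphalt
polylines (value ≈ 0.05, below the mask's value floor), and elliptical
vegetation patches painted last with hue ∈ [80°, 150°], S ∈ [0.5, 0.9],
V ∈ [0.4, 0.8] — a ≥ 10° hue margin inside the default window. The exact
vegetation pixel set is recorded as ground truth before optional Gaussian
noise is added and the result clipped. The panchromatic band is the
grayscale of the high-resolution scene; the low-resolution multispectral
image is a σ = 1.5 Gaussian blur followed by factor-4 decimation — enough
degradation that fusion has visible work to do. All randomness flows from
one `numpy` generator seeded per call; no global state.

Default study conditions used by tests and the acceptance script: 256×256
scenes, 4 vegetation patches, 5 buildings, 2 roads, noise σ ∈ {0, 0.02},
20 seeds; 50 random 16×16 images for the algebraic fusion identities. These
sizes make the entire suite run in seconds while leaving every invariant
non-trivial.

What passing these tests shows: the segmentation and area arithmetic are
exact under the generator's idealized rendering, and degrade < 2 % under
moderate sensor-like noise. What it does not show: performance on real
imagery, where vegetation hue varies with season and species, shadows and
water confound the value floor, and mixed pixels blur patch boundaries.
The generator also renders no clouds, no atmospheric haze, and no
georeferencing; distinguishing farmland from parks or backyards is out of
scope.

## Known limitations

* Hue windows cannot wrap around 0°, so the tool cannot target red-ish
  ranges without modification.
* The rule engine's non-fixed cut-points and tolerance sets are editorial;
  conclusions drawn from them should treat them as priors, not facts.
* Only 1- and 3-band rasters are supported; no CRS/georeferencing, no
  NDVI or other multispectral indices (visible-band hue only).
* The evaluation fixtures are a 20-record set; no significance testing or
  cross-validation is meaningful at that size and none is offered.
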