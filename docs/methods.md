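# Methods

This note documents the models, conventions and numerical choices behind
woundkit, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Preprocessing and skin segmentation

Min–max normalization rescales intensities to [0, 1] globally over all
three channels, not per channel: per-channel rescaling would shift hue,
and hue is the signal every later stage depends on. A constant image maps
to all-zeros instead of raising, so pipelines running on degenerate crops
do not abort.

Segmentation thresholds two chroma planes in which skin sits at the
red-shifted (high) end: CIELAB a\* (sRGB companding, D65 white point, via
scikit-image) and YCbCr Cr in the full-range BT.601 convention, computed
in closed form as Cr = 128 + 0.5 R − 0.418688 G − 0.081312 B on the 8-bit
scale. Each plane is binarized with Otsu's threshold; "skin = high side"
is the default polarity and can be flipped for unusual backgrounds. The
two masks are merged by logical OR: each single-channel mask has false
negatives the other recovers, so union trades a few extra background
pixels for far fewer holes in the skin region. A median filter (default
5 × 5; any odd size ≥ 3) removes isolated speckle while preserving large
components. The merged-mask ⊇ single-channel-mask property and the
behavior of Otsu's threshold under brightness shifts are covered by tests.

## Detection contract and evaluation

Boxes are 0-based and half-open, [x_min, x_max) × [y_min, y_max), so area
is width × height with no ±1 bookkeeping. Matching is greedy in descending
confidence (stable for ties): each detection claims the unmatched ground
truth of highest IoU provided it reaches the threshold; each ground truth
matches at most once. Average precision is the area under the all-points
interpolated precision–recall curve; mAP averages AP over the 10 IoU
thresholds 0.50, 0.55, …, 0.95; F1 uses all detections with no confidence
cut, at IoU 0.5 by default. These are the COCO conventions; they are
verified against brute-force oracle implementations in the tests.

Mask filtering keeps a detection only if at least `min_skin_fraction`
(default 0.5) of the pixels in its clipped box are skin. Because the
calibration marker is a known non-skin object that reads as a strong
chromatic anomaly, the end-to-end pipeline detects the marker *before*
wound detection and blanks its rectangle (padded by 15% of the marker
side) out of the mask; without this, the marker would be the
highest-confidence false positive in nearly every frame.

The reference detector estimates per-channel CIELAB medians and MADs over
the skin mask, scores each pixel by its largest robust z-score across L\*,
a\*, b\* (MAD scaled by 1.4826 and floored at 1 to avoid blowups on very
uniform skin), thresholds at z > 4, closes small gaps morphologically, and
reports connected components of ≥ 40 px as boxes. Confidence is
1 − exp(−z̄ / 8), a saturating transform of the component's mean score. By
default candidates are restricted to the (eroded) skin mask; with
`restrict_to_mask=False` the detector sees the whole frame, which is the
configuration used to demonstrate the value of mask filtering. It applies
no non-maximum suppression across boxes (nested detections, e.g. an open
wound inside a larger wound area, are reported as-is).

## Handcrafted features

The 441-value descriptor concatenates six segments in fixed order; a
layout table maps segment names to index ranges and a config hash ties
feature files to the extraction configuration.

* **CIELAB distributions (60).** Per channel: mean, SD, skewness, excess
  kurtosis, and a 16-bin histogram over the channel's nominal range (L\*
  [0, 100]; a\*, b\* [−128, 128]). Exactly-black pixels are excluded —
  they are masked background, and including them would make the color
  moments depend on how much background a crop retains. Texture operators,
  by contrast, run on the full rectangular crop. Zero-variance channels
  get skewness = kurtosis = 0, and an SD below 1e−9 (color-conversion
  rounding) is snapped to 0.
* **GLCM (12 + 30).** 32 gray levels on the L\* plane (fixed [0, 100]
  range so quantization is comparable across crops), distances {1, 2},
  angles {0°, 45°, 90°, 135°}, symmetric and normalized. Distances count
  steps along the angle's pixel direction, so distance 2 at 45° pairs
  pixels offset by (2, 2) — the co-occurrence library's rounded-offset
  convention would collapse diagonal distance 2 onto distance 1.
  Properties: contrast, correlation, energy, homogeneity, entropy
  (Shannon, bits), dissimilarity, averaged over angles per distance. The
  tile-wise variant computes one scalar per property per non-overlapping
  64 × 64 tile (partial tiles discarded) and summarizes each property by
  mean/SD/min/max/median over tiles.
* **LBP (59).** 8 neighbors of the 3 × 3 square, circular order starting
  east; bit set when the neighbor is *strictly greater* than the center,
  so flat regions produce the all-zeros pattern (with the common ≥
  convention a constant crop lands in the all-ones bin instead — either
  is self-consistent; the strict form makes the flat-region bin the
  natural zero). Uniform patterns (≤ 2 circular transitions; 58 of them)
  get bins in ascending code order, all non-uniform codes share bin 59.
* **LPQ (256).** Windowed STFT over a 7 × 7 Gaussian window (σ = 7/6) at
  the four lowest non-zero frequencies (a, 0), (0, a), (a, a), (a, −a)
  with a = 1/7; the 8-bit code packs the signs of the four real and four
  imaginary parts. No decorrelation step. Histograms are near
  shift-invariant away from borders (tested).
* **Gabor (24).** 4 orientations × 3 wavelengths {4, 8, 16 px},
  σ = 0.56 λ, kernels DC-removed so constant crops give zero response;
  mean and variance of response magnitude per filter. Orientation is the
  wave-vector angle: the 90° filter responds maximally to horizontal
  stripes. Convolution is FFT-based with reflect padding.

Crops smaller than 64 px on a side are bilinearly upscaled so the
tile-based features are defined; erroring instead was rejected because
real wound crops are frequently small. Extraction is deterministic.

## Classification

Each condition (infection, ischemia) gets an independent binary pipeline:
StandardScaler → PCA → estimator. The PCA component count is selected by
stratified 5-fold cross-validation over {32, 64, 128, 256} (capped by data
size; ties prefer fewer components); 128 is the default when the search is
skipped. The default estimator is an RBF-kernel SVM with Platt-scaled
probabilities; gradient boosting (100 trees, depth 3) and an MLP with
three hidden layers (128, 64, 32) sit behind the same interface — a single
gradient-boosting implementation covers the gradient-boosted-tree family.
All randomness (folds, Platt calibration, MLP init) derives from one seed.

Minority upsampling replicates each minority-class image `factor` times
(original + factor − 1 augmented copies: rotation ±25°, flips, brightness
×[0.8, 1.2], seeded), the policy used for rare ischemia positives. It must
be applied to training data only; validation metrics on upsampled folds
would be optimistically biased.

The four-way combiner multiplies the two marginals under an independence
assumption; the four products always sum to
(p + (1−p))(q + (1−q)) = 1. The predicted class is the argmax (first
maximum in the order none, infection-only, ischemia-only, both). Hard
binary labels use threshold 0.5 with p = 0.5 classified positive. AUC is
the trapezoidal ROC area (equivalently the all-pairs concordance, the
form the tests check against); it is reported as undefined, without
failing the other metrics, when only one class is present.

## Characterization

* **Sizing.** The fiducial is a 6 × 6-cell square marker (1-cell black
  border, 4 × 4 payload) from a 50-pattern dictionary generated once from
  a fixed constant seed with rejection rules: no near rotation-symmetric
  payloads, and ≥ 4 bits Hamming distance to every rotation of every
  accepted code, so decoding is unambiguous under the four square
  rotations. Detection thresholds dark regions (Otsu), fills holes, keeps
  roughly square components, estimates the corner quadrilateral from
  diagonal extremes of the filled component (pushed outward half a pixel
  so corners sit on pixel edges — an axis-aligned marker spanning columns
  c0..c1 has side c1 − c0 + 1), samples the cell grid through a projective
  transform, requires an all-black border and matches the payload under
  all rotations. The side length is the mean of the four quadrilateral
  sides; the largest decoded marker wins if several are visible. cm/px =
  physical side (default 1.3 cm) / pixel side. No perspective correction
  is applied: the capture protocol holds the camera parallel to the wound
  plane, and side-averaging absorbs small tilt; strongly oblique views are
  out of scope. Sizes are reported at 0.1 cm precision with full precision
  retained in the raw fields.
* **Colors.** k-means with k = 7, k-means++ init, 10 restarts, fixed
  seed, on CIELAB coordinates — distances in CIELAB track perceptual color
  difference, which RGB distances do not. The output always has exactly 7
  entries (empty clusters at 0%) sorted by descending share, so consumers
  get a fixed schema; centers are reported as sRGB hex and CIELAB. The
  percentage drift from float accumulation is pinned onto the largest
  entry so shares sum to exactly 100.
* **Roughness.** The height map is the Gaussian-smoothed (σ = 2 px
  default) L\* plane; Ra = mean |h − h̄| and Rq = √(mean (h − h̄)²) over
  in-mask pixels. Rq ≥ Ra always (RMS dominates the mean absolute
  deviation); both are 0 on constant crops and grow monotonically with
  additive noise amplitude. Ra/Rq of a smoothed lightness surface is a
  declared operationalization of "surface roughness" from a single 2-D
  photo — it measures shading texture, not true 3-D relief.

## Synthetic scenes

Each scene is a teal-green drape background (surgical-drape colored, with
a\* and Cr both well below skin, so the chroma polarity assumption holds
by construction), an elliptical skin region (semi-axes 0.36/0.32 of the
frame) with low-frequency Gaussian-filtered luminance mottling (SD 6 8-bit
units), an elliptical wound whose pixels draw independently from a
red/yellow/dark/pink tissue palette with per-pixel jitter (SD 8), an
optional marker with a white quiet zone rendered at a known pixel scale,
and additive Gaussian sensor noise (SD 4). Default frame 288 × 288 px at
0.026 cm/px with a 50 px marker. Skin bases span six light-to-dark tones.
Scenes are flagged infected when the yellow fraction exceeds 0.25 and
ischemic when the dark fraction exceeds 0.25 — generator constants chosen
so labels are recoverable from color statistics by construction, not
claims about wound biology. Randomized scenes sample the dominant fraction
in [0.35, 0.6] (or [0.30, 0.45] each when both conditions hold) against a
[0, 0.12] background rate, so flags are unambiguous. Optional distractors
are dark shadowed objects on the drape: chromatically non-skin (excluded
by the mask) but strongly anomalous to a detector that ignores the mask —
the configuration that demonstrates mask filtering.

What passing tests on these scenes shows — and does not. The scenes
exercise the geometry and color logic of every stage with exact ground
truth, but they are not photorealistic: no specular highlights, shadows,
perspective, motion blur, camera color profiles, hair, toenails,
dressings, or gradual wound boundaries. Segmentation Dice ≥ 0.90 and
near-perfect detection/classification here validate the machinery, not
clinical performance; the sustained gap between synthetic and clinical
difficulty is exactly why the detector interface accepts externally
trained models.

Test-suite problem sizes (200 scenes for segmentation, 100 for the
filtering comparison, 400/200 for classification, 500 random instances
for metric oracles) are the suite's own scale choices, large enough for
the aggregate statistics to be stable under the fixed seeds.

## Known limitations

* The reference detector is a testing device; it assumes wounds are
  chromatic outliers on otherwise homogeneous skin and will fail on
  heavily textured or lesion-dense skin.
* Marker detection assumes a roughly frontal marker and decodes a single
  dictionary; heavy blur, occlusion or strong perspective defeat it.
* Roughness from a single 2-D image conflates illumination texture with
  relief.
* The four-way combiner's independence assumption ignores any correlation
  between infection and ischemia given the image.
* Classification probabilities are Platt-calibrated on the training set;
  on shifted populations the 0.5 threshold is not guaranteed to be the
  accuracy-optimal operating point.
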