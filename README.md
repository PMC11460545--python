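# woundkit

A toolkit for analyzing photographs of chronic wounds — built around the
needs of diabetic foot ulcer (DFU) monitoring, where early detection of
infection and ischemia drives outcomes but assessment is usually invasive,
slow and restricted to specialist clinics. woundkit implements the
image-analysis core of a phone-photo wound pipeline: everything between a
raw RGB photograph and a structured report of where the wound is, how
likely it is to be infected or ischemic, how big it is in centimeters, and
what its color and texture look like.

It is aimed at researchers prototyping wound-analysis pipelines. The wound
*detector* is deliberately pluggable — any callable producing scored boxes
(e.g. an external YOLO runtime) drops in; the built-in reference detector
is a simple chromatic-anomaly proposer used for testing the surrounding
machinery, not for clinical use.

## What it computes

**Skin segmentation.** Skin pixels cluster at the red-shifted end of two
chroma axes: a\* in CIELAB and Cr in YCbCr. Each plane is binarized with
Otsu's threshold, the masks are merged by logical OR (each channel misses
regions the other recovers), and a median filter removes speckle. Images
are first min–max normalized, x' = (x − min) / (max − min), jointly over
channels to preserve hue.

**Detection evaluation and filtering.** IoU, greedy confidence-ordered
matching, all-points-interpolated average precision, mAP over IoU
thresholds 0.50:0.05:0.95, and F1; plus false-positive suppression that
drops any detection whose box covers less than a threshold fraction of
skin mask.

**Infection/ischemia classification.** A 441-dimensional handcrafted
descriptor per wound crop (CIELAB channel distributions; full-crop GLCM
statistics; tile-wise GLCM distributions; uniform LBP and LPQ histograms; Gabor-bank
response energies), fed to a standardize → PCA → RBF-SVM pipeline (PC count
chosen by stratified 5-fold CV; gradient boosting with 100 depth-3 trees
and a 3-hidden-layer MLP are available behind the same interface). Rare
positive classes can be rebalanced by seeded minority upsampling with
random augmentations (training folds only). Two binary probabilities are
combined under independence into a four-way posterior:

    P(none)      = (1 − P(inf)) (1 − P(isch))
    P(inf only)  =      P(inf)  (1 − P(isch))
    P(isch only) = (1 − P(inf))      P(isch)
    P(both)      =      P(inf)       P(isch)

which sums to 1 by construction; hard labels use a 0.5 threshold with ties
positive.

**Wound characterization.** A 1.3 cm square fiducial marker in frame gives
a cm/px ratio (marker dictionary, rendering and decoding are built in);
the wound box times the ratio gives width/height in cm. k-means (k = 7) on
CIELAB pixels reports the dominant-color composition in percent. Surface
roughness treats the Gaussian-smoothed L\* plane as a height map and
reports Ra (mean absolute deviation) and Rq (RMS deviation).

**Synthetic scenes.** A deterministic generator renders labeled wound
photographs — drape background, mottled elliptical skin region, a wound
ellipse whose red/yellow/dark/pink tissue mixture encodes the
infection/ischemia labels, optional marker at known scale, Gaussian noise —
with full ground truth (skin mask, wound box, labels, physical sizes).
All tests run against these scenes.

## Worked example

```bash
python examples/measure_and_characterize.py
```

prints

```
marker: 50.0 px side -> 0.260 mm/px (generator truth 0.260 mm/px)
wound size: 1.3 x 1.0 cm (truth 1.27 x 0.96 cm)
color composition (top 4):
  #c6866a   49.6%
  #c9b348   11.5%
  #cda54d   11.1%
  #ac281f   10.4%
roughness: Ra=2.65, Rq=3.26 (L* units)
```

The detected marker calibrates pixels to metric exactly (0.260 mm/px is
the generator's truth), the wound size lands within the 0.1 cm reporting
precision, the composition shows skin tone plus the yellow slough tones
that encode this scene's infected label, and Rq ≥ Ra as it must be.
`examples/segment_and_detect.py` and `examples/classify_fourway.py` walk
the segmentation/detection and classification stages the same way.

The same stages are available as a CLI:

```bash
woundkit simulate --n 10 --out scenes/ --seed 17
woundkit analyze scenes/scene_0000.png --out report.json
woundkit segment IN.png --out-mask MASK.png --out-fg FG.png
woundkit measure IN.png --box 120,126,169,163 --out size.json
```

`analyze` runs the full flow (segment → detect → filter → per-wound
classification, sizing, colors, roughness) and writes a JSON report that
validates against `src/woundkit/report_schema.json`; identical inputs and
seeds give byte-identical reports.

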