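# cellseg-bench

A benchmarking toolkit for **label-free cell instance segmentation**. It
implements the evaluation suite used for large phase-contrast microscopy
benchmarks of cultured cells: COCO-style mask average precision adapted to
cell sizes, a detection-focused false-negative metric, a cross-cell-type
transferability index, validation of model object counts against
fluorescence-based nuclei counts, and morphology-PCA dataset profiling.
A seeded synthetic-scene and count-series generator makes every metric
testable without any curated imaging dataset.

## Who this is for

Researchers developing or comparing instance-segmentation models for 2D cell
culture images (phase contrast or similar label-free modalities), where images
routinely contain hundreds to thousands of overlapping, oddly shaped objects
and standard object-detection defaults (size categories, per-image detection
caps) do not fit the biology.

## The metrics

**Segmentation quality.** A prediction and a ground-truth mask are compared by
intersection over union on their rasterized pixel sets,
IoU = |Pred ∩ Target| / |Pred ∪ Target|. At each IoU threshold
t ∈ {0.50, 0.55, …, 0.95} predictions are matched greedily in descending score
order; precision p = TP/(TP+FP) and recall r = TP/(TP+FN) accumulate along the
score-ranked list, precision is interpolated to be monotonically decreasing,
p_interp(r) = max_{r′≥r} p(r′), and

    AP_t = Σ_i (r_{i+1} − r_i) · p_interp(r_{i+1}),      AP = mean_t AP_t.

**Detection completeness.** FNR_t = 1 − Recall_t, and AFNR = mean_t FNR_t.
AP asks "are the detected masks right?"; AFNR asks "how many cells were
missed?".

Size-stratified AP/AFNR uses cell-appropriate pixel-area bands (small < 500 px
≈ 320 µm², medium 500–1,500 px, large > 1,500 px ≈ 970 µm²) and a per-image
detection cap of 3,000 (dense cultures far exceed the usual cap of 100).

**Transferability.** Given an AP grid over cell types (models trained on one
type, evaluated on all), the transfer ratio is r_{A,B} = log₂(AP_B / AP_A) and

    transferability index = −(1/(n(n−1))) Σ_{c1≠c2} r_{c1,c2}.

0 means a model performs as well on unseen cell types as on its own; larger
is worse.

**Count linearity.** Model counts are validated against fluorescence-nuclei
counts by R² = 1 − SS_residual/SS_total with SS_residual = Σᵢ(y_fluor,i −
y_model,i)² (direct residuals, not a fitted line), and by an iterative
goodness-of-fit test: for increasing maximum fluorescence-count candidates, an
OLS line and a 5-nearest-neighbor regression are fitted (fluorescence count on
model count) and their residual variances compared with Levene's test; the
iteration stops at the first p < 10⁻⁵ and reports how far the linear
relationship extends.

**Morphology profiling.** 17 per-cell metrics (size, intensity, intensity
distribution, texture, shape), image-wise averaging, standard scaling, and a
two-component PCA for score/loading plots of dataset diversity.

## Worked example

Simulate ten dense scenes, degrade them into imperfect "predictions"
(10% missed cells, 5% spurious detections, mean mask IoU ≈ 0.8), and evaluate:

```python
from cellseg_bench import (SceneConfig, DegradationConfig,
                           generate_scenes, degrade, write_annotations)

gt, _ = generate_scenes(SceneConfig(seed=7, n_images=10, instances_per_image=30,
                                    width_px=256, height_px=256,
                                    median_area_px=450, area_sigma=0.8))
write_annotations(gt, "gt.json")
preds = degrade(gt, DegradationConfig(seed=8, false_negative_rate=0.1,
                                      false_positive_rate=0.05, target_iou=0.8))
write_annotations(preds, "pred.json")
```

```console
$ cellseg-bench evaluate --gt gt.json --pred pred.json --out report.json
AP 58.0%  AFNR 40.2%
```

The overall AP of 58.0% averages the ten per-threshold APs (AP_0.50 = 91.7%
here, falling as the threshold approaches 0.95 because perturbed masks stop
clearing stricter overlap requirements), and the AFNR of 40.2% reflects both
the 10% of cells that were never predicted and matches lost at high
thresholds. `report.json` carries the full per-threshold and per-size-band
breakdown (for this run: small 57.7%, medium 58.2%, large 60.3% AP).

```console
$ cellseg-bench transfer --matrix ap.csv --out transfer.json
transferability index 1.21
```

where `ap.csv` is a train-type × eval-type AP table; an index of 1.21 means
cross-type AP is on average 2^1.21 ≈ 2.3-fold lower than same-type AP.

```console
$ cellseg-bench simulate counts --seed 9 --out sim
$ cellseg-bench counts --table sim/counts.csv --out linearity.json
R2 99.8%  breakpoint 1768
```

The simulated series is linear up to 1,500 objects per image and saturates
beyond; the explained variance on sub-confluent images (< 1,600 objects) is
99.8%, and the goodness-of-fit iteration flags the breakdown at 1,768 counts
(the test requires accumulated evidence past the true break; see
`docs/methods.md`).

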