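# embryoeval

Evaluation of embryo developmental-stage classification along three axes:
**accuracy** against a reference standard, **chance-corrected agreement**
between raters (human or model), and the **spatial interpretability** of
saliency-style model explanations.

## The problem

In time-lapse IVF monitoring, single embryo frames are staged on an ordinal
scale — 2-cell, 3-cell, 4-cell, 5-cell, 8/9-cell (merged, as in clinical
grading), morula, blastocyst — encoded 1..7. Convolutional classifiers for
this task are typically benchmarked on accuracy alone, but accuracy hides
two clinically relevant dimensions: whether a model *agrees* with experts
the way experts agree with each other, and whether the image regions the
model attends to (as visualised by Grad-CAM heatmaps or LIME superpixel
boundaries) are biologically meaningful and mutually consistent. This
package implements the full evaluation battery for that three-axis view,
together with a synthetic-data layer so every statistic is testable
without clinical images or a trained network.

## What it computes

* **Accuracy & confusion** — pooled and per-stage proportion correct; 7×7
  confusion matrices with round-half-up percent display.
* **Quadratic-weighted Cohen's κ** between any two raters, with weights
  `w_ij = 1 − (i−j)²/(K−1)²` over the full K = 7 coding,
  `κ = (p_o − p_e)/(1 − p_e)`, large-sample (Fleiss–Cohen–Everitt) SE,
  Wald 95% CI and a test of H₀: κ = 0. Stage-specific subgroup κ filters
  frames by reference stage while keeping labels on the 1..7 scale (so
  subgroup κ can legitimately go negative).
* **Fleiss' κ** for ≥ 3 raters with its asymptotic SE.
* **Cochran's Q** on the frames × raters correctness grid, with
  **McNemar post-hoc** pairwise tests (exact binomial below 25 discordant
  pairs, continuity-corrected χ² otherwise) under **Holm** step-down
  adjustment.
* **χ² / Fisher** two-proportion comparisons and the **Wilcoxon
  matched-pairs signed-rank** test (signed-rank sum W reported).
* **XAI overlap** — HSV colour segmentation turns heatmap overlays into
  binary masks (warm cyan-through-red hues contributive, blue and grey
  excluded); yellow boundary overlays are contour-filled; spatial
  agreement is IoU = |A∩B|/|A∪B|, summarised per stage by medians with
  distribution-free order-statistic 95% CIs.
* **Focus-rating analysis** — per-stage proportions of expert
  "good/intermediate/poor" assessments of heatmaps, model comparisons,
  and accuracy crossed with rating group.

The synthetic layer simulates raters with per-stage accuracy `a_s` and a
geometric adjacency decay ρ (errors land on stage j ≠ s with probability
∝ ρ^(|j−s|−1)), and renders heatmap/boundary overlays from known
ground-truth attention fields, so mask extraction and the agreement
estimators can be validated against closed-form oracles.

## Worked example

```sh
python examples/02_agreement_battery.py
```

prints (excerpt):

```
weighted kappa vs reference (95% CI):
  E1           k=0.979 [0.967, 0.991] p=<0.001
  ...
  resnet_like  k=0.964 [0.950, 0.977] p=<0.001
  vgg_like     k=0.939 [0.917, 0.960] p=<0.001

Fleiss kappa (E1..E3): 0.763 [0.734, 0.793]
...
Cochran's Q(4) = 33.60, p = <0.001
Holm-adjusted McNemar post-hocs (significant pairs):
  E1 vs vgg_like: p_holm = <0.001
```

Note the dissociation the battery is designed to expose: the simulated
models sit ~15 accuracy points below the human raters, yet their weighted
κ vs the reference stays above 0.93 — quadratic weights penalise the
dominant adjacent-stage errors only lightly, so κ and accuracy answer
different questions. Cochran's Q still detects the rater-wise accuracy
differences, and the Holm-adjusted McNemar post-hocs localise them to the
human-vs-model pairs.

Each numbered script under `examples/` exercises one capability
(simulation, agreement battery, XAI overlap, focus ratings, full
pipeline). The `embryoeval` CLI wraps the same pipeline:
`embryoeval analyze --out report_dir` writes `report.json` and
`report.md`; `embryoeval mask` / `embryoeval iou` operate on single PNGs.

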