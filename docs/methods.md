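# Methods

## Stage coding

Frames are staged on the ordinal scale 2-cell (1), 3-cell (2), 4-cell (3),
5-cell (4), 8/9-cell (5), morula (6), blastocyst (7). The 8- and 9-cell
annotations merge into one class because they are routinely
interchangeable in clinical grading; the merge happens at parse time and
every downstream statistic operates on the 7-level coding. The coding is
order-preserving in developmental time, which is the premise behind
quadratic disagreement weights.

## Rater simulation

A simulated rater is a per-stage accuracy vector `a_s` plus an adjacency
decay `ρ ∈ (0, 1]`. Conditional on an error at true stage *s*, the
assigned stage *j ≠ s* has probability proportional to `ρ^(|j−s|−1)`:
as ρ → 0 all errors land on the nearest neighbouring stages, matching the
dominant error mode of both embryologists and CNN classifiers on this
task; ρ = 1 spreads errors uniformly. The default ρ = 0.25 makes adjacent
errors heavily dominant without being degenerate. Raters are mutually
independent given the true stage.

Because each profile's full conditional confusion matrix is available in
closed form, the joint label distribution of two simulated raters is
`P(i, j) = Σ_s π_s C_a[s, i] C_b[s, j]`, and the population value of any
agreement coefficient follows analytically
(`expected_weighted_kappa`). This is the oracle used to validate the
empirical estimator: on a ~5,000-row simulated table the estimate must
land within 0.03 of the closed-form value.

Default study shape: 31 embryos, 35 frames per stage (245 frames total,
equal per stage — per-stage counts of the emulated study design are not
fixed by anything, so a balanced design is used), three human-like raters
with `a_s` ≈ 0.89–0.91 and two model-like raters at 0.79 and 0.74. All
frame counts and accuracies are configurable.

What the generator deliberately does **not** emulate: embryo-image
appearance (backgrounds are flat grey plus luminance noise), correlation
of errors across raters beyond the shared true stage, within-embryo frame
correlation, and class imbalance. Consequently, green tests demonstrate
the *estimators and pipeline* are correct under known conditions — they
say nothing about how any particular classifier behaves on real embryo
images.

## Agreement statistics

* **Weighted Cohen's κ.** Quadratic weights `w_ij = 1 − (i−j)²/(K−1)²`.
  The weight denominator always uses the full coding span (K = 7) even on
  subgroup tables missing categories, so stage-wise κ values are
  comparable across stages. The CI uses the Fleiss–Cohen–Everitt
  large-sample variance with a Wald interval clipped to [−1, 1]; the
  p-value uses the null-variance (κ = 0) form of the same expansion. At
  exactly perfect agreement the variance expansion is identically zero
  and the SE is set to 0 rather than left to floating-point residue.
* **Stage-specific (subgroup) κ** filters rows by *reference* stage while
  the two raters' labels stay free over 1..7. When raters systematically
  place a stage's frames on opposite neighbours this produces negative
  κ — a real phenomenon in early cleavage stages, not an error.
* **Fleiss' κ** uses the classical large-sample null SE (Fleiss 1971).
  It requires ≥ 3 raters; two raters are served by Cohen's κ.
* **Cochran's Q** is computed from the textbook formula with df = k − 1.
  A constant grid (all correct or all wrong) raises a degenerate-table
  error; a grid whose every row is unanimous but not globally constant
  has no within-frame discordance and returns Q = 0, p = 1.
* **McNemar post-hocs** use the exact two-sided binomial tail when the
  discordant count is below 25 and the continuity-corrected χ² form
  otherwise. The Holm family is all pairs within one call. Zero
  discordant pairs yield p = 1 with a flag rather than an error.
* **Two-proportion comparison** uses the Yates-corrected 2×2 χ², falling
  back to Fisher's exact test when any expected cell is below 5 **or**
  any observed cell is zero (the χ² approximation is unreliable in both
  regimes). Equal observed rows short-circuit to statistic 0, p 1.
* **Wilcoxon signed-rank** drops zero differences, mid-ranks ties, and
  reports the signed-rank sum W = R⁺ − R⁻ together with the median
  difference. The p-value is the exact tail for n ≤ 25 with tie-free
  magnitudes, otherwise the normal approximation with tie-corrected
  variance.
* p-values below 10⁻³ are *displayed* as "<0.001" in reports; stored
  values keep full precision.

## Explanation overlays and masks

The heatmap renderer maps relevance r ∈ [0, 1] to hue 240°(1 − r)
(blue → cyan → green → yellow → red), full saturation and value, then
alpha-blends over neutral grey (default α = 0.5). Blending any colour
with grey leaves hue unchanged, so relevance class survives rendering.
The ground-truth mask is the level set `field ≥ 0.25`; at that cutoff the
colour scale crosses from blue into cyan, so truth-mask pixels are exactly
the pixels rendered with contributive hues — mask extraction and truth
agree by construction, up to 8-bit rounding at the level-set boundary.

Mask extraction keeps pixels with hue in [0°, 180°] ∪ [330°, 360°]
(warm half plus the red wrap), saturation ≥ 0.20 and value ≥ 0.15; the
saturation floor excludes the grey background, the value floor excludes
dark pixels. All thresholds are configurable (`HueConfig`).

The boundary renderer draws each region's closed inner boundary
(region minus its erosion, thickened inward to the line width) in pure
yellow. Recovery detects yellow by hue, morphologically closes gaps up to
2 px, and fills every closed contour with `binary_fill_holes`; nested
contours merge into the outermost region. The boundary image is padded
before closing/filling so that contours truncated by the image border
remain closed — without padding, closing erodes border-lying contour
pixels and border-touching regions fail to fill.

Round-trip floors enforced by the tests: heatmap render→extract IoU
≥ 0.95 and boundary render→fill IoU ≥ 0.90 against the constructed truth,
across a fixed battery of 10 seeds.

IoU with an empty union is defined as 0 with a degenerate flag (so a
stage whose explanations never overlap reports 0% rather than
undefined). Masks of differing sizes are rejected, not resampled.
Stage-wise summaries report medians of percent IoU with the
distribution-free order-statistic 95% CI (`[x_(a), x_(n−a+1)]` with `a`
the largest rank keeping ≥ 95% binomial coverage); below n = 6 no such
interval exists and the CI is reported as undefined.

## Focus ratings

Expert assessments of heatmap relevance use the 3-level scale
good / intermediate / poor. Multiple raters are collapsed by majority
vote with ties resolved to "intermediate" (the scale's natural middle);
the tie-break is configurable. Cells with fewer than 5 frames are flagged
"too few instances" and excluded from between-group testing, mirroring
the expected-count-5 rule of the underlying χ² machinery.

The fixture generator draws one consensus rating per frame × model from
model-specific mixes (defaults 0.89/0.10/0.01 and 0.59/0.14/0.27 — one
model whose explanations are mostly judged on-target, one with a large
off-target fraction), independent of classification correctness.

## Pipeline and determinism

A run is driven by one `RunConfig` with exactly one input mode: `simulate`
(a `FixtureConfig`) or `inputs` (paths to ratings/focus CSVs and an
overlay manifest). One integer seed drives a single root generator from
which all sub-seeds are derived (per frame × model sub-seeds come from a
SHA-256 mix of the run seed and the frame/model identity, keeping results
independent of iteration order). The report bundle carries a provenance
block (config hash, seed, version) and no timestamps, so identical
config + seed serialise to a byte-identical `report.json`.

A seeding hazard worth noting for users composing the generators
manually: passing the *same* integer seed to two different generator
functions makes their underlying uniform streams coincide, which can
silently correlate e.g. focus ratings with classification correctness.
The pipeline always derives distinct sub-seeds; scripts should too.

Default problem sizes: the pipeline renders and scores overlays for 5
frames per stage (70 frame × model pairs at 224×224) — the IoU medians
stabilise quickly and this keeps a full run in seconds; the cap is
configurable (`iou_max_frames_per_stage`). Type-I calibration checks use
1,000 replicates; oracle-equivalence sweeps use 200 random tables of ≤ 12
frames.

## Known limitations

* κ confidence intervals are asymptotic (Wald); no bootstrap option. For
  κ near ±1 with small n the clipped Wald interval is conservative.
* The exact Wilcoxon path requires tie-free magnitudes; tied small
  samples fall back to the normal approximation.
* LIME-style recovery assumes boundaries are drawn over a background that
  contains no saturated yellow; boundary overlays composited onto heatmap
  backgrounds would need a tighter yellow hue window.
* The simulator's conditional-independence assumption between raters
  makes pairwise κ between simulated raters lower than between raters
  with correlated errors; real expert panels are positively correlated.
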