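"""Render explanation overlays with known ground truth and measure overlap.

A heatmap overlay is rendered from a disc-shaped relevance field and
segmented back into a binary mask by hue; a boundary overlay is drawn
around a shifted copy of the same region and recovered by contour filling.
Their intersection-over-union quantifies how well two explanation styles
agree on where the "model" was looking.
"""

import numpy as np

from embryoeval import (
    disc_attention,
    gradcam_to_mask,
    iou,
    lime_to_mask,
    render_gradcam_overlay,
    render_lime_overlay,
)
from scipy import ndimage

truth = disc_attention((224, 224), radius=45)
overlay = render_gradcam_overlay(truth, seed=1)
heat_mask = gradcam_to_mask(overlay)
print(f"heatmap mask: {heat_mask.positive_count} px; "
      f"truth: {int(truth.truth_mask.sum())} px")
print(f"render->extract round-trip IoU: "
      f"{iou(heat_mask.grid, truth.truth_mask).iou:.3f}")  # ~= 1: recoverable

# a LIME-style region displaced 30 px from the heatmap focus
region = ndimage.shift(truth.truth_mask.astype(float), (30, 0), order=0) > 0.5
lime_overlay = render_lime_overlay([region], background=128, line_width=2)
lime_mask = lime_to_mask(lime_overlay)
res = iou(heat_mask.grid, lime_mask.grid)
print(f"\nheatmap vs boundary-overlay IoU: {res.iou:.3f} ({res.percent:.1f}%)")
print(f"intersection {res.intersection_px} px / union {res.union_px} px")
# partial overlap: the two explanation styles only partly agree spatially
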