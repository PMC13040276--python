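"""Binary-mask extraction from explanation overlays and IoU overlap.

Grad-CAM heatmaps and LIME boundary overlays are reduced to boolean masks
of "contributive" pixels:

* For heatmaps, colour segmentation in HSV space keeps pixels whose hue
  lies in the warm (cyan-through-red) half of the scale and whose
  saturation and value clear minimal thresholds — blue hues and the
  desaturated grey background are non-contributive.
* For LIME overlays, pure-yellow boundary pixels are detected, small gaps
  are morphologically closed, and each closed contour is filled; all filled
  regions merge into one mask.

Spatial agreement between two explanations for the same frame is the
intersection-over-union of their masks, reported both as a ratio in [0, 1]
and as a percentage. Stage-wise summaries use the distribution-free
order-statistic 95% confidence interval for the median.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.color import rgb2hsv

from .agreement import TestResult, wilcoxon_signed_rank
from .exceptions import ParameterError, ShapeMismatchError
from .render import OverlayImage

__all__ = [
    "BinaryMask",
    "HueConfig",
    "IoUResult",
    "DEFAULT_GRADCAM_HUE",
    "DEFAULT_YELLOW_HUE",
    "gradcam_to_mask",
    "lime_to_mask",
    "iou",
    "median_ci",
    "stagewise_iou_summary",
]


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean grid of contributive pixels."""

    grid: np.ndarray
    empty_input: bool = False  # set when no signal pixels were found at all

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2 or g.size == 0:
            raise ParameterError("mask grid must be a non-empty 2-D boolean array")
        object.__setattr__(self, "grid", g)

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def positive_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class HueConfig:
    """HSV segmentation thresholds.

    ``contributive_hue_ranges`` are closed intervals in degrees on the hue
    circle (a range may wrap past 360 by listing e.g. (330, 360) and
    (0, 30) separately). Pixels must also meet ``min_saturation`` and
    ``min_value`` so that desaturated/dark background never segments.
    """

    contributive_hue_ranges: tuple[tuple[float, float], ...] = ((0.0, 180.0), (330.0, 360.0))
    min_saturation: float = 0.20
    min_value: float = 0.15

    def __post_init__(self) -> None:
        for lo, hi in self.contributive_hue_ranges:
            if not (0.0 <= lo <= hi <= 360.0):
                raise ParameterError(f"malformed hue range ({lo}, {hi})")
        for name in ("min_saturation", "min_value"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")

    def select(self, hsv: np.ndarray) -> np.ndarray:
        hue = hsv[..., 0] * 360.0
        keep = np.zeros(hue.shape, dtype=bool)
        for lo, hi in self.contributive_hue_ranges:
            keep |= (hue >= lo) & (hue <= hi)
        keep &= hsv[..., 1] >= self.min_saturation
        keep &= hsv[..., 2] >= self.min_value
        return keep


#: Warm (cyan-through-red) half of the heatmap scale; blue band excluded.
DEFAULT_GRADCAM_HUE = HueConfig()

#: Pure yellow boundary lines as drawn by the LIME renderer.
DEFAULT_YELLOW_HUE = HueConfig(
    contributive_hue_ranges=((45.0, 75.0),), min_saturation=0.5, min_value=0.5
)


@dataclass(frozen=True)
class IoUResult:
    intersection_px: int
    union_px: int
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def iou(self) -> float:
        return self.intersection_px / self.union_px if self.union_px else 0.0

    @property
    def percent(self) -> float:
        return 100.0 * self.iou

    def to_dict(self) -> dict:
        return {
            "intersection_px": self.intersection_px,
            "union_px": self.union_px,
            "iou": self.iou,
            "percent": self.percent,
            "degenerate": self.degenerate,
        }


def _as_rgb(image: OverlayImage | np.ndarray, expected_kind: str | None) -> np.ndarray:
    if isinstance(image, OverlayImage):
        if expected_kind is not None and image.kind != expected_kind:
            raise ParameterError(
                f"expected a {expected_kind} overlay, got {image.kind!r}"
            )
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ParameterError("overlay raster must be HxWx3 RGB")
    return arr


def gradcam_to_mask(
    image: OverlayImage | np.ndarray, config: HueConfig = DEFAULT_GRADCAM_HUE
) -> BinaryMask:
    """Segment a heatmap overlay into its contributive-pixel mask.

    A pixel is contributive iff its hue lies in the configured warm range
    and its saturation and value clear the thresholds; blue and grey pixels
    stay black.
    """
    rgb = _as_rgb(image, "gradcam")
    hsv = rgb2hsv(rgb)
    return BinaryMask(grid=config.select(hsv))


def lime_to_mask(
    image: OverlayImage | np.ndarray,
    yellow_config: HueConfig = DEFAULT_YELLOW_HUE,
    gap_closing_px: int = 2,
) -> BinaryMask:
    """Recover the filled super-pixel union from a yellow-boundary overlay.

    Yellow boundary pixels are detected by hue, gaps up to
    ``gap_closing_px`` are morphologically closed, and every closed contour
    is filled; nested contours merge into the outermost region. With no
    yellow pixels at all, an all-false mask is returned and a warning
    (not an error) is emitted.
    """
    rgb = _as_rgb(image, "lime")
    hsv = rgb2hsv(rgb)
    boundary = yellow_config.select(hsv)
    if not boundary.any():
        warnings.warn("no yellow boundary pixels found; returning empty mask",
                      stacklevel=2)
        return BinaryMask(grid=boundary, empty_input=True)
    # pad so that closing cannot erode contour segments lying on the image
    # border (regions cut off by the frame edge stay closed)
    pad = gap_closing_px + 1
    padded = np.pad(boundary, pad, constant_values=False)
    if gap_closing_px > 0:
        structure = ndimage.generate_binary_structure(2, 2)
        padded = ndimage.binary_closing(
            padded, structure=structure, iterations=gap_closing_px, border_value=0
        )
    filled = ndimage.binary_fill_holes(padded)[pad:-pad, pad:-pad]
    return BinaryMask(grid=filled | boundary)


def iou(mask_a: BinaryMask | np.ndarray, mask_b: BinaryMask | np.ndarray) -> IoUResult:
    """Intersection-over-union of two binary masks of identical shape.

    ``iou = |A & B| / |A | B|``; both masks empty gives 0 with the
    degenerate flag set.
    """
    a = mask_a.grid if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, dtype=bool)
    b = mask_b.grid if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    return IoUResult(intersection_px=inter, union_px=union, degenerate=union == 0)


def median_ci(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Median with a distribution-free order-statistic confidence interval.

    Returns ``(median, ci_low, ci_high)``. The interval is
    ``[x_(a), x_(n-a+1)]`` (1-indexed order statistics) with ``a`` the
    largest rank satisfying ``P(Bin(n, 1/2) < a) <= alpha/2``, giving
    coverage >= ``confidence``. For n too small (no valid ``a``, i.e.
    n < 6 at 95%) the bounds are NaN.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ParameterError("median_ci needs at least one value")
    med = float(np.median(x))
    alpha = 1.0 - confidence
    # largest a >= 1 with cdf(a-1) <= alpha/2
    a = int(stats.binom.ppf(alpha / 2.0, n, 0.5))
    while a >= 1 and stats.binom.cdf(a - 1, n, 0.5) > alpha / 2.0:
        a -= 1
    while stats.binom.cdf(a, n, 0.5) <= alpha / 2.0:
        a += 1
    if a < 1:
        return med, float("nan"), float("nan")
    return med, float(x[a - 1]), float(x[n - a])


def stagewise_iou_summary(
    records: pd.DataFrame,
    confidence: float = 0.95,
    min_n_for_ci: int = 6,
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Per stage x model medians of percent IoU, with paired model tests.

    ``records`` needs columns ``frame_id``, ``stage``, ``model`` and
    ``iou`` (ratio in [0, 1]). Returns a summary frame with columns
    ``stage, model, n, median_percent, ci_low, ci_high`` (CI bounds NaN
    when n < ``min_n_for_ci``) and, for each stage and model pair, a
    Wilcoxon signed-rank test on the frames present for both models.
    """
    required = {"frame_id", "stage", "model", "iou"}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ParameterError("no IoU records supplied")
    rows = []
    for (stage, model), grp in records.groupby(["stage", "model"], sort=True):
        pct = grp["iou"].to_numpy() * 100.0
        med, lo, hi = median_ci(pct, confidence)
        if len(pct) < min_n_for_ci:
            lo = hi = float("nan")
        rows.append(
            {
                "stage": stage,
                "model": model,
                "n": len(pct),
                "median_percent": round(med, 1),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    summary = pd.DataFrame(rows)

    tests: list[TestResult] = []
    models = sorted(records["model"].unique())
    for stage, grp in records.groupby("stage", sort=True):
        wide = grp.pivot_table(index="frame_id", columns="model", values="iou")
        for m1, m2 in itertools.combinations(models, 2):
            if m1 not in wide.columns or m2 not in wide.columns:
                continue
            both = wide[[m1, m2]].dropna()
            if len(both) < 2:
                continue
            res = wilcoxon_signed_rank(both[m1].to_numpy(), both[m2].to_numpy())
            res.extras.update({"stage": stage, "models": (m1, m2), "n_pairs": len(both)})
            tests.append(res)
    return summary, tests
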