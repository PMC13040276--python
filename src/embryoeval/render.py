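"""Synthetic explanation-overlay rendering with known ground truth.

Saliency-style explanations come in two rendered forms here:

* **Grad-CAM-style heatmaps** — a continuous relevance field mapped through
  a cold-to-hot colour scale (blue 240deg -> cyan -> green -> yellow ->
  red 0deg in hue) and alpha-blended over a neutral grey background.
  Because blending with grey leaves hue untouched, the relevance level of
  every pixel stays recoverable from the rendered image.
* **LIME-style boundary overlays** — closed pure-yellow contours drawn
  around the super-pixel regions that contribute to a prediction; region
  interiors are left untouched.

Both renderers start from a :class:`GroundTruthAttention` (or explicit
region masks) so that the mask-extraction stage can be validated by
construction: the binary mask recovered from a rendered overlay must agree
with the truth mask it was rendered from.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .exceptions import ParameterError, ShapeMismatchError

__all__ = [
    "GroundTruthAttention",
    "OverlayImage",
    "disc_attention",
    "blob_attention",
    "render_gradcam_overlay",
    "render_lime_overlay",
]

#: Relevance at which the colour scale leaves the blue band; pixels at or
#: above this level render with contributive (cyan-through-red) hues.
DEFAULT_RELEVANCE_CUTOFF = 0.25

YELLOW = np.array([255, 255, 0], dtype=np.uint8)


@dataclass(frozen=True)
class GroundTruthAttention:
    """A relevance field in [0, 1] plus the cutoff defining its truth mask."""

    field: np.ndarray
    relevance_cutoff: float = DEFAULT_RELEVANCE_CUTOFF

    def __post_init__(self) -> None:
        f = np.asarray(self.field, dtype=float)
        if f.ndim != 2 or f.size == 0:
            raise ParameterError("relevance field must be a non-empty 2-D grid")
        if f.min() < 0.0 or f.max() > 1.0:
            raise ParameterError("relevance values must lie in [0, 1]")
        if not (0.0 < self.relevance_cutoff < 1.0):
            raise ParameterError("relevance_cutoff must lie in (0, 1)")
        object.__setattr__(self, "field", f)

    @property
    def truth_mask(self) -> np.ndarray:
        """Boolean level set ``field >= relevance_cutoff``."""
        return self.field >= self.relevance_cutoff


@dataclass(frozen=True)
class OverlayImage:
    """An 8-bit RGB raster tagged with the explanation style it renders."""

    pixels: np.ndarray
    kind: str  # "gradcam" | "lime"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ParameterError("overlay pixels must be HxWx3 uint8")
        if self.kind not in ("gradcam", "lime"):
            raise ParameterError(f"unknown overlay kind {self.kind!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def disc_attention(
    shape: tuple[int, int] = (224, 224),
    center: tuple[float, float] | None = None,
    radius: float | None = None,
    relevance_cutoff: float = DEFAULT_RELEVANCE_CUTOFF,
) -> GroundTruthAttention:
    """Radially decaying relevance field whose truth mask is a disc.

    The field equals 1 at the centre and decays linearly so that it crosses
    ``relevance_cutoff`` exactly at ``radius``; the truth mask is therefore
    the disc of that radius.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = min(h, w) / 4.0
    if radius <= 0:
        raise ParameterError("radius must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - center[0], xx - center[1])
    field = np.clip(1.0 - (d / radius) * (1.0 - relevance_cutoff), 0.0, 1.0)
    return GroundTruthAttention(field=field, relevance_cutoff=relevance_cutoff)


def blob_attention(
    shape: tuple[int, int],
    rng: np.random.Generator,
    n_blobs: int = 2,
    relevance_cutoff: float = DEFAULT_RELEVANCE_CUTOFF,
) -> GroundTruthAttention:
    """Random smooth multi-blob relevance field (sum of Gaussians, peak 1)."""
    h, w = shape
    if n_blobs < 1:
        raise ParameterError("n_blobs must be >= 1")
    yy, xx = np.mgrid[0:h, 0:w]
    field = np.zeros(shape, dtype=float)
    for _ in range(n_blobs):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        sigma = rng.uniform(0.06, 0.16) * min(h, w)
        field += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    field /= field.max()
    return GroundTruthAttention(field=field, relevance_cutoff=relevance_cutoff)


def relevance_to_rgb(field: np.ndarray) -> np.ndarray:
    """Map relevance [0, 1] through the blue->red scale; returns float RGB."""
    hue = (240.0 * (1.0 - np.asarray(field, dtype=float))) / 360.0
    hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
    return hsv_to_rgb(hsv)


def render_gradcam_overlay(
    truth: GroundTruthAttention,
    background_level: int = 128,
    blend_alpha: float = 0.5,
    seed: int | None = None,
    noise_sigma: float = 6.0,
) -> OverlayImage:
    """Render a heatmap overlay of a relevance field over a grey background.

    The colour scale runs blue (relevance 0) through cyan, green and yellow
    to red (relevance 1); at the default cutoff 0.25 the scale crosses from
    blue into cyan, so truth-mask pixels render with contributive hues.
    ``seed`` adds mild luminance-only texture to the background (equal in
    all channels, hence hue-preserving).
    """
    if not (0.0 <= blend_alpha <= 1.0):
        raise ParameterError("blend_alpha must lie in [0, 1]")
    if not (0 <= background_level <= 255):
        raise ParameterError("background_level must lie in 0..255")
    h, w = truth.field.shape
    bg = np.full((h, w), float(background_level))
    if seed is not None and noise_sigma > 0:
        rng = np.random.default_rng(seed)
        bg = np.clip(bg + rng.normal(0.0, noise_sigma, size=(h, w)), 0.0, 255.0)
    color = relevance_to_rgb(truth.field) * 255.0
    out = blend_alpha * color + (1.0 - blend_alpha) * bg[..., None]
    return OverlayImage(
        pixels=np.clip(np.round(out), 0, 255).astype(np.uint8), kind="gradcam"
    )


def _region_boundary(mask: np.ndarray, line_width: int) -> np.ndarray:
    """Closed inner boundary of a filled region, thickened to line_width."""
    mask = np.asarray(mask, dtype=bool)
    inner = mask & ~ndimage.binary_erosion(mask, border_value=0)
    if line_width > 1:
        inner = ndimage.binary_dilation(inner, iterations=line_width - 1) & mask
    return inner


def render_lime_overlay(
    regions: Sequence[np.ndarray],
    background: OverlayImage | int = 128,
    line_width: int = 2,
) -> OverlayImage:
    """Draw pure-yellow closed boundaries of regions over a background.

    ``regions`` are boolean masks sharing one shape; interiors are not
    recoloured. An empty region list returns the background unchanged.
    """
    if line_width < 1:
        raise ParameterError("line_width must be >= 1")
    if isinstance(background, OverlayImage):
        canvas = background.pixels.copy()
    else:
        if regions is None or len(regions) == 0:
            raise ParameterError(
                "a gray-level background needs at least one region to size the image"
            )
        if not (0 <= int(background) <= 255):
            raise ParameterError("background gray level must lie in 0..255")
        shape = np.asarray(regions[0]).shape
        canvas = np.full(shape + (3,), int(background), dtype=np.uint8)
    for region in regions or []:
        region = np.asarray(region, dtype=bool)
        if region.shape != canvas.shape[:2]:
            raise ShapeMismatchError(
                f"region shape {region.shape} != image shape {canvas.shape[:2]}"
            )
        canvas[_region_boundary(region, line_width)] = YELLOW
    return OverlayImage(pixels=canvas, kind="lime")
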