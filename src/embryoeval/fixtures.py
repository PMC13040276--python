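"""Self-contained synthetic study fixtures.

A fixture bundle emulates the shape of a single-centre embryo-staging
study: ~245 single frames from ~31 embryos spread over the 7 merged
stages, three human raters whose errors fall mostly on adjacent stages,
two classifier-like raters with lower accuracy, per-frame heatmap and
boundary-overlay explanation images for the two models (with their
ground-truth attention masks), and a 3-level spatial-focus rating per
frame and model. Everything is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as eio
from .exceptions import ParameterError
from .focus import RATING_LEVELS
from .render import (
    GroundTruthAttention,
    OverlayImage,
    blob_attention,
    render_gradcam_overlay,
    render_lime_overlay,
)
from .simulate import RaterProfile, simulate_rating_table, uniform_profile
from .stages import ALL_CODES

__all__ = ["FixtureConfig", "simulate_focus_ratings", "simulate_frame_overlays",
           "make_fixture_bundle"]

#: Overall focus-rating mixes used for the two simulated models: one whose
#: explanations are mostly judged on-target and one with a sizeable
#: off-target fraction.
DEFAULT_FOCUS_MIX = {
    "resnet_like": (0.89, 0.10, 0.01),
    "vgg_like": (0.59, 0.14, 0.27),
}

#: Pixel jitter applied to the LIME region relative to the heatmap truth
#: mask, per model — the knob controlling how much the two explanation
#: styles spatially agree. Defaults put both models in the weak-overlap
#: regime (median IoU in the 20-40% band) typical of independent post-hoc
#: explanation methods, with the second model slightly weaker.
DEFAULT_LIME_JITTER = {"resnet_like": 38, "vgg_like": 44}


@dataclass(frozen=True)
class FixtureConfig:
    """Study-scale defaults: 31 embryos, 35 frames per stage (245 total)."""

    n_embryos: int = 31
    frames_per_stage: int | dict[int, int] = 35
    embryologist_accuracy: tuple[float, ...] = (0.91, 0.90, 0.89)
    model_accuracy: dict[str, float] = dc_field(
        default_factory=lambda: {"resnet_like": 0.79, "vgg_like": 0.74}
    )
    adjacency_decay: float = 0.25
    image_size: int = 224
    blend_alpha: float = 0.5
    line_width: int = 2
    focus_mix: dict[str, tuple[float, float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_FOCUS_MIX)
    )
    lime_jitter_px: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_LIME_JITTER)
    )

    def profiles(self) -> list[RaterProfile]:
        profiles = [
            uniform_profile(f"E{i + 1}", a, self.adjacency_decay)
            for i, a in enumerate(self.embryologist_accuracy)
        ]
        profiles += [
            uniform_profile(model, a, self.adjacency_decay)
            for model, a in self.model_accuracy.items()
        ]
        return profiles

    @property
    def embryologist_ids(self) -> list[str]:
        return [f"E{i + 1}" for i in range(len(self.embryologist_accuracy))]

    @property
    def model_ids(self) -> list[str]:
        return list(self.model_accuracy)


def simulate_focus_ratings(
    frame_ids: list[str],
    model_ids: list[str],
    focus_mix: dict[str, tuple[float, float, float]],
    seed: int,
) -> pd.DataFrame:
    """Draw one consensus focus rating per (frame, model) from a fixed mix."""
    rng = np.random.default_rng(seed)
    rows = []
    for model in model_ids:
        mix = np.asarray(focus_mix[model], dtype=float)
        if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
            raise ParameterError(f"focus mix for {model!r} is not a distribution")
        draws = rng.choice(len(RATING_LEVELS), size=len(frame_ids), p=mix)
        for frame, d in zip(frame_ids, draws):
            rows.append({"frame_id": frame, "model_id": model,
                         "rating": RATING_LEVELS[d]})
    return pd.DataFrame(rows)


def _jittered_region(truth_mask: np.ndarray, jitter_px: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Translate the truth mask by a random offset of magnitude ~jitter_px."""
    if jitter_px <= 0:
        return truth_mask.copy()
    dy, dx = rng.integers(-jitter_px, jitter_px + 1, size=2)
    return ndimage.shift(truth_mask.astype(float), (dy, dx), order=0,
                         mode="constant", cval=0.0) > 0.5


def simulate_frame_overlays(
    config: FixtureConfig,
    model_id: str,
    seed: int,
) -> tuple[GroundTruthAttention, OverlayImage, OverlayImage, np.ndarray]:
    """One frame's heatmap + boundary overlay for one model.

    Returns ``(truth, gradcam_overlay, lime_overlay, lime_region)``. The
    LIME region is the heatmap truth mask displaced by a model-specific
    jitter, so cross-method overlap is high for the low-jitter model and
    lower for the other.
    """
    rng = np.random.default_rng(seed)
    shape = (config.image_size, config.image_size)
    truth = blob_attention(shape, rng, n_blobs=int(rng.integers(1, 3)))
    gradcam = render_gradcam_overlay(
        truth, blend_alpha=config.blend_alpha, seed=int(rng.integers(2**31))
    )
    region = _jittered_region(
        truth.truth_mask, config.lime_jitter_px.get(model_id, 0), rng
    )
    if not region.any():  # jitter pushed the region off-canvas
        region = truth.truth_mask.copy()
    lime = render_lime_overlay([region], background=128,
                               line_width=config.line_width)
    return truth, gradcam, lime, region


def make_fixture_bundle(
    config: FixtureConfig,
    seed: int,
    out_dir: str | Path,
    write_overlays: bool = True,
    max_overlay_frames: int | None = 10,
) -> dict:
    """Write a self-contained fixture directory and return its file map.

    Contents: ``ratings.csv``, ``focus_ratings.csv``, ``manifest.csv`` and
    (optionally) per-frame Grad-CAM/LIME/truth-mask PNGs for each simulated
    model under ``overlays/``. Overlays are written for the first
    ``max_overlay_frames`` frames by default to keep bundles small; pass
    ``None`` to render every frame. Deterministic under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    table = simulate_rating_table(
        config.n_embryos, config.frames_per_stage, config.profiles(),
        seed=int(rng.integers(2**31)),
    )
    files: dict = {"ratings": eio.write_ratings(table, out / "ratings.csv")}

    focus = simulate_focus_ratings(
        table["frame_id"].tolist(), config.model_ids, config.focus_mix,
        seed=int(rng.integers(2**31)),
    )
    files["focus_ratings"] = eio.write_focus_ratings(focus, out / "focus_ratings.csv")

    manifest_rows = []
    if write_overlays:
        overlay_dir = out / "overlays"
        frames = table["frame_id"].tolist()
        if max_overlay_frames is not None:
            frames = frames[:max_overlay_frames]
        stage_of = dict(zip(table["frame_id"], table["reference"]))
        for frame in frames:
            for model in config.model_ids:
                sub_seed = int(rng.integers(2**31))
                truth, gradcam, lime, _ = simulate_frame_overlays(
                    config, model, sub_seed
                )
                gpath = overlay_dir / f"gradcam_{model}_{frame}.png"
                lpath = overlay_dir / f"lime_{model}_{frame}.png"
                tpath = overlay_dir / f"truth_{model}_{frame}.png"
                eio.write_overlay_png(gradcam, gpath)
                eio.write_overlay_png(lime, lpath)
                eio.write_mask_png(truth.truth_mask, tpath)
                manifest_rows.append(
                    {
                        "frame_id": frame,
                        "stage": stage_of[frame],
                        "model": model,
                        "gradcam_path": str(gpath),
                        "lime_path": str(lpath),
                    }
                )
        manifest = pd.DataFrame(manifest_rows)
        manifest.to_csv(out / "manifest.csv", index=False, lineterminator="\n")
        files["manifest"] = out / "manifest.csv"
    return files
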