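"""Readers and writers for the package's plain-text and raster formats.

* Ratings CSV — header ``embryo_id,frame_id,reference,<rater>...``; stage
  values may be codes 1..7 or names t2/t3/t4/t5/t8/t9/tM/tB; the reader
  normalises everything to merged codes and reports malformed rows with
  their line numbers.
* Focus-rating CSV — header ``frame_id,model_id,rating`` with rating in
  {good, intermediate, poor}.
* Masks — single-channel PNG with values {0, 255}; overlays — RGB PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DataError, EmptyInputError
from .focus import RATING_LEVELS
from .overlap import BinaryMask
from .render import OverlayImage
from .stages import encode_stage

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_focus_ratings",
    "write_focus_ratings",
    "read_mask_png",
    "write_mask_png",
    "read_overlay_png",
    "write_overlay_png",
    "read_manifest",
]

_META_COLUMNS = ("embryo_id", "frame_id", "reference")


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read and normalise a ratings CSV.

    Returns a DataFrame with ``embryo_id``, ``frame_id``, integer
    ``reference`` and one integer column per rater. Unknown stage labels
    are collected and reported with their CSV line numbers in a single
    :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing required columns {missing}")
    rater_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not rater_cols:
        raise DataError(f"{path.name}: no rater columns found")
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: no data rows")

    dup = df.duplicated(subset=["embryo_id", "frame_id"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise DataError(f"{path.name}: duplicate (embryo_id, frame_id) at lines {lines}")

    errors: list[str] = []
    out = df[["embryo_id", "frame_id"]].copy()
    for col in ("reference", *rater_cols):
        codes = np.empty(len(df), dtype=int)
        for i, raw in enumerate(df[col]):
            try:
                codes[i] = encode_stage(raw)
            except Exception:
                errors.append(f"line {i + 2}, column {col!r}: {raw!r}")
                codes[i] = -1
        out[col] = codes
    if errors:
        shown = "; ".join(errors[:10])
        raise DataError(f"{path.name}: unparseable stage labels — {shown}")
    return out


def write_ratings(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def read_focus_ratings(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("frame_id", "model_id", "rating") if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing required columns {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: no data rows")
    bad = df[~df["rating"].isin(RATING_LEVELS)]
    if len(bad):
        lines = (bad.index + 2).tolist()[:10]
        raise DataError(f"{path.name}: unknown rating values at lines {lines}")
    return df


def write_focus_ratings(ratings: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ratings.to_csv(path, index=False, lineterminator="\n")
    return path


def write_mask_png(mask: BinaryMask | np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as a single-channel PNG with values {0, 255}."""
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((grid.astype(np.uint8) * 255), mode="L").save(path)
    return path


def read_mask_png(path: str | Path) -> BinaryMask:
    arr = np.asarray(Image.open(path).convert("L"))
    values = set(np.unique(arr).tolist())
    if not values <= {0, 255}:
        raise DataError(f"{Path(path).name}: mask PNG has values other than 0/255")
    return BinaryMask(grid=arr == 255)


def write_overlay_png(overlay: OverlayImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(overlay.pixels, mode="RGB").save(path)
    return path


def read_overlay_png(path: str | Path, kind: str) -> OverlayImage:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return OverlayImage(pixels=arr, kind=kind)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Batch-mode manifest: ``frame_id,stage,model,gradcam_path,lime_path``."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["frame_id", "stage", "model", "gradcam_path", "lime_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing required columns {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: no data rows")
    df["stage"] = [encode_stage(s) for s in df["stage"]]
    return df
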