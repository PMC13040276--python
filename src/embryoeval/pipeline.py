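"""End-to-end orchestration: simulate or ingest, analyse, report.

A run executes the full evaluation battery in a fixed order — ingest or
simulate the rating table, score accuracy and confusion per rater, run the
agreement battery (weighted kappa vs reference, all pairwise kappas,
Fleiss' kappa among the human raters, stage-wise subgroup kappas,
Cochran's Q with Holm-adjusted McNemar post-hocs), extract explanation
masks and their IoU overlap, cross focus ratings with correctness, and
assemble everything into one JSON-serialisable report bundle with a
provenance block (config hash, seed, package version). Identical config
and seed produce a byte-identical ``report.json``.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as eio
from .agreement import (
    accuracy,
    cochran_q,
    cohen_weighted_kappa,
    confusion,
    correctness_grid,
    fleiss_kappa,
    format_p,
    mcnemar_pairwise,
)
from .exceptions import DataError, EmbryoEvalError, ParameterError
from .fixtures import FixtureConfig, simulate_focus_ratings, simulate_frame_overlays
from .focus import accuracy_by_focus, compare_models_on_rating, rating_proportions
from .overlap import gradcam_to_mask, iou, lime_to_mask, stagewise_iou_summary
from .simulate import simulate_rating_table
from .stages import ALL_CODES, STAGE_NAMES

log = logging.getLogger("embryoeval")

__all__ = ["RunConfig", "run", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`FixtureConfig`) or ``inputs``
    (paths to ratings/focus CSVs and an overlay manifest) is active.
    """

    seed: int = 0
    simulate: FixtureConfig | None = None
    inputs: dict[str, str] | None = None
    embryologist_ids: tuple[str, ...] = ("E1", "E2", "E3")
    model_ids: tuple[str, ...] = ("resnet_like", "vgg_like")
    alpha: float = 0.05
    iou_max_frames_per_stage: int = 5
    figures: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ParameterError(
                "exactly one of 'simulate' or 'inputs' must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = FixtureConfig(**sim)
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("embryologist_ids", "model_ids"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def canonical_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _kappa_record(table, a, b, **kw) -> dict:
    try:
        res = cohen_weighted_kappa(table, a, b, **kw)
        d = res.to_dict()
        d["p_display"] = format_p(res.p_value)
        return d
    except EmbryoEvalError as exc:
        return {"error": f"{type(exc).__name__}: {exc}"}


def _stage_subseed(seed: int, *parts) -> int:
    """Stable sub-seed derived from the run seed and string/int parts."""
    mix = hashlib.sha256(("/".join(map(str, (seed, *parts)))).encode()).digest()
    return int.from_bytes(mix[:4], "big") % (2**31)


def _simulated_iou_records(config: RunConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Render explanations for a per-stage subset of frames and score IoU."""
    sim = config.simulate
    assert sim is not None
    rows = []
    for stage in ALL_CODES:
        frames = table.loc[table["reference"] == stage, "frame_id"]
        frames = frames.iloc[: config.iou_max_frames_per_stage]
        for k, frame in enumerate(frames):
            for model in sim.model_ids:
                sub_seed = _stage_subseed(config.seed, stage, k, model)
                _, gradcam, lime, _ = simulate_frame_overlays(sim, model, sub_seed)
                g_mask = gradcam_to_mask(gradcam)
                l_mask = lime_to_mask(lime)
                rows.append(
                    {
                        "frame_id": frame,
                        "stage": stage,
                        "model": model,
                        "iou": iou(g_mask, l_mask).iou,
                    }
                )
    return pd.DataFrame(rows)


def _manifest_iou_records(manifest: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for rec in manifest.itertuples(index=False):
        g_mask = gradcam_to_mask(eio.read_overlay_png(rec.gradcam_path, "gradcam"))
        l_mask = lime_to_mask(eio.read_overlay_png(rec.lime_path, "lime"))
        rows.append(
            {
                "frame_id": rec.frame_id,
                "stage": int(rec.stage),
                "model": rec.model,
                "iou": iou(g_mask, l_mask).iou,
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report bundle."""
    t0 = time.perf_counter()
    bundle: dict = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "config": config.canonical_dict(),
        }
    }

    # -- ingest or simulate -------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        rng = np.random.default_rng(config.seed)
        table = simulate_rating_table(
            sim.n_embryos, sim.frames_per_stage, sim.profiles(),
            seed=int(rng.integers(2**31)),
        )
        focus = simulate_focus_ratings(
            table["frame_id"].tolist(), sim.model_ids, sim.focus_mix,
            seed=int(rng.integers(2**31)),
        )
        embryologists = list(sim.embryologist_ids)
        models = list(sim.model_ids)
        iou_records = _simulated_iou_records(config, table)
    else:
        inputs = dict(config.inputs or {})
        if "ratings" not in inputs:
            raise DataError("inputs must provide a 'ratings' CSV path")
        table = eio.read_ratings(inputs["ratings"])
        focus = (
            eio.read_focus_ratings(inputs["focus_ratings"])
            if "focus_ratings" in inputs
            else None
        )
        embryologists = [r for r in config.embryologist_ids if r in table.columns]
        models = [m for m in config.model_ids if m in table.columns]
        iou_records = (
            _manifest_iou_records(eio.read_manifest(inputs["manifest"]))
            if "manifest" in inputs
            else None
        )
    raters = embryologists + models
    log.info("ingest: %d frames, raters %s", len(table), raters)

    # -- accuracy and confusion ---------------------------------------------
    acc = {r: accuracy(table, r).to_dict() for r in raters}
    if embryologists:
        acc["embryologists_pooled"] = accuracy(table, embryologists).to_dict()
    bundle["accuracy"] = acc
    bundle["confusion"] = {
        r: {
            "counts": confusion(table, r).counts.tolist(),
            "display_percent": confusion(table, r).display_percent.tolist(),
        }
        for r in raters
    }
    if embryologists:
        pooled = confusion(table, embryologists)
        bundle["confusion"]["embryologists_pooled"] = {
            "counts": pooled.counts.tolist(),
            "display_percent": pooled.display_percent.tolist(),
        }

    # -- agreement battery ---------------------------------------------------
    bundle["kappa_vs_reference"] = {
        r: _kappa_record(table, r, "reference") for r in raters
    }
    bundle["kappa_pairwise"] = {
        f"{a}|{b}": _kappa_record(table, a, b)
        for a, b in itertools.combinations(raters, 2)
    }
    if len(embryologists) >= 3:
        try:
            bundle["fleiss_embryologists"] = fleiss_kappa(
                table, embryologists
            ).to_dict()
        except EmbryoEvalError as exc:
            bundle["fleiss_embryologists"] = {"error": str(exc)}

    stagewise: dict = {}
    for stage in ALL_CODES:
        entry: dict = {"stage_name": STAGE_NAMES[stage]}
        if len(embryologists) >= 3:
            try:
                entry["embryologists_fleiss"] = fleiss_kappa(
                    table, embryologists, subgroup_stage=stage
                ).to_dict()
            except EmbryoEvalError as exc:
                entry["embryologists_fleiss"] = {"error": str(exc)}
        if len(models) == 2:
            entry["models_cohen"] = _kappa_record(
                table, models[0], models[1], subgroup_stage=stage
            )
        stagewise[str(stage)] = entry
    bundle["kappa_stagewise"] = stagewise

    grid = correctness_grid(table, raters)
    try:
        q = cochran_q(grid)
        bundle["cochran_q"] = q.to_dict()
        posthoc = mcnemar_pairwise(grid)
        bundle["mcnemar_posthoc"] = [r.to_dict() for r in posthoc]
    except EmbryoEvalError as exc:
        bundle["cochran_q"] = {"error": str(exc)}
        bundle["mcnemar_posthoc"] = []

    # -- XAI overlap ----------------------------------------------------------
    if iou_records is not None and len(iou_records):
        summary, tests = stagewise_iou_summary(iou_records)
        bundle["iou"] = {
            "summary": summary.to_dict(orient="records"),
            "stage_tests": [t.to_dict() for t in tests],
            "overall_median_percent": {
                m: round(
                    float(iou_records.loc[iou_records["model"] == m, "iou"]
                          .median() * 100.0), 1)
                for m in sorted(iou_records["model"].unique())
            },
        }

    # -- focus ratings ---------------------------------------------------------
    if focus is not None and len(focus) and models:
        stage_of = dict(zip(table["frame_id"], table["reference"]))
        props = rating_proportions(focus, stage_of)
        bundle["focus"] = {"proportions": props.to_dict(orient="records")}
        if len(models) == 2:
            bundle["focus"]["model_comparisons"] = {
                level: compare_models_on_rating(
                    focus, models[0], models[1], level
                ).to_dict()
                for level in ("good", "poor")
            }
        correctness = {
            (f, m): bool(lbl == stage_of[f])
            for m in models
            for f, lbl in zip(table["frame_id"], table[m])
        }
        cells, tests = accuracy_by_focus(focus, correctness, stage_of)
        bundle["focus"]["accuracy_by_focus"] = [
            {
                "stage": c.stage,
                "model_id": c.model_id,
                "rating": c.rating,
                "n": c.n,
                "correct": c.correct,
                "proportion": c.proportion if c.n else None,
                "too_few": c.too_few,
            }
            for c in cells
        ]
        bundle["focus"]["accuracy_tests"] = [t.to_dict() for t in tests]

    bundle["runtime_seconds"] = round(time.perf_counter() - t0, 3)
    log.info("run complete in %.2fs", bundle["runtime_seconds"])
    return bundle


# ---------------------------------------------------------------------------
# report writing


def _md_kappa_table(records: dict, heading: str) -> list[str]:
    lines = [f"## {heading}", "",
             "| comparison | kappa | 95% CI | p |", "|---|---|---|---|"]
    for name, rec in records.items():
        if "error" in rec:
            lines.append(f"| {name} | — | — | {rec['error']} |")
            continue
        lines.append(
            f"| {name} | {rec['estimate']:.3f} "
            f"| {rec['ci_low']:.3f}–{rec['ci_high']:.3f} "
            f"| {rec['p_display']} |"
        )
    lines.append("")
    return lines


def write_report(bundle: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write ``report.json`` plus human-readable Markdown tables.

    JSON is written with sorted keys and no timestamps, so identical
    bundles serialise byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    # bundle runtime varies between runs; report content must not
    payload = {k: v for k, v in bundle.items() if k != "runtime_seconds"}
    json_path.write_text(
        json.dumps(_sanitize(payload), sort_keys=True, indent=2,
                   allow_nan=False, default=_json_default) + "\n"
    )

    lines = ["# Evaluation report", ""]
    prov = bundle["provenance"]
    lines += [
        f"- config hash: `{prov['config_hash']}`",
        f"- seed: {prov['seed']}",
        f"- version: {prov['version']}",
        "",
    ]
    if "accuracy" in bundle:
        lines += ["## Accuracy", "", "| rater | correct | total | % |",
                  "|---|---|---|---|"]
        for rater, rec in bundle["accuracy"].items():
            lines.append(
                f"| {rater} | {rec['correct']} | {rec['total']} "
                f"| {100 * rec['proportion']:.1f} |"
            )
        lines.append("")
    if "kappa_vs_reference" in bundle:
        lines += _md_kappa_table(
            bundle["kappa_vs_reference"], "Weighted kappa vs reference"
        )
    if "kappa_pairwise" in bundle:
        lines += _md_kappa_table(bundle["kappa_pairwise"], "Pairwise weighted kappa")
    if "iou" in bundle:
        lines += ["## IoU (Grad-CAM vs LIME)", "",
                  "| stage | model | n | median % | 95% CI |", "|---|---|---|---|---|"]
        for rec in bundle["iou"]["summary"]:
            ci = (
                f"{rec['ci_low']:.1f}–{rec['ci_high']:.1f}"
                if rec["ci_low"] == rec["ci_low"]  # not NaN
                else "n/a"
            )
            lines.append(
                f"| {rec['stage']} | {rec['model']} | {rec['n']} "
                f"| {rec['median_percent']:.1f} | {ci} |"
            )
        lines.append("")
    md_path = out / "report.md"
    md_path.write_text("\n".join(lines))

    paths = {"json": json_path, "markdown": md_path}
    return paths


def _sanitize(obj):
    """Recursively replace NaN/inf with None so JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not math.isfinite(obj):
        return None
    return obj


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
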