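"""Embryologist spatial-focus ratings of heatmap explanations.

Each Grad-CAM explanation is rated "good" (high-relevance areas fall on
biologically relevant structures), "intermediate" (mixed) or "poor" (no
relevant structures highlighted). This module aggregates those ratings into
per-model and per-stage proportions, compares models on a rating level, and
crosses ratings with classification correctness — the question being
whether "good-looking" explanations actually mark frames the model gets
right.

All hypothesis tests delegate to :mod:`embryoeval.agreement` so every
statistic has a single implementation.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

from .agreement import TestResult, chi_square_proportions
from .exceptions import DataError, InsufficientDataError, ParameterError

__all__ = [
    "RATING_LEVELS",
    "FocusAccuracyCell",
    "consensus_ratings",
    "rating_proportions",
    "compare_models_on_rating",
    "accuracy_by_focus",
]

RATING_LEVELS = ("good", "intermediate", "poor")

#: Below this many frames a cell is flagged "too few instances" and
#: excluded from between-group testing.
MIN_CELL_N = 5


@dataclass(frozen=True)
class FocusAccuracyCell:
    stage: int
    model_id: str
    rating: str
    n: int
    correct: int
    too_few: bool

    @property
    def proportion(self) -> float:
        return self.correct / self.n if self.n else float("nan")


def _validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    required = {"frame_id", "model_id", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ParameterError(f"ratings table missing columns: {sorted(missing)}")
    bad = set(ratings["rating"]) - set(RATING_LEVELS)
    if bad:
        raise DataError(f"unknown rating levels: {sorted(bad)}")
    return ratings


def consensus_ratings(
    per_rater: pd.DataFrame, tie_break: str = "intermediate"
) -> pd.DataFrame:
    """Collapse per-rater ratings to one consensus rating per (frame, model).

    ``per_rater`` needs columns ``frame_id, model_id, rater_id, rating``.
    Majority vote; ties resolve to ``tie_break`` (default "intermediate",
    the natural middle of the 3-level scale).
    """
    required = {"frame_id", "model_id", "rater_id", "rating"}
    missing = required - set(per_rater.columns)
    if missing:
        raise ParameterError(f"per-rater table missing columns: {sorted(missing)}")
    if tie_break not in RATING_LEVELS:
        raise ParameterError(f"tie_break must be one of {RATING_LEVELS}")

    def vote(group: pd.Series) -> str:
        counts = group.value_counts()
        top = counts[counts == counts.max()]
        if len(top) > 1:
            return tie_break
        return str(top.index[0])

    out = (
        per_rater.groupby(["frame_id", "model_id"])["rating"]
        .apply(vote)
        .reset_index()
    )
    return _validate_ratings(out)


def rating_proportions(
    ratings: pd.DataFrame, stages: Mapping[str, int]
) -> pd.DataFrame:
    """Proportion of each rating level per model x stage, plus overall rows.

    ``stages`` maps frame_id -> stage code. Overall rows carry stage 0.
    Proportions over the three levels sum to 1 within each model x stage.
    """
    ratings = _validate_ratings(ratings)
    unmapped = [f for f in ratings["frame_id"].unique() if f not in stages]
    if unmapped:
        raise DataError(f"frames without a stage: {sorted(unmapped)[:5]}")
    df = ratings.copy()
    df["stage"] = df["frame_id"].map(stages).astype(int)
    rows = []
    for (model, stage), grp in df.groupby(["model_id", "stage"]):
        n = len(grp)
        for level in RATING_LEVELS:
            rows.append(
                {
                    "model_id": model,
                    "stage": int(stage),
                    "rating": level,
                    "n": n,
                    "count": int((grp["rating"] == level).sum()),
                }
            )
    for model, grp in df.groupby("model_id"):
        n = len(grp)
        for level in RATING_LEVELS:
            rows.append(
                {
                    "model_id": model,
                    "stage": 0,
                    "rating": level,
                    "n": n,
                    "count": int((grp["rating"] == level).sum()),
                }
            )
    out = pd.DataFrame(rows)
    out["proportion"] = out["count"] / out["n"]
    return out


def compare_models_on_rating(
    ratings: pd.DataFrame,
    model_a: str,
    model_b: str,
    rating_level: str,
    stages: Mapping[str, int] | None = None,
    stage: int | None = None,
) -> TestResult:
    """2x2 test of one rating level's proportion between two models.

    Counts frames rated ``rating_level`` vs not, per model, optionally
    restricted to one stage, and delegates to
    :func:`embryoeval.agreement.chi_square_proportions` (Fisher fallback
    when expected counts are small).
    """
    ratings = _validate_ratings(ratings)
    if rating_level not in RATING_LEVELS:
        raise ParameterError(f"unknown rating level {rating_level!r}")
    df = ratings
    if stage is not None:
        if stages is None:
            raise ParameterError("stage filtering requires a frame -> stage map")
        keep = df["frame_id"].map(lambda f: stages.get(f) == stage)
        df = df[keep]
    counts = {}
    for model in (model_a, model_b):
        sub = df[df["model_id"] == model]
        if len(sub) == 0:
            raise InsufficientDataError(f"no ratings for model {model!r}")
        counts[model] = (int((sub["rating"] == rating_level).sum()), len(sub))
    return chi_square_proportions(counts[model_a], counts[model_b])


def accuracy_by_focus(
    ratings: pd.DataFrame,
    correctness: Mapping[tuple[str, str], bool],
    stages: Mapping[str, int],
    min_cell_n: int = MIN_CELL_N,
) -> tuple[list[FocusAccuracyCell], list[TestResult]]:
    """Classification accuracy within each stage x model x rating cell.

    ``correctness`` maps (frame_id, model_id) -> whether the model
    classified the frame correctly. Cells with fewer than ``min_cell_n``
    frames are flagged ``too_few`` and excluded from the pairwise
    rating-group comparisons (chi-squared / Fisher via agreement_stats).
    """
    ratings = _validate_ratings(ratings)
    df = ratings.copy()
    missing = [
        (f, m)
        for f, m in zip(df["frame_id"], df["model_id"])
        if (f, m) not in correctness
    ]
    if missing:
        raise DataError(f"correctness missing for pairs: {missing[:5]}")
    unmapped = [f for f in df["frame_id"].unique() if f not in stages]
    if unmapped:
        raise DataError(f"frames without a stage: {sorted(unmapped)[:5]}")
    df["stage"] = df["frame_id"].map(stages).astype(int)
    df["correct"] = [
        bool(correctness[(f, m)]) for f, m in zip(df["frame_id"], df["model_id"])
    ]

    cells: list[FocusAccuracyCell] = []
    tests: list[TestResult] = []
    for (stage, model), grp in df.groupby(["stage", "model_id"]):
        by_rating = {}
        for level in RATING_LEVELS:
            sub = grp[grp["rating"] == level]
            n = len(sub)
            cell = FocusAccuracyCell(
                stage=int(stage),
                model_id=str(model),
                rating=level,
                n=n,
                correct=int(sub["correct"].sum()),
                too_few=n < min_cell_n,
            )
            cells.append(cell)
            by_rating[level] = cell
        for i, lvl_a in enumerate(RATING_LEVELS):
            for lvl_b in RATING_LEVELS[i + 1:]:
                ca, cb = by_rating[lvl_a], by_rating[lvl_b]
                if ca.too_few or cb.too_few:
                    continue
                res = chi_square_proportions((ca.correct, ca.n), (cb.correct, cb.n))
                res.extras.update(
                    {"stage": int(stage), "model_id": str(model),
                     "ratings": (lvl_a, lvl_b)}
                )
                tests.append(res)
    return cells, tests
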