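"""Accuracy and inter-rater agreement statistics for ordinal stage labels.

The battery mirrors how classifier-vs-expert comparisons are reported for
ordinal clinical gradings:

* pooled and per-stage classification **accuracy** against a reference
  standard, with 7x7 **confusion matrices**;
* **quadratic-weighted Cohen's kappa** between any two raters (or a rater
  and the reference), with large-sample standard error, Wald 95% CI and a
  p-value for H0: kappa = 0;
* **Fleiss' kappa** for three or more raters;
* **Cochran's Q** on the frames x raters correctness grid, with
  **McNemar** post-hoc pairwise tests under Holm step-down adjustment;
* two-sample **chi-squared** proportion comparisons (Fisher fallback) and
  the **Wilcoxon matched-pairs signed-rank** test.

Quadratic weights use the full 7-level coding, ``w_ij = 1 - (i-j)^2 / 36``,
even on subgroup tables that do not exhibit all categories, so stage-wise
kappas are comparable across stages (and may be negative).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateTableError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
)
from .stages import ALL_CODES, N_STAGES, encode_stage

__all__ = [
    "AccuracyResult",
    "ConfusionMatrix",
    "KappaResult",
    "TestResult",
    "accuracy",
    "confusion",
    "weighted_kappa",
    "cohen_weighted_kappa",
    "fleiss_kappa",
    "correctness_grid",
    "cochran_q",
    "mcnemar_pair",
    "mcnemar_pairwise",
    "holm_adjust",
    "chi_square_proportions",
    "wilcoxon_signed_rank",
]

REFERENCE = "reference"


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class AccuracyResult:
    correct: int
    total: int
    by_stage: dict[int, tuple[int, int, float]]

    @property
    def proportion(self) -> float:
        return self.correct / self.total

    def to_dict(self) -> dict:
        return {
            "correct": self.correct,
            "total": self.total,
            "proportion": self.proportion,
            "by_stage": {
                str(s): {"correct": c, "total": t, "proportion": p}
                for s, (c, t, p) in self.by_stage.items()
            },
        }


@dataclass(frozen=True)
class ConfusionMatrix:
    """7x7 confusion counts; rows index the reference stage, columns the
    predicted stage. ``display_percent`` rounds half-up to whole percent for
    heatmap-style display while ``row_proportions`` keeps full precision."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_STAGES, N_STAGES) or (c < 0).any():
            raise ParameterError("confusion counts must be a non-negative 7x7 grid")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_proportions(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / rows
        return np.where(rows > 0, out, 0.0)

    @property
    def display_percent(self) -> np.ndarray:
        # round-half-up, not banker's rounding
        return np.floor(self.row_proportions * 100.0 + 0.5).astype(int)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


@dataclass(frozen=True)
class KappaResult:
    estimate: float
    standard_error: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "standard_error": self.standard_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "method": self.method,
            "n": self.n,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "extras": {k: v for k, v in self.extras.items()},
        }


def format_p(p: float) -> str:
    """Report-style p-value rendering; values below 1e-3 print as '<0.001'."""
    return "<0.001" if p < 1e-3 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# accuracy and confusion


def _rater_columns(table: pd.DataFrame, rater_ids: str | Sequence[str]) -> list[str]:
    if isinstance(rater_ids, str):
        rater_ids = [rater_ids]
    rater_ids = list(rater_ids)
    missing = [r for r in rater_ids if r not in table.columns]
    if missing:
        raise ParameterError(f"raters not present in table: {missing}")
    return rater_ids


def accuracy(table: pd.DataFrame, rater_ids: str | Sequence[str]) -> AccuracyResult:
    """Pooled classification accuracy of one or more raters vs the reference.

    Each rater x frame pair is one trial; e.g. three raters on 245 frames
    give 735 trials. ``by_stage`` breaks trials down by reference stage.
    """
    raters = _rater_columns(table, rater_ids)
    if len(table) == 0:
        raise EmptyInputError("rating table has no rows")
    ref = table[REFERENCE].to_numpy()
    by_stage: dict[int, tuple[int, int, float]] = {}
    correct_total = 0
    for s in ALL_CODES:
        mask = ref == s
        t = int(mask.sum()) * len(raters)
        c = int(sum((table.loc[mask, r].to_numpy() == s).sum() for r in raters))
        correct_total += c
        by_stage[s] = (c, t, c / t if t else float("nan"))
    total = len(table) * len(raters)
    return AccuracyResult(correct=correct_total, total=total, by_stage=by_stage)


def confusion(table: pd.DataFrame, rater_id: str | Sequence[str]) -> ConfusionMatrix:
    """Confusion counts for one rater (or pooled over several) vs reference."""
    raters = _rater_columns(table, rater_id)
    if len(table) == 0:
        raise EmptyInputError("rating table has no rows")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=int)
    ref = table[REFERENCE].to_numpy()
    for r in raters:
        pred = table[r].to_numpy()
        np.add.at(counts, (ref - 1, pred - 1), 1)
    return ConfusionMatrix(counts=counts)


# ---------------------------------------------------------------------------
# Cohen's weighted kappa


def _weights(categories: np.ndarray, weighting: str) -> np.ndarray:
    k = categories.size
    if weighting == "unweighted":
        return np.eye(k)
    if weighting == "quadratic":
        if k < 2:
            raise DegenerateTableError("weighted kappa needs >= 2 categories")
        d = categories[:, None] - categories[None, :]
        span = categories.max() - categories.min()
        return 1.0 - (d / span) ** 2
    raise ParameterError(f"unknown weighting {weighting!r}")


def weighted_kappa(
    labels_a: Sequence[int],
    labels_b: Sequence[int],
    weighting: str = "quadratic",
    categories: Sequence[int] | None = None,
) -> KappaResult:
    """Cohen's (weighted) kappa between two label vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with weighted observed agreement
    ``p_o = sum w_ij p_ij`` and chance agreement ``p_e = sum w_ij p_i. p_.j``.
    Quadratic weights are ``w_ij = 1 - (i - j)^2 / (K - 1)^2`` over the
    category coding; by default the categories are the distinct observed
    labels, but an explicit full coding (e.g. 1..7) can be supplied so that
    subgroup tables remain on a common scale.

    The CI uses the large-sample (Fleiss-Cohen-Everitt) standard error and a
    Wald interval clipped to [-1, 1]; the p-value tests H0: kappa = 0 using
    the null-variance form of the same expansion.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("label vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise InsufficientDataError("kappa needs at least 2 frames")
    if categories is None:
        cats = np.unique(np.concatenate([a, b]))
    else:
        cats = np.asarray(sorted(set(int(c) for c in categories)))
        if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
            raise ParameterError("labels outside the supplied category set")
    if np.unique(np.concatenate([a, b])).size < 2:
        raise DegenerateTableError(
            "fewer than 2 distinct categories observed across both raters"
        )
    index = {c: i for i, c in enumerate(cats)}
    k = cats.size
    counts = np.zeros((k, k))
    ia = np.vectorize(index.get)(a)
    ib = np.vectorize(index.get)(b)
    np.add.at(counts, (ia, ib), 1)
    p = counts / n
    w = _weights(cats.astype(float), weighting)

    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e == 1.0:
        raise DegenerateTableError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # expected weights of each row/column under the marginals
    wbar_row = w @ col       # wbar_i. = sum_j p_.j w_ij
    wbar_col = row @ w       # wbar_.j = sum_i p_i. w_ij
    cross = wbar_row[:, None] + wbar_col[None, :]

    # Fleiss-Cohen-Everitt large-sample variance (for the CI)
    if p_o == 1.0:
        se1 = 0.0  # perfect agreement: the variance expansion is exactly 0
    else:
        term = (w * (1.0 - p_e) - cross * (1.0 - p_o)) ** 2
        var1 = ((p * term).sum() - (p_o * p_e - 2.0 * p_e + p_o) ** 2) / (
            n * (1.0 - p_e) ** 4
        )
        se1 = math.sqrt(max(var1, 0.0))

    # null (kappa = 0) variance for the significance test
    var0 = ((np.outer(row, col) * (w - cross) ** 2).sum() - p_e**2) / (
        n * (1.0 - p_e) ** 2
    )
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        z = kappa / se0
        p_value = 2.0 * stats.norm.sf(abs(z))
    else:
        p_value = 1.0 if kappa == 0 else 0.0

    half = 1.959963984540054 * se1
    return KappaResult(
        estimate=float(kappa),
        standard_error=se1,
        ci_low=max(-1.0, kappa - half),
        ci_high=min(1.0, kappa + half),
        p_value=float(p_value),
        method=f"cohen_{weighting}",
        n=n,
        extras={"p_o": p_o, "p_e": p_e, "se_null": se0},
    )


def cohen_weighted_kappa(
    table: pd.DataFrame,
    rater_a: str,
    rater_b: str,
    weighting: str = "quadratic",
    subgroup_stage: int | None = None,
) -> KappaResult:
    """Weighted kappa between two raters of a rating table.

    Either rater may be ``"reference"``.  ``subgroup_stage`` restricts the
    rows to frames whose *reference* stage equals the given code while the
    raters' labels stay on the full 1..7 coding — this is what allows
    stage-specific kappas to go negative when raters disagree on where a
    stage's frames belong.
    """
    _rater_columns(table, [rater_a, rater_b])
    sub = table
    if subgroup_stage is not None:
        code = encode_stage(subgroup_stage)
        sub = table[table[REFERENCE] == code]
        if len(sub) < 2:
            raise InsufficientDataError(
                f"subgroup stage {code} has {len(sub)} rows; need >= 2"
            )
    return weighted_kappa(
        sub[rater_a].to_numpy(),
        sub[rater_b].to_numpy(),
        weighting=weighting,
        categories=ALL_CODES,
    )


# ---------------------------------------------------------------------------
# Fleiss' kappa


def fleiss_kappa(
    table: pd.DataFrame,
    rater_ids: Sequence[str],
    subgroup_stage: int | None = None,
) -> KappaResult:
    """Fleiss' multirater kappa over the 7 stage categories.

    Requires at least 3 raters (use Cohen's kappa for two). The standard
    error is the large-sample null form of Fleiss (1971), with a Wald 95%
    interval clipped to [-1, 1].
    """
    raters = _rater_columns(table, rater_ids)
    if len(raters) < 3:
        raise ParameterError("fleiss_kappa needs >= 3 raters; use Cohen's kappa for 2")
    sub = table
    if subgroup_stage is not None:
        code = encode_stage(subgroup_stage)
        sub = table[table[REFERENCE] == code]
    if len(sub) < 2:
        raise InsufficientDataError("fewer than 2 frames for Fleiss' kappa")
    labels = sub[list(raters)].to_numpy(dtype=int)
    n_items, n_raters = labels.shape
    counts = np.zeros((n_items, N_STAGES))
    for j in range(N_STAGES):
        counts[:, j] = (labels == j + 1).sum(axis=1)
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    p_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())
    q_j = 1.0 - p_j
    spq = float((p_j * q_j).sum())
    if spq == 0.0:
        raise DegenerateTableError(
            "all raters assigned a single category to every frame; kappa undefined"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    var = (
        2.0
        * (spq**2 - float((p_j * q_j * (q_j - p_j)).sum()))
        / (n_items * n_raters * (n_raters - 1) * spq**2)
    )
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        p_value = 2.0 * stats.norm.sf(abs(kappa) / se)
    else:
        p_value = 1.0 if kappa == 0 else 0.0
    half = 1.959963984540054 * se
    return KappaResult(
        estimate=float(kappa),
        standard_error=se,
        ci_low=max(-1.0, kappa - half),
        ci_high=min(1.0, kappa + half),
        p_value=float(p_value),
        method="fleiss",
        n=n_items,
        extras={"n_raters": n_raters, "p_bar": p_bar, "p_e": p_e},
    )


# ---------------------------------------------------------------------------
# correctness-grid tests: Cochran's Q and McNemar post-hocs


def correctness_grid(table: pd.DataFrame, rater_ids: Sequence[str]) -> pd.DataFrame:
    """frames x raters boolean grid of agreement with the reference."""
    raters = _rater_columns(table, rater_ids)
    ref = table[REFERENCE].to_numpy()
    data = {r: table[r].to_numpy() == ref for r in raters}
    return pd.DataFrame(data, index=table.index)


def cochran_q(grid: pd.DataFrame | np.ndarray) -> TestResult:
    """Cochran's Q for equality of correct-classification rates.

    ``grid`` is frames x raters boolean. Frames on which every rater agrees
    (all correct or all wrong) carry no information and drop out of the
    statistic. A grid that is constant overall leaves Q undefined.
    """
    x = np.asarray(grid, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ParameterError("correctness grid must be frames x raters with >= 2 of each")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ParameterError("correctness grid must be boolean")
    n, k = x.shape
    if x.min() == x.max():
        raise DegenerateTableError("constant correctness grid; Q undefined")
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - (row**2).sum()
    if denom == 0:
        # every frame is unanimous (mix of all-correct and all-wrong rows):
        # no within-frame discordance, no evidence of rate differences
        return TestResult(0.0, k - 1, 1.0, "cochran_q", {"n_frames": n})
    q = (k - 1) * (k * (col**2).sum() - col.sum() ** 2) / denom
    p = float(stats.chi2.sf(q, k - 1))
    return TestResult(float(q), k - 1, p, "cochran_q", {"n_frames": n})


def mcnemar_pair(a: np.ndarray, b: np.ndarray, exact_threshold: int = 25) -> TestResult:
    """McNemar's test on two paired boolean correctness vectors.

    Uses the exact two-sided binomial test when the number of discordant
    pairs is below ``exact_threshold``, otherwise the continuity-corrected
    chi-squared form. Zero discordant pairs give p = 1 with a flag.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    disc = n10 + n01
    extras: dict = {"b": n10, "c": n01, "discordant": disc}
    if disc == 0:
        extras["zero_discordant"] = True
        return TestResult(0.0, None, 1.0, "mcnemar_exact", extras)
    if disc < exact_threshold:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(n10, n01), disc, 0.5)))
        return TestResult(float(min(n10, n01)), None, p, "mcnemar_exact", extras)
    stat = (abs(n10 - n01) - 1.0) ** 2 / disc
    p = float(stats.chi2.sf(stat, 1))
    return TestResult(float(stat), 1, p, "mcnemar_chi2", extras)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def mcnemar_pairwise(
    grid: pd.DataFrame,
    adjust: str = "holm",
    exact_threshold: int = 25,
) -> list[TestResult]:
    """All pairwise McNemar tests over a correctness grid, Holm-adjusted.

    One test per rater pair; the Holm family is the full set of pairs in
    this call (e.g. 10 pairs for 5 raters).
    """
    if grid.shape[1] < 2:
        raise ParameterError("need >= 2 raters for pairwise McNemar tests")
    if adjust not in ("holm", "none"):
        raise ParameterError(f"unknown adjustment {adjust!r}")
    raters = list(grid.columns)
    results: list[TestResult] = []
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            res = mcnemar_pair(
                grid[raters[i]].to_numpy(),
                grid[raters[j]].to_numpy(),
                exact_threshold=exact_threshold,
            )
            res.extras["pair"] = (raters[i], raters[j])
            results.append(res)
    if adjust == "holm":
        adjusted = holm_adjust([r.p_value for r in results])
        for res, p_adj in zip(results, adjusted):
            res.extras["p_holm"] = float(p_adj)
    return results


# ---------------------------------------------------------------------------
# proportion and paired-sample tests


def chi_square_proportions(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> TestResult:
    """Compare two binomial proportions via a 2x2 chi-squared test.

    ``counts_x = (hits, n)``. Falls back to Fisher's exact test when any
    expected cell count is below 5 (flagged in ``extras``).
    """
    (h1, n1), (h2, n2) = counts_a, counts_b
    for h, n in ((h1, n1), (h2, n2)):
        if n <= 0:
            raise ParameterError("group size n must be > 0")
        if not (0 <= h <= n):
            raise ParameterError(f"hits {h} outside 0..{n}")
    table = np.array([[h1, n1 - h1], [h2, n2 - h2]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    # exact test whenever the chi-squared approximation is unreliable:
    # small expected counts or an empty observed cell
    if (expected < 5).any() or (table == 0).any():
        odds, p = stats.fisher_exact(table)
        return TestResult(
            float(odds),
            None,
            float(p),
            "fisher_exact",
            {"fallback": True, "min_expected": float(expected.min())},
        )
    if table[0].tolist() == table[1].tolist():
        # identical rows: statistic is exactly 0 by symmetry
        return TestResult(0.0, 1, 1.0, "chi_square", {"fallback": False})
    res = stats.chi2_contingency(table, correction=True)
    return TestResult(
        float(res.statistic),
        1,
        float(res.pvalue),
        "chi_square",
        {"fallback": False, "min_expected": float(expected.min())},
    )


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on two paired samples.

    Zero differences are dropped; tied absolute differences are mid-ranked.
    ``extras['W']`` carries the signed-rank sum W = R+ - R- and
    ``extras['median_difference']`` the median of a - b. The p-value is the
    exact two-sided tail when the post-zero sample size is <= 25 and the
    absolute differences are tie-free, otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired samples must be 1-D and equal length")
    if a.size < 1:
        raise ParameterError("paired samples must be non-empty")
    d = a - b
    median_diff = float(np.median(d))
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(
            0.0, None, 1.0, "wilcoxon_signed_rank",
            {"W": 0.0, "median_difference": median_diff, "all_zero": True},
        )
    ranks = stats.rankdata(np.abs(nz))
    w_signed = float((np.sign(nz) * ranks).sum())
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=False, alternative="two-sided",
        method=method,
    )
    return TestResult(
        w_signed,
        None,
        float(res.pvalue),
        "wilcoxon_signed_rank",
        {
            "W": w_signed,
            "median_difference": median_diff,
            "n_nonzero": int(nz.size),
            "mode": method,
        },
    )
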