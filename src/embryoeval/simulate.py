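"""Synthetic rater tables with a stage-dependent ordinal confusion structure.

Real per-frame stage annotations by embryologists and CNN classifiers are
not publicly deposited, so downstream statistics are exercised on simulated
tables whose generative model mirrors the dominant empirical error pattern:
misclassifications concentrate on ordinally *adjacent* stages.

Each simulated rater is described by a :class:`RaterProfile` — a per-stage
probability ``a_s`` of labelling a frame of true stage *s* correctly, and a
geometric adjacency decay ``rho``: conditional on an error at true stage
*s*, the probability of assigning stage ``j != s`` is proportional to
``rho ** (|j - s| - 1)``.  As ``rho -> 0`` all errors land on the nearest
neighbouring stages; ``rho = 1`` spreads errors uniformly.

Because the full conditional confusion matrix of every profile is available
in closed form (:meth:`RaterProfile.confusion_matrix`), the chance-corrected
agreement between any two independent simulated raters has an analytic
value (:func:`expected_weighted_kappa`) against which the empirical
estimator can be validated.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ParameterError
from .stages import ALL_CODES, N_STAGES

__all__ = [
    "RaterProfile",
    "uniform_profile",
    "simulate_rating_table",
    "joint_label_distribution",
    "expected_weighted_kappa",
]


@dataclass(frozen=True)
class RaterProfile:
    """Stochastic labelling behaviour of one simulated rater.

    Parameters
    ----------
    rater_id : str
        Column name in the generated table.
    per_stage_accuracy : mapping of stage code -> float
        ``a_s``, the probability of a correct label at true stage ``s``.
        Must cover all 7 merged stage codes with values in [0, 1].
    adjacency_decay : float
        ``rho`` in (0, 1]; geometric decay of error mass with ordinal
        distance. Small values concentrate errors on adjacent stages.
    """

    rater_id: str
    per_stage_accuracy: Mapping[int, float] = field(default_factory=dict)
    adjacency_decay: float = 0.25

    def __post_init__(self) -> None:
        acc = dict(self.per_stage_accuracy)
        missing = [s for s in ALL_CODES if s not in acc]
        if missing:
            raise ParameterError(
                f"profile {self.rater_id!r}: per_stage_accuracy missing stages {missing}"
            )
        for s, a in acc.items():
            if not (0.0 <= float(a) <= 1.0):
                raise ParameterError(
                    f"profile {self.rater_id!r}: accuracy a_{s}={a} outside [0, 1]"
                )
        if not (0.0 < float(self.adjacency_decay) <= 1.0):
            raise ParameterError(
                f"profile {self.rater_id!r}: adjacency_decay {self.adjacency_decay} "
                "outside (0, 1]"
            )
        object.__setattr__(self, "per_stage_accuracy", acc)

    def confusion_row(self, true_stage: int) -> np.ndarray:
        """Conditional label distribution ``P(assigned = j | true = s)``.

        Length-7 vector over codes 1..7: mass ``a_s`` on the true stage and
        the complement distributed over the other stages with geometric
        decay in ordinal distance.
        """
        s = int(true_stage)
        a = float(self.per_stage_accuracy[s])
        rho = float(self.adjacency_decay)
        row = np.zeros(N_STAGES)
        codes = np.asarray(ALL_CODES)
        off = codes != s
        weights = rho ** (np.abs(codes[off] - s) - 1.0)
        row[off] = (1.0 - a) * weights / weights.sum()
        row[s - 1] = a
        return row

    def confusion_matrix(self) -> np.ndarray:
        """7x7 matrix of conditional rows, indexed [true-1, assigned-1]."""
        return np.vstack([self.confusion_row(s) for s in ALL_CODES])


def uniform_profile(rater_id: str, accuracy: float, adjacency_decay: float = 0.25) -> RaterProfile:
    """Profile with the same accuracy ``a_s = accuracy`` at every stage."""
    return RaterProfile(
        rater_id=rater_id,
        per_stage_accuracy={s: accuracy for s in ALL_CODES},
        adjacency_decay=adjacency_decay,
    )


def _normalise_frames_per_stage(frames_per_stage: int | Mapping[int, int]) -> dict[int, int]:
    if isinstance(frames_per_stage, int):
        counts = {s: frames_per_stage for s in ALL_CODES}
    else:
        counts = {int(s): int(c) for s, c in frames_per_stage.items()}
        unknown = [s for s in counts if s not in ALL_CODES]
        if unknown:
            raise ParameterError(f"frames_per_stage has unknown stage codes {unknown}")
        for s in ALL_CODES:
            counts.setdefault(s, 0)
    if any(c < 0 for c in counts.values()):
        raise ParameterError("frames_per_stage counts must be >= 0")
    return counts


def simulate_rating_table(
    n_embryos: int,
    frames_per_stage: int | Mapping[int, int],
    profiles: Sequence[RaterProfile],
    seed: int,
) -> pd.DataFrame:
    """Simulate a per-frame rating table for a panel of raters.

    Returns a DataFrame with columns ``embryo_id``, ``frame_id``,
    ``reference`` (true stage code 1..7) and one column per rater holding
    that rater's assigned code. Reference stages follow ``frames_per_stage``
    exactly; frames are distributed round-robin over embryos. Identical
    inputs and seed give an identical table.
    """
    if n_embryos < 1:
        raise ParameterError("n_embryos must be >= 1")
    if not profiles:
        raise ParameterError("at least one RaterProfile is required")
    ids = [p.rater_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"duplicate rater ids in profiles: {ids}")
    counts = _normalise_frames_per_stage(frames_per_stage)
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("frames_per_stage sums to zero frames")

    reference = np.concatenate([np.full(counts[s], s, dtype=int) for s in ALL_CODES])
    n = reference.size
    embryo_id = [f"embryo_{(i % n_embryos) + 1:03d}" for i in range(n)]
    frame_id = [f"frame_{i + 1:04d}" for i in range(n)]

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {"embryo_id": embryo_id, "frame_id": frame_id, "reference": reference}
    )
    for profile in profiles:
        labels = np.empty(n, dtype=int)
        # draw stage-blocks at once; reference is sorted by construction
        for s in ALL_CODES:
            idx = np.flatnonzero(reference == s)
            if idx.size:
                labels[idx] = rng.choice(
                    np.asarray(ALL_CODES), size=idx.size, p=profile.confusion_row(s)
                )
        table[profile.rater_id] = labels
    return table


def joint_label_distribution(
    profile_a: RaterProfile,
    profile_b: RaterProfile,
    prevalence: Sequence[float] | None = None,
) -> np.ndarray:
    """Joint cell probabilities P(a=i, b=j) for two independent raters.

    ``P(i, j) = sum_s pi_s * Ca[s, i] * Cb[s, j]`` where ``pi`` is the stage
    prevalence (uniform by default) and ``C`` the profiles' conditional
    confusion matrices. Raters are conditionally independent given the true
    stage, matching the sampling scheme of :func:`simulate_rating_table`.
    """
    if prevalence is None:
        pi = np.full(N_STAGES, 1.0 / N_STAGES)
    else:
        pi = np.asarray(prevalence, dtype=float)
        if pi.shape != (N_STAGES,) or np.any(pi < 0):
            raise ParameterError("prevalence must be 7 non-negative values")
        if not np.isclose(pi.sum(), 1.0):
            raise ParameterError("prevalence must sum to 1")
    ca = profile_a.confusion_matrix()
    cb = profile_b.confusion_matrix()
    return np.einsum("s,si,sj->ij", pi, ca, cb)


def expected_weighted_kappa(
    profile_a: RaterProfile,
    profile_b: RaterProfile,
    prevalence: Sequence[float] | None = None,
    weighting: str = "quadratic",
) -> float:
    """Closed-form quadratic-weighted kappa between two simulated raters.

    Evaluates the population value of Cohen's weighted kappa directly on the
    analytic joint distribution from :func:`joint_label_distribution` — the
    oracle against which empirical estimates on large simulated tables are
    checked.
    """
    p = joint_label_distribution(profile_a, profile_b, prevalence)
    i = np.arange(1, N_STAGES + 1)
    if weighting == "quadratic":
        w = 1.0 - (i[:, None] - i[None, :]) ** 2 / (N_STAGES - 1) ** 2
    elif weighting == "unweighted":
        w = (i[:, None] == i[None, :]).astype(float)
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    return (p_o - p_e) / (1.0 - p_e)
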