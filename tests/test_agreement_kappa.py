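import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import inter_rater

import oracles
from embryoeval import (
    accuracy,
    cohen_weighted_kappa,
    confusion,
    fleiss_kappa,
    weighted_kappa,
)
from embryoeval.exceptions import (
    DegenerateTableError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
)
from conftest import random_rating_table


class TestAccuracyAndConfusion:
    def test_accuracy_pools_rater_frame_trials(self, small_table):
        res = accuracy(small_table, ["perfect", "noisy"])
        assert res.total == 16
        assert res.correct == 14
        assert res.proportion == pytest.approx(14 / 16)

    def test_perfect_rater_is_exact_everywhere(self, small_table):
        res = accuracy(small_table, "perfect")
        assert res.proportion == 1.0
        assert all(p == 1.0 for _, _, p in res.by_stage.values() if p == p)

    def test_by_stage_counts_sum_to_overall(self, small_table):
        res = accuracy(small_table, "noisy")
        assert sum(c for c, _, _ in res.by_stage.values()) == res.correct
        assert sum(t for _, t, _ in res.by_stage.values()) == res.total

    def test_confusion_counts_and_proportions(self, small_table):
        cm = confusion(small_table, "noisy")
        assert cm.total == 8
        assert cm.counts[1, 2] == 1  # reference 2 rated 3
        assert cm.counts[3, 2] == 1  # reference 4 rated 3
        # 3 frames of stage 2 rated (2, 3, 3) -> proportions 1/3, 2/3
        import pandas as pd

        t = pd.DataFrame(
            {
                "embryo_id": list("aaa"),
                "frame_id": list("xyz"),
                "reference": [2, 2, 2],
                "r": [2, 3, 3],
            }
        )
        cm2 = confusion(t, "r")
        assert cm2.row_proportions[1, 1] == pytest.approx(1 / 3)
        assert cm2.row_proportions[1, 2] == pytest.approx(2 / 3)
        # display rounds half-up: 33 and 67
        assert cm2.display_percent[1, 1] == 33
        assert cm2.display_percent[1, 2] == 67

    def test_accuracy_equals_confusion_trace(self, rng):
        table = random_rating_table(rng, 40, ["r1"])
        acc = accuracy(table, "r1")
        cm = confusion(table, "r1")
        assert acc.proportion == pytest.approx(cm.overall_accuracy)

    def test_empty_table_raises(self, small_table):
        with pytest.raises(EmptyInputError):
            accuracy(small_table.iloc[:0], "perfect")

    def test_missing_rater_raises(self, small_table):
        with pytest.raises(ParameterError):
            accuracy(small_table, "ghost")


class TestCohenWeightedKappa:
    def test_identical_raters_give_exactly_one(self, small_table):
        res = cohen_weighted_kappa(small_table, "perfect", "reference")
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low == res.ci_high == 1.0

    def test_two_category_hand_example(self):
        # p_o = 3/4, p_e = 1/2 -> kappa = 0.5; quadratic == unweighted for
        # a two-category coding
        res = weighted_kappa([1, 1, 2, 2], [1, 2, 2, 2], categories=(1, 2))
        assert res.estimate == pytest.approx(0.5)
        resu = weighted_kappa(
            [1, 1, 2, 2], [1, 2, 2, 2], weighting="unweighted", categories=(1, 2)
        )
        assert resu.estimate == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_on_random_tables(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        a = rng.integers(1, 8, n)
        b = rng.integers(1, 8, n)
        if np.unique(np.concatenate([a, b])).size < 2:
            pytest.skip("degenerate draw")
        got = weighted_kappa(a, b, categories=range(1, 8)).estimate
        want = oracles.brute_weighted_kappa(a.tolist(), b.tolist(), range(1, 8))
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("weighting", ["quadratic", "unweighted"])
    def test_matches_sklearn(self, rng, weighting):
        a = rng.integers(1, 8, 200)
        b = rng.integers(1, 8, 200)
        got = weighted_kappa(a, b, weighting=weighting, categories=range(1, 8))
        want = cohen_kappa_score(
            a, b, labels=list(range(1, 8)),
            weights="quadratic" if weighting == "quadratic" else None,
        )
        assert got.estimate == pytest.approx(want, abs=1e-12)

    def test_reversal_invariance_of_quadratic_kappa(self, rng):
        a = rng.integers(1, 8, 80)
        b = rng.integers(1, 8, 80)
        k1 = weighted_kappa(a, b, categories=range(1, 8)).estimate
        k2 = weighted_kappa(8 - a, 8 - b, categories=range(1, 8)).estimate
        assert k1 == pytest.approx(k2, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_flipping_an_agreement_decreases_kappa(self, data):
        n = data.draw(st.integers(6, 20))
        a = np.array(data.draw(
            st.lists(st.integers(1, 7), min_size=n, max_size=n)))
        b = a.copy()
        # perturb some positions to disagreements
        n_flip = data.draw(st.integers(0, n // 3))
        for pos in range(n_flip):
            b[pos] = 1 + (b[pos] % 7)
        try:
            k_before = weighted_kappa(a, b, categories=range(1, 8)).estimate
        except DegenerateTableError:
            return  # constant labels carry no agreement information
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            return  # a constant rater pins kappa at 0 regardless of flips
        idx = data.draw(st.integers(0, n - 1))
        if a[idx] != b[idx]:
            return  # already a disagreement
        b2 = b.copy()
        b2[idx] = 1 + (b2[idx] % 7)
        k_after = weighted_kappa(a, b2, categories=range(1, 8)).estimate
        assert k_after < k_before

    def test_ci_brackets_estimate_and_is_clipped(self, rng):
        a = rng.integers(1, 8, 50)
        b = np.where(rng.random(50) < 0.8, a, rng.integers(1, 8, 50))
        res = weighted_kappa(a, b, categories=range(1, 8))
        assert -1.0 <= res.ci_low <= res.estimate <= res.ci_high <= 1.0
        assert res.standard_error >= 0
        assert 0 <= res.p_value <= 1

    def test_subgroup_filters_by_reference_stage(self, rng):
        table = random_rating_table(rng, 120, ["m1", "m2"])
        sub = table[table["reference"] == 3]
        want = weighted_kappa(
            sub["m1"].to_numpy(), sub["m2"].to_numpy(), categories=range(1, 8)
        ).estimate
        got = cohen_weighted_kappa(table, "m1", "m2", subgroup_stage=3).estimate
        assert got == pytest.approx(want)

    def test_subgroup_kappa_can_be_negative(self):
        import pandas as pd

        # within a single reference stage the raters systematically disagree
        t = pd.DataFrame(
            {
                "embryo_id": list("abcdef"),
                "frame_id": list("uvwxyz"),
                "reference": [2] * 6,
                "m1": [1, 1, 1, 3, 3, 3],
                "m2": [3, 3, 3, 1, 1, 1],
            }
        )
        res = cohen_weighted_kappa(t, "m1", "m2", subgroup_stage=2)
        assert res.estimate < 0

    def test_degenerate_single_category(self):
        with pytest.raises(DegenerateTableError):
            weighted_kappa([3, 3, 3], [3, 3, 3], categories=range(1, 8))

    def test_insufficient_subgroup_rows(self, small_table):
        with pytest.raises(InsufficientDataError):
            cohen_weighted_kappa(small_table, "perfect", "noisy", subgroup_stage=1)


class TestFleissKappa:
    def test_identical_raters_give_one(self, rng):
        table = random_rating_table(rng, 30, ["r1"])
        table["r2"] = table["r1"]
        table["r3"] = table["r1"]
        res = fleiss_kappa(table, ["r1", "r2", "r3"])
        assert res.estimate == pytest.approx(1.0)

    def test_single_category_everywhere_is_degenerate(self, rng):
        table = random_rating_table(rng, 20, [])
        for r in ("r1", "r2", "r3"):
            table[r] = 4
        with pytest.raises(DegenerateTableError):
            fleiss_kappa(table, ["r1", "r2", "r3"])

    def test_two_raters_rejected(self, small_table):
        with pytest.raises(ParameterError):
            fleiss_kappa(small_table, ["perfect", "noisy"])

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_on_random_tables(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(4, 11))
        table = random_rating_table(rng, n, ["r1", "r2", "r3"])
        labels = table[["r1", "r2", "r3"]].to_numpy().tolist()
        if len({x for row in labels for x in row}) < 2:
            pytest.skip("degenerate draw")
        got = fleiss_kappa(table, ["r1", "r2", "r3"]).estimate
        want = oracles.brute_fleiss_kappa(labels, range(1, 8))
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        table = random_rating_table(rng, 100, ["r1", "r2", "r3", "r4"])
        labels = table[["r1", "r2", "r3", "r4"]].to_numpy()
        counts, _ = inter_rater.aggregate_raters(labels)
        want = inter_rater.fleiss_kappa(counts, method="fleiss")
        got = fleiss_kappa(table, ["r1", "r2", "r3", "r4"]).estimate
        assert got == pytest.approx(want, abs=1e-12)
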