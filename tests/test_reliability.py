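"""Agreement/validity statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semacd.reliability import (
    KappaResult,
    ReliabilityError,
    change_score_correlation,
    icc_band,
    icc_oneway,
    kappa_band,
    pool_kappas,
    pooled_mean_difference,
    spearman_ci,
    weighted_kappa,
)


def brute_force_weighted_kappa(a, b, k, scheme):
    """Independent plain-loop evaluation over the explicit contingency table."""
    n = len(a)
    counts = [[0.0] * k for _ in range(k)]
    for x, y in zip(a, b):
        counts[x][y] += 1.0 / n
    row = [sum(counts[i][j] for j in range(k)) for i in range(k)]
    col = [sum(counts[i][j] for i in range(k)) for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1)
            if scheme == "quadratic":
                w = w**2
            num += w * counts[i][j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


class TestSpearman:
    def test_hand_computed_rank_formula(self):
        # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.ci_low <= res.rho <= res.ci_high
        assert res.meets_threshold

    def test_monotone_relabeling_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        assert spearman_ci(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman_ci(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_small_n_and_zero_variance_rejected(self):
        with pytest.raises(ReliabilityError, match="n >= 4"):
            spearman_ci([1, 2, 3], [1, 2, 3])
        with pytest.raises(ReliabilityError, match="zero variance"):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_missing_pairs_dropped_complete_case(self):
        x = [1, 2, 3, 4, 5, np.nan]
        y = [2, 1, 4, 3, 5, 7]
        assert spearman_ci(x, y).n == 5

    def test_fieller_variant_gives_valid_interval(self):
        res = spearman_ci([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], se_method="fieller")
        assert res.ci_low <= res.rho <= res.ci_high

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(0, 10), min_size=6, max_size=12).filter(
            lambda v: len(set(v)) > 1
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_invariant_to_strictly_increasing_transform(self, x, seed):
        rng = np.random.default_rng(seed)
        y = rng.permutation(len(x)).astype(float)
        x = np.asarray(x, dtype=float)
        base = spearman_ci(x, y).rho
        assert spearman_ci(np.exp(x / 3) + 5, y).rho == pytest.approx(base)


class TestIcc:
    def test_duplicated_reads_give_icc_one(self):
        t = pd.DataFrame(
            {"video_id": list(range(10)) * 2, "score": list(range(10)) * 2}
        )
        res = icc_oneway(t)
        assert res.icc == pytest.approx(1.0)
        assert res.variance_within == pytest.approx(0.0)

    def test_pure_noise_gives_icc_near_zero(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {"video_id": np.repeat(np.arange(400), 2), "score": rng.normal(size=800)}
        )
        assert icc_oneway(t).icc < 0.1

    def test_balanced_matches_anova_closed_form(self):
        pairs = [(1.0, 2.0), (5.0, 6.0), (9.0, 8.0), (3.0, 3.0), (7.0, 9.0)]
        t = pd.DataFrame(
            {
                "video_id": np.repeat(np.arange(5), 2),
                "score": np.array(pairs).ravel(),
            }
        )
        # independent mean-squares arithmetic on the 5-video toy table
        arr = np.array(pairs)
        grand = arr.mean()
        k = 2
        msb = k * ((arr.mean(axis=1) - grand) ** 2).sum() / (5 - 1)
        msw = ((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum() / (10 - 5)
        expected = (msb - msw) / (msb + (k - 1) * msw)
        res = icc_oneway(t)
        assert res.method == "anova"
        assert res.icc == pytest.approx(expected)

    def test_known_variance_components_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        video = rng.normal(0.0, 2.0, size=n)  # sigma_b = 4
        scores = video[:, None] + rng.normal(0.0, 1.0, size=(n, 2))  # sigma_w = 1
        t = pd.DataFrame(
            {"video_id": np.repeat(np.arange(n), 2), "score": scores.ravel()}
        )
        res = icc_oneway(t)
        assert res.icc == pytest.approx(0.8, abs=0.03)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_unbalanced_reml_close_to_balanced_estimate(self):
        rng = np.random.default_rng(9)
        n = 300
        video = rng.normal(0.0, 2.0, size=n)
        rows = []
        for i in range(n):
            for j in range(3 if i % 5 == 0 else 2):
                rows.append({"video_id": i, "score": video[i] + rng.normal(0, 1)})
        res = icc_oneway(pd.DataFrame(rows))
        assert res.method == "reml"
        assert res.icc == pytest.approx(0.8, abs=0.08)

    def test_all_single_read_rejected(self):
        t = pd.DataFrame({"video_id": [1, 2, 3], "score": [1.0, 2.0, 3.0]})
        with pytest.raises(ReliabilityError):
            icc_oneway(t)

    def test_band_edges(self):
        assert [icc_band(v) for v in (0.49, 0.50, 0.74, 0.75, 0.90, 0.91)] == [
            "poor", "moderate", "moderate", "good", "good", "excellent",
        ]


class TestWeightedKappa:
    def test_perfect_agreement(self):
        a = ["mild"] * 5 + ["severe"] * 5
        res = weighted_kappa(a, list(a), ["mild", "moderate", "severe"])
        assert res.kappa == pytest.approx(1.0)

    def test_chance_agreement_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, size=4000)
        b = rng.integers(0, 4, size=4000)
        res = weighted_kappa(a, b, list(range(4)))
        assert abs(res.kappa) < 0.05
        assert res.ci_low <= res.kappa <= res.ci_high

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_random_tables_match_brute_force_and_sklearn(self, scheme):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            a = rng.integers(0, k, size=n)
            b = np.where(rng.random(n) < 0.6, a, rng.integers(0, k, size=n))
            if len(np.unique(np.concatenate([a, b]))) < 2:
                continue
            res = weighted_kappa(a, b, list(range(k)), scheme=scheme)
            assert res.kappa == pytest.approx(brute_force_weighted_kappa(a, b, k, scheme))
            assert res.kappa == pytest.approx(
                cohen_kappa_score(a, b, labels=list(range(k)), weights=scheme)
            )

    def test_two_categories_linear_equals_unweighted(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 2, size=200)
        b = np.where(rng.random(200) < 0.7, a, 1 - a)
        res = weighted_kappa(a, b, [0, 1], scheme="linear")
        # independent unweighted Cohen kappa
        po = np.mean(a == b)
        pe = np.mean(a) * np.mean(b) + (1 - np.mean(a)) * (1 - np.mean(b))
        assert res.kappa == pytest.approx((po - pe) / (1 - pe))

    def test_degenerate_expected_agreement_rejected(self):
        with pytest.raises(ReliabilityError, match="undefined kappa"):
            weighted_kappa([0, 0, 0], [0, 0, 0], [0, 1])

    def test_band_edges(self):
        assert [kappa_band(v) for v in (0.40, 0.41, 0.60, 0.61, 0.80, 0.81)] == [
            "below_moderate", "moderate", "moderate", "good", "good", "very_good",
        ]


def _kr(kappa, var, pair=("a", "b")):
    return KappaResult(pair, kappa, kappa - 1, min(kappa + 1, 1), var, 50, "linear")


class TestPooling:
    def test_single_pair_passthrough(self):
        r = _kr(0.7, 0.01)
        assert pool_kappas([r]) is r

    def test_equal_variances_give_simple_mean(self):
        res = pool_kappas([_kr(0.6, 0.01), _kr(0.8, 0.01)])
        assert res.kappa == pytest.approx(0.7)

    def test_hand_weighted_example(self):
        # weights 100 and 400: (60 + 360) / 500 = 0.84
        res = pool_kappas([_kr(0.6, 0.01), _kr(0.9, 0.0025)])
        assert res.kappa == pytest.approx(0.84)
        assert res.variance == pytest.approx(1 / 500)

    def test_pooled_mean_difference_examples(self):
        one = pooled_mean_difference([("all", [1.0, -1.0, 0.0, 0.0])])
        assert one.mean_diff == pytest.approx(0.0)
        sym = pooled_mean_difference([("a", [0.0, 2.0]), ("b", [2.0, 4.0])])
        assert sym.mean_diff == pytest.approx(2.0)
        # inverse-variance weights 1/0.25 = 4 and 1/0.0625 = 16:
        # (4*0.5 + 16*(-0.5)) / 20 = -0.3
        res = pooled_mean_difference([("a", [0.0, 1.0]), ("b", [-0.25, -0.75])])
        assert res.strata[0][2] == pytest.approx(0.25)
        assert res.strata[1][2] == pytest.approx(0.0625)
        assert res.mean_diff == pytest.approx(-0.3)

    def test_small_strata_dropped_and_all_dropped_errors(self):
        res = pooled_mean_difference([("a", [1.0]), ("b", [0.0, 2.0])])
        assert len(res.strata) == 1
        with pytest.raises(ReliabilityError):
            pooled_mean_difference([("a", [1.0])])


class TestChangeScores:
    def test_proportional_changes_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        pre = rng.integers(0, 20, size=12).astype(float)
        post = pre - rng.integers(0, 6, size=12)
        t = pd.DataFrame(
            {"sema_pre": pre, "sema_post": post, "ses_pre": 2 * pre, "ses_post": 2 * post}
        )
        assert change_score_correlation(t).rho == pytest.approx(1.0)

    def test_all_unchanged_is_degenerate(self):
        t = pd.DataFrame(
            {"sema_pre": [1.0] * 6, "sema_post": [1.0] * 6,
             "ses_pre": [2.0] * 6, "ses_post": [2.0] * 6}
        )
        with pytest.raises(ReliabilityError, match="zero variance"):
            change_score_correlation(t)
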