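"""Behavioural-score and infarct-volume statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfqpipe import (
    LongaScores,
    anova_snk,
    infarct_percent,
    rank_sum,
    reconstruct_score_multiset,
)


class TestInfarct:
    def test_hand_cases(self):
        assert infarct_percent([0] * 5, [10] * 5) == 0.0
        assert infarct_percent([1, 2, 3, 2, 1], [10] * 5) == pytest.approx(18.0)
        assert infarct_percent([10] * 5, [10] * 5) == 100.0

    def test_scale_invariance(self):
        a = infarct_percent([1, 2, 3, 2, 1], [8, 9, 10, 9, 8])
        b = infarct_percent([2, 4, 6, 4, 2], [16, 18, 20, 18, 16])
        assert a == pytest.approx(b)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            infarct_percent([1, 2, 3], [10, 10, 10])
        with pytest.raises(ValueError):
            infarct_percent([11, 0, 0, 0, 0], [10] * 5)
        with pytest.raises(ValueError):
            infarct_percent([0] * 5, [0] * 5)


class TestRankSum:
    def test_exact_extreme_separation(self):
        """{0,0,0,0} vs {3,3,3,3}: one-sided tail 1/70, two-sided ~0.0286."""
        a, b = [0, 0, 0, 0], [3, 3, 3, 3]
        _, p_less = rank_sum(a, b, method="exact", alternative="less")
        assert p_less == pytest.approx(1 / 70)
        _, p_two = rank_sum(a, b, method="exact")
        assert p_two == pytest.approx(2 / 70)

    def test_identical_multisets_p_one(self):
        _, p = rank_sum([1, 2, 2, 3], [1, 2, 2, 3], method="exact")
        assert p == 1.0
        _, p_norm = rank_sum([1, 2, 2, 3] * 3, [1, 2, 2, 3] * 3, method="normal")
        assert p_norm > 0.95

    def test_exact_and_normal_branches_agree(self):
        """The branches track each other on random tied score sets of size 8.

        With five-point scores ties make the exact null distribution lumpy,
        so agreement is tight (0.02) in the decision-relevant region
        (p <= 0.1) and within 0.12 elsewhere.
        """
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = rng.integers(0, 5, 8)
            b = rng.integers(0, 5, 8)
            _, p_exact = rank_sum(a, b, method="exact")
            _, p_norm = rank_sum(a, b, method="normal")
            tol = 0.02 if p_exact <= 0.1 else 0.12
            assert abs(p_exact - p_norm) < tol

    def test_agrees_with_scipy_mannwhitney(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 5, 12), rng.integers(0, 5, 12)
        _, p = rank_sum(a, b, method="normal")
        ref = mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
        assert p == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 4), min_size=2, max_size=6),
        b=st.lists(st.integers(0, 4), min_size=2, max_size=6),
    )
    def test_monotone_transform_invariance(self, a, b):
        """Rank-based: any strictly increasing transform leaves (W, p) unchanged."""
        w1, p1 = rank_sum(a, b, method="exact")
        f = lambda x: [v**3 + 2 * v for v in x]  # strictly increasing on 0..4
        w2, p2 = rank_sum(f(a), f(b), method="exact")
        assert w1 == w2 and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1])

    def test_longa_scores_validated(self):
        with pytest.raises(ValueError):
            LongaScores("g", (0, 5))
        assert LongaScores("g", (0, 4)).scores == (0, 4)


class TestAnovaSNK:
    def test_identical_groups(self):
        res = anova_snk({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res["F"] == pytest.approx(0.0)
        assert not any(p["significant"] for p in res["pairs"])

    def test_two_group_f_equals_t_squared(self):
        """F = t^2 and identical p to the pooled two-sample t-test."""
        res = anova_snk({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert res["F"] == pytest.approx(3.6742346**2, abs=1e-4)
        assert res["F"] == pytest.approx(13.5)
        assert res["p"] == pytest.approx(0.021312, abs=1e-5)

    def test_snk_decisions_match_critical_value_tables(self):
        """Frozen from printed studentized-range tables: q_.05(2,12)=3.08, q_.05(3,12)=3.77.

        Three groups of 5 (df error 12), MS_within = 0.5, means 0 / 0.9 / 2.0.
        Hand computation with q_crit from the tables: span-3 q = 2.0/sqrt(0.1)
        = 6.32 > 3.77 (sig); span-2 qs = 0.9/sqrt(0.1) = 2.85 and 1.1/sqrt(0.1)
        = 3.48, vs 3.08 -> (lo, mid) not significant, (mid, hi) significant.
        """

        def group(mean):
            base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
            base = base / base.std(ddof=1) * np.sqrt(0.5)  # SD^2 = 0.5 exactly
            return list(base - base.mean() + mean)

        res = anova_snk({"lo": group(0.0), "mid": group(0.9), "hi": group(2.0)})
        assert res["df_within"] == 12
        assert res["ms_within"] == pytest.approx(0.5)
        decisions = {
            (p["group_lo"], p["group_hi"]): p["significant"] for p in res["pairs"]
        }
        assert decisions[("lo", "hi")] is True
        assert decisions[("lo", "mid")] is False
        assert decisions[("mid", "hi")] is True

    def test_nonsignificant_span_blocks_nested_pairs(self):
        """Step-down rule: pairs inside a non-significant span stay non-significant."""

        def group(mean, n=4, sd2=4.0):
            base = np.array([-1.5, -0.5, 0.5, 1.5])
            base = base / base.std(ddof=1) * np.sqrt(sd2)
            return list(base - base.mean() + mean)

        # widest span far from significant -> everything blocked
        res = anova_snk({"a": group(0.0), "b": group(0.4), "c": group(0.8)})
        assert not any(p["significant"] for p in res["pairs"])

    def test_zero_variance_flagged(self):
        res = anova_snk({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res["zero_variance"]
        assert res["F"] == float("inf")

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            anova_snk({"a": [1.0]})


class TestReconstructMultiset:
    def test_printed_summaries_from_scores(self):
        """Printed '2.75 +/- 0.43' and '1.50 +/- 0.50' are reachable at n=8."""
        hits = reconstruct_score_multiset(2.75, 0.43, 8)
        assert tuple(sorted((3, 3, 3, 3, 3, 3, 2, 2))) in hits
        hits2 = reconstruct_score_multiset(1.50, 0.50, 8)
        assert tuple(sorted((2, 2, 2, 2, 1, 1, 1, 1))) in hits2

    def test_zero_mean_zero_sd(self):
        assert reconstruct_score_multiset(0.0, 0.0, 6) == [(0,) * 6]

    def test_impossible_summary_empty(self):
        assert reconstruct_score_multiset(4.0, 3.0, 3) == []

    def test_every_match_reproduces_summary(self):
        for combo in reconstruct_score_multiset(2.75, 0.43, 8):
            arr = np.array(combo)
            assert round(arr.mean(), 2) == 2.75
            assert round(arr.std(ddof=0), 2) == 0.43
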