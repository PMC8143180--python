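import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from guidedreading.stats import (
    GroupSummary,
    cohens_d,
    cohens_d_ci,
    d_contrast,
    holm_bonferroni,
    percent_of_total,
    pooled_sd,
    rank_sum,
    wilcoxon_signed_rank,
)

THERAPY_UNAIDED = GroupSummary(30, 16.57, 6.76)
THERAPY_AIDED = GroupSummary(30, 5.03, 3.56)


class TestPooledSD:
    def test_equal_sds_are_preserved(self):
        assert pooled_sd(GroupSummary(12, 0, 3.3), GroupSummary(7, 5, 3.3)) == pytest.approx(3.3)

    def test_therapy_group_value(self):
        assert pooled_sd(THERAPY_UNAIDED, THERAPY_AIDED) == pytest.approx(5.402, abs=1e-3)

    def test_speech_onset_value(self):
        g1 = GroupSummary(19, 1456.45, 473.08)
        g2 = GroupSummary(18, 1404.84, 705.60)
        assert pooled_sd(g1, g2) == pytest.approx(597.4, abs=0.1)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1, 0.0, 1.0)


class TestCohensD:
    def test_therapy_effect_size(self):
        assert cohens_d(THERAPY_UNAIDED, THERAPY_AIDED).d == pytest.approx(2.137, abs=0.01)

    def test_speech_onset_contrast_4_vs_5_letters(self):
        g4 = GroupSummary(18, 1404.84, 705.60)
        g5 = GroupSummary(18, 1466.39, 562.96)
        assert cohens_d(g4, g5).d == pytest.approx(-0.096, abs=0.001)

    def test_identical_groups_give_zero(self):
        g = GroupSummary(10, 4.2, 1.1)
        assert cohens_d(g, g).d == 0.0

    def test_antisymmetry_and_affine_invariance(self, rng):
        g1 = GroupSummary(14, 3.0, 1.4)
        g2 = GroupSummary(9, 1.2, 2.0)
        assert cohens_d(g1, g2).d == pytest.approx(-cohens_d(g2, g1).d)
        a, b = 2.5, -7.0
        h1 = GroupSummary(14, a * 3.0 + b, a * 1.4)
        h2 = GroupSummary(9, a * 1.2 + b, a * 2.0)
        assert cohens_d(h1, h2).d == pytest.approx(cohens_d(g1, g2).d)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))

    def test_ci_contains_d(self):
        eff = cohens_d(THERAPY_UNAIDED, THERAPY_AIDED)
        assert eff.ci_low <= eff.d <= eff.ci_high


class TestCohensDCI:
    def test_symmetric_about_zero(self):
        lo, hi = cohens_d_ci(0.0, 100, 100, 0.95)
        assert lo == pytest.approx(-hi)

    def test_width_shrinks_with_n(self):
        w10 = np.diff(cohens_d_ci(0.5, 10, 10))
        w1000 = np.diff(cohens_d_ci(0.5, 1000, 1000))
        assert w1000 < w10

    def test_formula_direct_evaluation(self):
        d, n1, n2 = 0.5, 30, 30
        z = sps.norm.ppf(0.975)
        se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
        lo, hi = cohens_d_ci(d, n1, n2, 0.95)
        assert (lo, hi) == pytest.approx((d - z * se, d + z * se))

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            cohens_d_ci(0.5, 10, 10, 1.5)


class TestDContrast:
    def test_published_contrast(self):
        assert d_contrast(2.137, -0.512) == pytest.approx(2.649)

    def test_identity_and_antisymmetry(self):
        assert d_contrast(1.3, 1.3) == 0.0
        assert d_contrast(0.7, -0.2) == -d_contrast(-0.2, 0.7)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            d_contrast(math.inf, 0.0)


def signed_rank_oracle(diffs: np.ndarray) -> float:
    """Exhaustive enumeration over all sign assignments."""
    d = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.asarray(signs).dot(ranks)
        for signs in itertools.product([0, 1], repeat=d.size)
    ]
    ws = np.asarray(ws)
    le = (ws <= w_obs + 1e-9).mean()
    ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(le, ge))


def rank_sum_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive enumeration over all group labelings."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[: a.size].sum()
    ws = np.asarray(
        [sum(ranks[list(c)]) for c in itertools.combinations(range(pooled.size), a.size)]
    )
    le = (ws <= w_obs + 1e-9).mean()
    ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(le, ge))


class TestWilcoxonSignedRank:
    def test_identical_pairs(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0

    def test_matches_enumeration_with_and_without_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            d = rng.integers(-4, 5, size=n).astype(float)  # integer data -> ties
            res = wilcoxon_signed_rank(d)
            assert res.exact
            assert res.p_value == pytest.approx(signed_rank_oracle(d), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=9), rng.normal(size=9)
            mine = wilcoxon_signed_rank(x, y).p_value
            ref = float(sps.wilcoxon(x, y, method="exact").pvalue)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_extreme_shift_gives_minimal_p(self):
        x = np.arange(1, 11, dtype=float)
        res = wilcoxon_signed_rank(x + 1000.0, x)
        # all 10 differences positive: most extreme of 2^10 assignments
        assert res.p_value == pytest.approx(2 / 2**10)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 1, size=40)
        res = wilcoxon_signed_rank(x)
        assert not res.exact
        assert res.p_value == pytest.approx(
            float(sps.wilcoxon(x, correction=True, method="approx").pvalue)
        )


class TestRankSum:
    def test_equal_samples_give_high_p(self):
        res = rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = rng.integers(0, 6, size=n1).astype(float)
            b = rng.integers(0, 6, size=n2).astype(float)
            res = rank_sum(a, b)
            assert res.exact
            assert res.p_value == pytest.approx(rank_sum_oracle(a, b), abs=1e-12)

    def test_two_sided_p_symmetric_under_swap(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert rank_sum(a, b).p_value == pytest.approx(rank_sum(b, a).p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


def holm_oracle(p):
    """Hand-stepped Holm definition: sort, multiply by (m - rank + 1),
    enforce monotonicity with a running maximum, cap at 1."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == pytest.approx([0.03])

    def test_hand_stepped_example(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones(self):
        assert holm_bonferroni([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 10)))
            assert holm_bonferroni(p) == pytest.approx(holm_oracle(p), abs=1e-12)

    def test_adjusted_at_least_raw_and_permutation_equivariant(self, rng):
        p = rng.uniform(size=6)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p - 1e-12)
        perm = rng.permutation(6)
        assert holm_bonferroni(p[perm]) == pytest.approx(adj[perm])


class TestPercentOfTotal:
    COUNTS = [59, 67, 51, 39]  # four texts, both parts -> 216 words

    @pytest.mark.parametrize(
        "mean,expected",
        [(16.57, 7.67), (5.03, 2.33), (14.4, 6.67), (17.2, 7.96), (0.0, 0.0)],
    )
    def test_published_percentages(self, mean, expected):
        assert percent_of_total(mean, self.COUNTS) == pytest.approx(expected, abs=0.01)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_of_total(1.0, [0, 0])
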