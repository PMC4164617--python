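"""Rank tests and Pearson correlation against enumeration/quadrature oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import rankdata

from dwiresponse import mann_whitney_u, pearson_correlation, wilcoxon_signed_rank
from dwiresponse.errors import DegenerateInputError, ValidationError


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by full enumeration of all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        signs = np.asarray(signs, bool)
        w = min(ranks[signs].sum(), ranks[~signs].sum())
        count += w <= w_obs + 1e-12
        total += 1
    return count / total


def mwu_exact_oracle(x, y):
    """Two-sided exact p by enumeration over all C(n, nx) group labelings."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = len(x), len(pooled)

    def u_min(idx):
        rx = ranks[list(idx)].sum()
        ux = rx - nx * (nx + 1) / 2
        return min(ux, nx * (n - nx) - ux)

    u_obs = u_min(range(nx))
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        count += u_min(idx) <= u_obs + 1e-12
        total += 1
    return count / total


def t_pvalue_quadrature(t_obs, df):
    """Two-sided p from the t density by numerical integration."""
    from scipy.special import gammaln

    lognorm = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)

    def pdf(t):
        return np.exp(lognorm - (df + 1) / 2 * np.log1p(t * t / df))

    tail, _ = quad(pdf, abs(t_obs), np.inf)
    return 2 * tail


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.exact
        assert res.p_value == pytest.approx(0.0625)
        assert res.p_value == pytest.approx(wilcoxon_exact_oracle([1, 2, 3, 4, 5]))

    def test_symmetric_pair(self):
        res = wilcoxon_signed_rank([-1, 1], [0, 0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_n10(self, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 10)
            d = np.where(d == 0, 0.1, d)
            res = wilcoxon_signed_rank(d, np.zeros(10))
            assert res.exact
            assert res.p_value == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_exact_approx_agree_at_crossover(self, rng):
        # tie-free samples either side of the exact-enumeration cutoff
        d24 = rng.normal(0.4, 1.0, 24)
        d26 = rng.normal(0.4, 1.0, 26)
        r24 = wilcoxon_signed_rank(d24, np.zeros(24))
        r26 = wilcoxon_signed_rank(d26, np.zeros(26))
        assert r24.exact and not r26.exact
        # approximate p on the same n=24 data agrees with exact within 0.01
        import scipy.stats
        approx = scipy.stats.wilcoxon(d24, method="approx", correction=True).pvalue
        assert abs(r24.p_value - approx) < 0.01
        assert 0 <= r26.p_value <= 1

    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=12),
           st.integers(min_value=1, max_value=5))
    def test_monotone_transform_invariance(self, diffs, k):
        x = np.asarray(diffs, float) + 0.5  # half-offset keeps values non-zero
        y = np.zeros(len(x))
        p1 = wilcoxon_signed_rank(x, y).p_value
        # strictly monotone odd transform of the differences preserves ranks
        p2 = wilcoxon_signed_rank(np.sign(x) * np.abs(x) ** (1 / k), y).p_value
        assert p1 == pytest.approx(p2, abs=1e-9)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

class TestMannWhitney:
    def test_small_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.p_value == pytest.approx(mwu_exact_oracle([1, 2], [3, 4]))

    def test_complete_overlap(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_6_5(self, rng):
        for _ in range(5):
            x = rng.normal(0.0, 1.0, 6)
            y = rng.normal(0.8, 1.0, 5)
            res = mann_whitney_u(x, y)
            assert res.exact
            assert res.p_value == pytest.approx(mwu_exact_oracle(x, y), abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 11)
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(b.statistic)

    def test_exact_approx_agree_at_crossover(self, rng):
        x = rng.normal(0, 1, 13)
        y = rng.normal(0.7, 1, 12)  # total 25: exact branch
        exact = mann_whitney_u(x, y)
        assert exact.exact
        import scipy.stats
        approx = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic").pvalue
        assert abs(exact.p_value - approx) < 0.01

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(2, 1, 8)
        y = rng.normal(3, 1, 7)
        p1 = mann_whitney_u(x, y).p_value
        p2 = mann_whitney_u(np.exp(x), np.exp(y)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------

class TestPearson:
    def test_perfect_linearity(self):
        x = np.asarray([1.0, 2.0, 3.0, 4.0])
        res = pearson_correlation(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_hand_computed_example(self):
        x = np.asarray([1, 2, 3, 4, 5], float)
        y = np.asarray([2, 1, 4, 3, 5], float)
        res = pearson_correlation(x, y)
        assert res.statistic == pytest.approx(0.8)
        t_obs = 0.8 * np.sqrt(3) / np.sqrt(1 - 0.64)
        assert res.p_value == pytest.approx(t_pvalue_quadrature(t_obs, 3), rel=1e-6)
        assert res.p_value == pytest.approx(0.104, abs=0.001)

    def test_independent_samples_near_zero(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert abs(pearson_correlation(x, y).statistic) < 0.03

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
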