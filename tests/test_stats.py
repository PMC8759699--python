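"""The nonparametric comparison plan against brute-force enumeration oracles."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ifsigtt.errors import ValidationError
from ifsigtt.stats import (
    friedman_with_dunns,
    mann_whitney_u,
    median_iqr,
    spearman,
    students_t,
)


def exact_mw_p_by_enumeration(x, y):
    """Two-sided exact Mann-Whitney p: enumerate all group labelings of the
    pooled sample and count Us at least as far from the null mean."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)
    center = nx * len(y) / 2.0
    u_obs = sum(1.0 for a in x for b in y if a > b) + \
        sum(0.5 for a in x for b in y if a == b)
    dev_obs = abs(u_obs - center)
    count = 0
    total = 0
    idx = range(len(pooled))
    for chosen in combinations(idx, nx):
        first = [pooled[i] for i in chosen]
        rest = [pooled[i] for i in idx if i not in chosen]
        u = sum(1.0 for a in first for b in rest if a > b) + \
            sum(0.5 for a in first for b in rest if a == b)
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def exact_spearman_p_by_enumeration(x, y):
    """Two-sided permutation p computed with scipy's rho, one call per pairing."""
    rho_obs = sps.spearmanr(x, y).statistic
    count = 0
    perms = list(permutations(y))
    for perm in perms:
        if abs(sps.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / len(perms)


class TestMedianIqr:
    def test_singleton(self):
        assert median_iqr([5.0]) == (5.0, 5.0, 5.0)

    def test_even_sample_median_interpolated(self):
        med, q25, q75 = median_iqr([1, 2, 3, 4])
        assert med == 2.5
        assert q25 == 1.75 and q75 == 3.25

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            median_iqr([])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        c = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0])
        assert c.p_value == 1.0
        assert c.warnings

    def test_complete_separation_exact_p(self):
        c = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert c.statistic == 0.0
        assert c.p_value == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("nx,ny", [(1, 1), (2, 3), (3, 3), (4, 4), (2, 7), (5, 5)])
    def test_exact_p_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(100 * nx + ny)
        x = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
        pool = [v for v in np.arange(1.0, nx + ny + 1) if v not in x]
        y = np.array(pool)
        c = mann_whitney_u(x, y)
        assert c.p_value == pytest.approx(exact_mw_p_by_enumeration(x, y), abs=1e-12)

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=10),
           st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=10))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_u_statistic_bounds(self, x, y):
        c = mann_whitney_u(x, y)
        assert 0.0 <= c.statistic <= len(x) * len(y)

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(loc=1.0, size=6)
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            mann_whitney_u(y, x).p_value, rel=1e-12)


class TestStudentsT:
    def test_identical_means_give_t_zero(self):
        c = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        c = students_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert c.statistic == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-9)
        assert c.statistic == pytest.approx(-3.674, abs=5e-4)
        assert c.df == 4

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=9), rng.normal(loc=0.5, size=7)
        a, b = students_t(x, y), students_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_group_summaries_are_mean_ci(self):
        c = students_t([10.0, 12.0, 14.0], [20.0, 22.0, 24.0], labels=("a", "b"))
        a = c.group_summaries[0]
        assert a.kind == "mean_ci95"
        assert a.center == pytest.approx(12.0)
        half = sps.t.ppf(0.975, 2) * 2.0 / math.sqrt(3)
        assert a.low == pytest.approx(12.0 - half)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValidationError):
            students_t([1.0, 1.0], [1.0, 1.0])


class TestSpearman:
    def test_perfect_monotone_gives_rho_one(self):
        c = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert c.statistic == pytest.approx(1.0)

    def test_rank_formula_example(self):
        c = spearman([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert c.statistic == pytest.approx(-0.5, rel=1e-12)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_full_permutation(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        c = spearman(x, y)
        assert c.p_value == pytest.approx(
            exact_spearman_p_by_enumeration(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        c = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert c.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert c.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFriedmanDunns:
    def test_constant_matrix_gives_zero_statistic(self):
        m = np.tile([[5.0, 5.0, 5.0]], (4, 1))
        rep = friedman_with_dunns(m, [0, 10, 20])
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_perfectly_consistent_ordering_gives_maximal_q(self):
        m = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        rep = friedman_with_dunns(m, [0, 10, 20])
        assert rep.statistic == pytest.approx(6.0)

    def test_matches_scipy_on_random_blocks(self):
        rng = np.random.default_rng(21)
        m = rng.normal(size=(8, 5))
        rep = friedman_with_dunns(m, [0, 2, 5, 10, 20])
        stat, p = sps.friedmanchisquare(*[m[:, j] for j in range(5)])
        assert rep.statistic == pytest.approx(stat, rel=1e-12)
        assert rep.p_value == pytest.approx(p, rel=1e-12)

    def test_incomplete_blocks_dropped_and_counted(self):
        m = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0],
                      [2.0, 3.0, 1.0], [5.0, 6.0, 4.0]])
        rep = friedman_with_dunns(m, [0, 10, 20])
        assert rep.n_subjects == 3 and rep.n_dropped == 1

    def test_dunns_detects_shifted_time_point(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 1))
        m = np.hstack([base, base + 0.01 * rng.normal(size=(10, 3)),
                       base + 5.0 + 0.01 * rng.normal(size=(10, 1))])
        rep = friedman_with_dunns(m, [0, 2, 5, 7, 10])
        shifted = [d for d in rep.dunns if d.time_label == 10][0]
        assert shifted.significant and shifted.direction == 1

    def test_dunns_adjustment_is_bonferroni_over_k_minus_1(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(6, 4))
        rep = friedman_with_dunns(m, [0, 1, 2, 3])
        for d in rep.dunns:
            raw = 2.0 * sps.norm.sf(abs(d.z))
            assert d.p_adjusted == pytest.approx(min(1.0, raw * 3), rel=1e-12)

    def test_too_few_times_rejected(self):
        with pytest.raises(ValidationError):
            friedman_with_dunns(np.ones((4, 2)), [0, 10])
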