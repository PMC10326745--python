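"""Statistical primitives against brute-force oracles and closed forms."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from coexnet.stats import (
    ZeroVarianceError,
    adjust_pvalues,
    binomial_tail,
    fisher_exact_enrichment,
    fisher_z_diff_test,
    pearson_with_p,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def bh_oracle(p):
    """Step-up definition: adj(i) = min_{j >= i} p(j) * m / j on sorted p."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def holm_oracle(p):
    """Step-down definition: cumulative max of p(j) * (m - j + 1) on sorted p."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for j in range(m):
        running = max(running, p[order[j]] * (m - j))
        adj_sorted[j] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed the observed table's."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = sps.hypergeom.pmf(x, n, c1, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# pearson_with_p


def test_pearson_perfect_correlation_and_anticorrelation():
    up = pearson_with_p([1, 2, 3, 4], [1, 2, 3, 4])
    assert up.r == pytest.approx(1.0)
    assert up.p == pytest.approx(0.0, abs=1e-12)
    down = pearson_with_p([1, 2, 3, 4], [4, 3, 2, 1])
    assert down.r == pytest.approx(-1.0)


def test_pearson_matches_direct_formula():
    x = np.array([1, 2, 3, 4, 5], float)
    y = np.array([2, 1, 4, 3, 6], float)
    r_direct = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    t = r_direct * math.sqrt((5 - 2) / (1 - r_direct**2))
    p_direct = 2 * sps.t.sf(abs(t), 5 - 2)
    stat = pearson_with_p(x, y)
    assert stat.r == pytest.approx(r_direct, abs=1e-12)
    assert stat.p == pytest.approx(p_direct, abs=1e-12)


def test_pearson_input_errors():
    with pytest.raises(ZeroVarianceError):
        pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        pearson_with_p([1, 2, 3], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        pearson_with_p([1, 2, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# fisher_z_diff_test


def test_fisher_z_identical_correlations_give_null():
    z, p = fisher_z_diff_test(0.5, 30, 0.5, 22)
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_fisher_z_antisymmetry():
    z1, p1 = fisher_z_diff_test(0.6, 25, -0.2, 18)
    z2, p2 = fisher_z_diff_test(-0.2, 18, 0.6, 25)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)


def test_fisher_z_tumor_normal_example():
    """Correlations 0.70 (n=30) vs -0.19 (n=22): independent formula gives
    z ~ 3.539, p ~ 4.0e-4."""
    expected_z = (math.atanh(0.70) - math.atanh(-0.19)) / math.sqrt(1 / 27 + 1 / 19)
    expected_p = 2 * sps.norm.sf(abs(expected_z))
    z, p = fisher_z_diff_test(0.70, 30, -0.19, 22)
    assert z == pytest.approx(expected_z, abs=1e-12)
    assert p == pytest.approx(expected_p, abs=1e-15)
    assert z == pytest.approx(3.539, abs=5e-4)
    assert p == pytest.approx(4.0e-4, abs=5e-5)


def test_fisher_z_input_errors():
    with pytest.raises(ValueError):
        fisher_z_diff_test(1.0, 30, 0.5, 22)
    with pytest.raises(ValueError):
        fisher_z_diff_test(0.5, 3, 0.5, 22)


def test_fisher_z_agrees_with_permutation_test(rng):
    """The analytic p agrees with a label-permutation test up to the O(1/n)
    error of the normal approximation at n=30/22 (the Monte-Carlo error of
    the permutation oracle itself is much smaller)."""
    n1, n2, reps = 30, 22, 20_000
    for rho in (0.0, 0.5, 0.8):
        cov = [[1, rho], [rho, 1]]
        d1 = rng.multivariate_normal([0, 0], cov, size=n1)
        d2 = rng.multivariate_normal([0, 0], cov, size=n2)
        r1 = np.corrcoef(d1.T)[0, 1]
        r2 = np.corrcoef(d2.T)[0, 1]
        _, p_analytic = fisher_z_diff_test(r1, n1, r2, n2)

        pooled = np.vstack([d1, d2])

        def rowwise_corr(block):  # block: (reps, n, 2)
            a = block - block.mean(axis=1, keepdims=True)
            num = (a[:, :, 0] * a[:, :, 1]).sum(axis=1)
            den = np.sqrt((a[:, :, 0] ** 2).sum(axis=1) * (a[:, :, 1] ** 2).sum(axis=1))
            return num / den

        idx = np.argsort(rng.random((reps, n1 + n2)), axis=1)  # random permutations
        perms = pooled[idx]

        def zstat(ra, rb):  # same atanh-difference statistic as the analytic test
            clip = lambda r: np.clip(r, -1 + 1e-12, 1 - 1e-12)
            return np.abs(np.arctanh(clip(ra)) - np.arctanh(clip(rb)))

        stat = zstat(rowwise_corr(perms[:, :n1]), rowwise_corr(perms[:, n1:]))
        obs = zstat(np.array(r1), np.array(r2))
        p_perm = (np.sum(stat >= obs) + 1) / (reps + 1)
        assert p_analytic == pytest.approx(p_perm, abs=0.075)


# ---------------------------------------------------------------------------
# adjust_pvalues


def test_bh_hand_example():
    out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="BH")
    assert np.allclose(out.adjusted, [0.04, 0.04, 0.04, 0.04])


def test_holm_hand_example():
    out = adjust_pvalues([0.01, 0.04], method="Holm")
    assert np.allclose(out.adjusted, [0.02, 0.04])


def test_single_value_either_method():
    for method in ("BH", "Holm"):
        out = adjust_pvalues([0.5], method=method)
        assert out.adjusted[0] == pytest.approx(0.5)


@pytest.mark.parametrize("method,oracle", [("BH", bh_oracle), ("Holm", holm_oracle)])
def test_adjustment_matches_bruteforce_on_random_vectors(method, oracle, rng):
    for _ in range(200):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m)
        out = adjust_pvalues(p, method=method)
        assert np.allclose(out.adjusted, oracle(p), atol=1e-12)
        assert np.all(out.adjusted >= p - 1e-15)
        assert np.all(out.adjusted <= 1.0)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_is_monotone_and_order_preserving(pvals):
    """BH dominates the raw p-values, preserves their ordering, and as a
    monotone operator never shrinks under re-application. (It is not a
    projection: re-adjusting an adjusted vector can only move it upward,
    e.g. (0.01, 0.04) -> (0.02, 0.04) -> (0.04, 0.04).)"""
    p = np.asarray(pvals)
    first = adjust_pvalues(pvals, method="BH").adjusted
    second = adjust_pvalues(first, method="BH").adjusted
    assert np.all(first >= p - 1e-15)
    assert np.all(second >= first - 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(first[order]) >= -1e-12)


def test_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_pvalues([0.1, 1.5])


# ---------------------------------------------------------------------------
# binomial_tail


def test_binomial_tail_examples():
    assert binomial_tail(0, 10, 0.3) == 1.0
    assert binomial_tail(7, 10, 1.0) == pytest.approx(1.0)
    # direct pmf summation
    expected = sum(math.comb(10, k) * 0.1**k * 0.9 ** (10 - k) for k in range(5, 11))
    assert binomial_tail(5, 10, 0.1) == pytest.approx(expected, rel=1e-12)
    assert binomial_tail(5, 10, 0.1) == pytest.approx(1.635e-3, abs=1e-6)
    with pytest.raises(ValueError):
        binomial_tail(11, 10, 0.1)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.integers(min_value=1, max_value=30),
    st.floats(min_value=0.01, max_value=0.99),
)
def test_binomial_tail_monotone_decreasing_in_k(n, rate):
    tails = [binomial_tail(k, n, rate) for k in range(n + 1)]
    assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))


# ---------------------------------------------------------------------------
# fisher_exact_enrichment


def test_fisher_enrichment_zero_overlap_is_one():
    assert fisher_exact_enrichment(0, 5, 8, 7, alternative="greater") == pytest.approx(1.0)


def test_fisher_enrichment_hypergeometric_example():
    # overlap 3 of set 5, selection 8, universe 20
    p = fisher_exact_enrichment(3, 2, 5, 10, alternative="greater")
    assert p == pytest.approx(float(sps.hypergeom.sf(2, 20, 5, 8)), rel=1e-12)
    assert p == pytest.approx(0.296, abs=5e-4)


def test_fisher_greater_equals_hypergeom_tail_all_small_tables():
    for a, b, c, d in product(range(5), repeat=4):
        if a + b + c + d == 0:
            continue
        p = fisher_exact_enrichment(a, b, c, d, alternative="greater")
        tail = float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
        assert p == pytest.approx(tail, rel=1e-9, abs=1e-12)


def test_fisher_two_sided_matches_enumeration_total_le_12():
    checked = 0
    for a, b, c, d in product(range(13), repeat=4):
        if not 0 < a + b + c + d <= 12:
            continue
        p = fisher_exact_enrichment(a, b, c, d, alternative="two-sided")
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-6, abs=1e-9)
        checked += 1
    assert checked > 1000


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValueError):
        fisher_exact_enrichment(-1, 2, 3, 4)
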