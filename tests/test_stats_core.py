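"""Oracle-based tests for the exact statistics kernels.

Every kernel is checked against an independent brute-force oracle
(enumeration, grid search, or direct ECDF evaluation) and, where a
library offers the same computation, against that library as a second
independent reference.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import ks_2samp, rankdata, wilcoxon
from scipy.stats.contingency import odds_ratio as scipy_cmle

from pcmckit.stats_core import (
    UndefinedTestError, cohens_kappa, exact_signed_rank_test,
    fisher_exact_2x2, fisher_exact_rxc, ks_two_sample,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def signed_rank_oracle(diffs, alternative="greater"):
    """Tail probability by explicit enumeration of all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0.0], dtype=float)
    ranks = rankdata(np.abs(d))
    neg = float(ranks[d < 0].sum())
    pos = float(ranks[d > 0].sum())
    sums = [sum(c) for r in range(len(ranks) + 1)
            for c in itertools.combinations(ranks, r)]
    if alternative == "greater":
        t = neg
        return t, sum(s <= t + 1e-9 for s in sums) / len(sums)
    if alternative == "less":
        t = pos
        return t, sum(s <= t + 1e-9 for s in sums) / len(sums)
    t = min(neg, pos)
    w = float(ranks.sum())
    hi = w - t
    p = sum(1 for s in sums if s <= t + 1e-9 or s >= hi - 1e-9) / len(sums)
    return t, min(1.0, p)


def fisher_2x2_oracle(table):
    """Two-sided p by explicit hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(r1 + r2, c1))

    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    p_obs = prob(a)
    return sum(prob(x) for x in support if prob(x) <= p_obs * (1 + 1e-7))


def cmle_or_oracle(table):
    """Conditional-MLE odds ratio by log-spaced grid search + refinement."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    support = list(range(max(0, c1 - r2), min(r1, c1) + 1))
    if a == support[0]:
        return 0.0
    if a == support[-1]:
        return math.inf

    def loglik(psi):
        terms = [math.comb(r1, x) * math.comb(r2, c1 - x) * psi ** x
                 for x in support]
        return a * math.log(psi) - math.log(sum(t / psi ** support[0]
                                                for t in terms)) \
            - support[0] * math.log(psi)

    grid = np.logspace(-8, 8, 2001)
    best = grid[int(np.argmax([loglik(p) for p in grid]))]
    span = 0.1
    for _ in range(40):  # shrinking-window refinement around the optimum
        cand = np.linspace(best * (1 - span), best * (1 + span), 41)
        best = cand[int(np.argmax([loglik(p) for p in cand]))]
        span *= 0.6
    return best


def rx2_oracle(table):
    """Exact r x 2 independence p by enumeration over all tables with the
    observed margins (itertools.product, independent of the DFS in the
    implementation)."""
    rows = [r for r in table if sum(r) > 0]
    row_sums = [sum(r) for r in rows]
    c1 = sum(r[0] for r in rows)
    n = sum(row_sums)

    def prob(xs):
        num = 1.0
        for x, r in zip(xs, row_sums):
            if x < 0 or x > r:
                return 0.0
            num *= math.comb(r, x)
        return num / math.comb(n, c1)

    p_obs = prob([r[0] for r in rows])
    total = 0.0
    for xs in itertools.product(*[range(r + 1) for r in row_sums]):
        if sum(xs) != c1:
            continue
        p = prob(list(xs))
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


def ks_d_oracle(xs, ys):
    """Supremum ECDF gap by direct double-loop evaluation."""
    pooled = sorted(set(xs) | set(ys))
    best = 0.0
    for t in pooled:
        fx = sum(1 for v in xs if v <= t) / len(xs)
        fy = sum(1 for v in ys if v <= t) / len(ys)
        best = max(best, abs(fx - fy))
    return best


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("diffs, expected_T, expected_p", [
    ([0.1, 0.2, 0.3, 0.4, 0.5], 0.0, 1 / 32),      # all five favour the alt
    ([0.1, -0.2, -0.3, 0.4, 0.5], 5.0, 10 / 32),   # opposing ranks sum to 5
    ([0.7], 0.0, 0.5),                              # single difference
])
def test_signed_rank_reference_values(diffs, expected_T, expected_p):
    res = exact_signed_rank_test(diffs, "greater")
    assert res.T == expected_T
    assert res.p == pytest.approx(expected_p, abs=1e-12)
    t_o, p_o = signed_rank_oracle(diffs, "greater")
    assert (res.T, res.p) == pytest.approx((t_o, p_o))


def test_signed_rank_drops_zeros_and_rejects_all_zero():
    res = exact_signed_rank_test([0.0, 0.5, -0.2, 0.0], "greater")
    assert res.n_used == 2
    with pytest.raises(UndefinedTestError):
        exact_signed_rank_test([0.0, 0.0])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(-40, 40).map(lambda v: v / 7.0), min_size=1, max_size=9),
    st.sampled_from(["greater", "less", "two_sided"]),
)
def test_signed_rank_matches_enumeration_oracle(diffs, alternative):
    if all(d == 0 for d in diffs):
        return
    res = exact_signed_rank_test(diffs, alternative)
    t_o, p_o = signed_rank_oracle(diffs, alternative)
    assert res.T == pytest.approx(t_o)
    assert res.p == pytest.approx(p_o, abs=1e-10)


def test_signed_rank_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(5)
    for _ in range(100):
        d = rng.normal(size=int(rng.integers(2, 10)))
        for alt, salt in [("greater", "greater"), ("less", "less"),
                          ("two_sided", "two-sided")]:
            assert exact_signed_rank_test(d, alt).p == pytest.approx(
                wilcoxon(d, alternative=salt, mode="exact").pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# Fisher 2x2
# ---------------------------------------------------------------------------


def test_fisher_trivial_and_derived_tables():
    res = fisher_exact_2x2([[1, 1], [1, 1]])
    assert res.p == pytest.approx(1.0)
    assert res.or_cmle == pytest.approx(1.0, abs=1e-6)
    assert fisher_exact_2x2([[2, 0], [0, 2]]).p == pytest.approx(1 / 3)
    res = fisher_exact_2x2([[3, 1], [1, 3]])
    assert res.or_cmle == pytest.approx(cmle_or_oracle([[3, 1], [1, 3]]),
                                        rel=1e-3)


def test_fisher_zero_cell_flags():
    assert fisher_exact_2x2([[0, 5], [3, 2]]).or_cmle == 0.0
    assert fisher_exact_2x2([[5, 0], [2, 3]]).unbounded
    assert fisher_exact_2x2([[0, 0], [2, 3]]).degenerate


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -1], [2, 3]])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 12)] * 4))
def test_fisher_p_matches_enumeration_and_scipy(cells):
    a, b, c, d = cells
    table = [[a, b], [c, d]]
    res = fisher_exact_2x2(table)
    if res.degenerate:
        return
    assert res.p == pytest.approx(fisher_2x2_oracle(table), abs=1e-12)
    assert res.p == pytest.approx(scipy_fisher(table)[1], abs=1e-9)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 10)] * 4))
def test_fisher_invariances(cells):
    a, b, c, d = cells
    res = fisher_exact_2x2([[a, b], [c, d]])
    if res.degenerate:
        return
    transposed = fisher_exact_2x2([[a, c], [b, d]])
    swapped = fisher_exact_2x2([[d, c], [b, a]])
    assert res.p == pytest.approx(transposed.p, abs=1e-12)
    assert res.p == pytest.approx(swapped.p, abs=1e-12)


def test_cmle_or_monotone_in_corner_cell():
    last = 0.0
    for a in range(1, 6):
        val = fisher_exact_2x2([[a, 6 - a], [3, 3]]).or_cmle
        assert val > last
        last = val


def test_cmle_or_matches_scipy_reference():
    rng = np.random.default_rng(11)
    for _ in range(100):
        t = rng.integers(0, 12, size=(2, 2))
        res = fisher_exact_2x2(t)
        if res.degenerate or not math.isfinite(res.or_cmle) or res.or_cmle == 0:
            continue
        ref = scipy_cmle(t).statistic
        assert res.or_cmle == pytest.approx(ref, rel=1e-4)


# ---------------------------------------------------------------------------
# Fisher r x 2
# ---------------------------------------------------------------------------


def test_rxc_consistent_with_2x2_and_zero_row_invariant():
    table = [[4, 1], [2, 5]]
    assert fisher_exact_rxc(table).p == pytest.approx(
        fisher_exact_2x2(table).p, abs=1e-12)
    with_zero = [[4, 1], [0, 0], [2, 5]]
    assert fisher_exact_rxc(with_zero).p == pytest.approx(
        fisher_exact_rxc(table).p, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                min_size=2, max_size=4))
def test_rxc_matches_enumeration_oracle(rows):
    if sum(a + b for a, b in rows) == 0:
        return
    res = fisher_exact_rxc([list(r) for r in rows])
    assert res.method == "exact"
    assert res.p == pytest.approx(rx2_oracle([list(r) for r in rows]),
                                  abs=1e-10)


def test_rxc_monte_carlo_agrees_with_exact():
    table = [[8, 3], [2, 9], [5, 5]]
    exact = fisher_exact_rxc(table)
    mc = fisher_exact_rxc(table, exact_limit=1, mc_reps=40_000, seed=3)
    assert mc.method == "monte_carlo"
    assert mc.se is not None
    assert abs(mc.p - exact.p) < 5 * mc.se + 1e-3


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("xs, ys, expected_d", [
    ([1, 2, 3], [1, 2, 3], 0.0),
    ([1, 2], [5, 6, 7], 1.0),
    ([1, 2], [1, 2, 3], 1 / 3),
])
def test_ks_statistic_reference_values(xs, ys, expected_d):
    assert ks_two_sample(xs, ys).D == pytest.approx(expected_d)


def test_ks_rejects_empty_sample():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(-35, 35).map(lambda v: v / 7.0),
                min_size=1, max_size=12),
       st.lists(st.integers(-35, 35).map(lambda v: v / 7.0),
                min_size=1, max_size=12))
def test_ks_d_matches_ecdf_oracle_and_monotone_invariance(xs, ys):
    res = ks_two_sample(xs, ys)
    assert res.D == pytest.approx(ks_d_oracle(xs, ys), abs=1e-12)
    transformed = ks_two_sample([math.exp(x / 3) for x in xs],
                                [math.exp(y / 3) for y in ys])
    assert transformed.D == pytest.approx(res.D, abs=1e-9)


def test_ks_exact_p_matches_scipy():
    rng = np.random.default_rng(2)
    for _ in range(60):
        x = rng.normal(size=int(rng.integers(2, 10)))
        y = rng.normal(size=int(rng.integers(2, 10)))
        mine = ks_two_sample(x, y)
        ref = ks_2samp(x, y, method="exact")
        assert mine.p_exact and not mine.ties_present
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)


def test_ks_flags_ties():
    res = ks_two_sample([1, 1, 2, 3], [1, 2, 2, 4])
    assert res.ties_present and not res.p_exact


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


def test_kappa_reference_values():
    assert cohens_kappa(list("aabb"), list("aabb")).kappa == 1.0
    labels_a = ["x"] * 25 + ["y"] * 25
    labels_b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
    res = cohens_kappa(labels_a, labels_b)
    assert res.p_observed == pytest.approx(0.7)
    assert res.p_expected == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.4)


def test_kappa_constant_coder_at_or_below_chance():
    res = cohens_kappa(["a"] * 10, ["a"] * 6 + ["b"] * 4)
    assert res.kappa <= 0.0


def test_kappa_category_relabelling_invariance():
    a = ["a", "b", "c", "a", "b", "c", "a"]
    b = ["a", "b", "b", "c", "b", "c", "a"]
    relabel = {"a": "z1", "b": "z2", "c": "z3"}
    assert cohens_kappa(a, b).kappa == pytest.approx(
        cohens_kappa([relabel[x] for x in a],
                     [relabel[x] for x in b]).kappa)


def test_kappa_rejects_length_mismatch():
    with pytest.raises(ValueError):
        cohens_kappa(["a"], ["a", "b"])
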