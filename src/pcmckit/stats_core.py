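"""Exact small-sample statistics.

Every inferential step of the pipeline runs through the four kernels in
this module: the exact Wilcoxon signed-rank test (full enumeration of sign
assignments, mid-ranks for ties, no normal approximation), Fisher's exact
test for 2x2 and r x 2 tables with the conditional-maximum-likelihood odds
ratio, the two-sample Kolmogorov-Smirnov test, and Cohen's kappa.

The tests are implemented here rather than delegated because the study
designs they serve have five or six paired observations and a handful of
counts per cell; the exact null distributions are cheap to enumerate and
an asymptotic approximation would be indefensible at these sizes.
Library implementations (scipy, statsmodels) are used as independent
cross-checks in the test suite, never as the computation itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SignedRankResult",
    "FisherResult",
    "RxCResult",
    "KSResult",
    "KappaResult",
    "exact_signed_rank_test",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "ks_two_sample",
    "cohens_kappa",
]

Alternative = Literal["greater", "less", "two_sided"]

#: relative tolerance used when comparing table probabilities in the
#: probability-ordering ("minimum likelihood") two-sided Fisher rule;
#: matches the behaviour of the reference exact-test implementations.
FISHER_REL_TOL = 1.0 + 1e-7


class UndefinedTestError(ValueError):
    """Raised when a test statistic is undefined for the given input
    (e.g. all-zero paired differences)."""


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedRankResult:
    """Exact signed-rank test result.

    ``T`` is the sum of the (mid-)ranks of the differences that oppose the
    alternative: for ``alternative='greater'`` the ranks of the negative
    differences, for ``'less'`` the ranks of the positive ones, and for
    ``'two_sided'`` the smaller of the two rank sums.  ``n_used`` counts the
    differences remaining after zeros are dropped.
    """

    T: float
    n_used: int
    p: float
    alternative: Alternative

    def __post_init__(self) -> None:
        w = self.n_used * (self.n_used + 1) / 2.0
        if not (-1e-9 <= self.T <= w + 1e-9):
            raise ValueError(f"T={self.T} outside [0, {w}]")
        if not (0.0 < self.p <= 1.0 + 1e-12):
            raise ValueError(f"p={self.p} outside (0, 1]")


def _signed_rank_distribution(ranks: Sequence[float]) -> np.ndarray:
    """Null distribution of the rank sum of a uniformly random subset of
    ``ranks``.

    Ranks are mid-ranks, hence multiples of 1/2; doubling makes them
    integers so the distribution is an exact integer convolution.  Returns
    an array ``c`` where ``c[s]`` counts sign assignments whose doubled
    rank sum equals ``s`` (total ``2**n``).
    """
    doubled = [int(round(2 * r)) for r in ranks]
    total = sum(doubled)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: counts.size - d]
        counts = counts + shifted
    return counts


def exact_signed_rank_test(
    differences: Iterable[float], alternative: Alternative = "greater"
) -> SignedRankResult:
    """Exact Wilcoxon signed-rank test by full enumeration.

    Zero differences are dropped; the absolute values of the remainder are
    mid-ranked (ties share the average rank).  The tail probability is
    computed from the exact permutation distribution of all ``2**n`` sign
    assignments conditioned on the observed rank vector, so the p-value is
    exact even in the presence of ties.

    Parameters
    ----------
    differences
        Signed paired differences.
    alternative
        ``'greater'`` tests for a positive location shift (small rank sum
        of negative differences is evidence), ``'less'`` the reverse,
        ``'two_sided'`` both.

    Raises
    ------
    UndefinedTestError
        If every difference is zero (or the input is empty).
    """
    d = np.asarray(list(differences), dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise UndefinedTestError("signed-rank test undefined: no nonzero differences")
    ranks = rankdata(np.abs(d))
    neg_sum = float(ranks[d < 0].sum())
    pos_sum = float(ranks[d > 0].sum())
    n = int(d.size)

    counts = _signed_rank_distribution(ranks)
    denom = 2.0**n

    def cdf_at(t: float) -> float:
        # P(rank sum of a random sign subset <= t); doubled-integer scale
        idx = int(math.floor(2 * t + 1e-9))
        idx = min(idx, counts.size - 1)
        return float(counts[: idx + 1].sum()) / denom

    if alternative == "greater":
        T = neg_sum
        p = cdf_at(T)
    elif alternative == "less":
        T = pos_sum
        p = cdf_at(T)
    elif alternative == "two_sided":
        T = min(neg_sum, pos_sum)
        w = float(ranks.sum())
        # symmetric null: sum both tails without double counting
        lo = cdf_at(T)
        hi = 1.0 - cdf_at(w - T - 0.5) if w - T > T else 0.0
        p = min(1.0, lo + hi) if w - T > T else 1.0
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown alternative {alternative!r}")
    return SignedRankResult(T=T, n_used=n, p=p, alternative=alternative)


# ---------------------------------------------------------------------------
# Fisher's exact test, 2x2, with conditional-MLE odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    """Fisher exact-test result for a 2x2 table.

    ``or_cmle`` is the conditional maximum-likelihood odds ratio (the value
    maximising the noncentral hypergeometric likelihood of the observed
    table given all margins); it is 0.0 or ``inf`` when the observed count
    sits at the boundary of its support, in which case ``unbounded`` or a
    zero flag applies.
    """

    p: float
    or_cmle: float
    table: tuple[tuple[int, int], tuple[int, int]]
    alternative: Alternative = "two_sided"
    degenerate: bool = False

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.or_cmle)


def _validate_2x2(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    return a, b, c, d


def _log_hypergeom_pmf(x: int, r1: int, r2: int, c1: int) -> float:
    n = r1 + r2
    return (
        _lchoose(r1, x)
        + _lchoose(r2, c1 - x)
        - _lchoose(n, c1)
    )


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _support(r1: int, r2: int, c1: int) -> range:
    return range(max(0, c1 - r2), min(r1, c1) + 1)


def _cond_mean(log_psi: float, r1: int, r2: int, c1: int) -> float:
    """Mean of the noncentral hypergeometric distribution with log-odds
    ``log_psi`` and the given margins (computed with log-sum-exp)."""
    sup = _support(r1, r2, c1)
    logs = [
        _lchoose(r1, x) + _lchoose(r2, c1 - x) + x * log_psi for x in sup
    ]
    m = max(logs)
    w = [math.exp(v - m) for v in logs]
    tot = sum(w)
    return sum(x * wi for x, wi in zip(sup, w)) / tot


def _conditional_mle_or(a: int, r1: int, r2: int, c1: int) -> float:
    """Conditional MLE of the odds ratio: solves E_psi[X] = a by bisection
    on the log-odds (the conditional mean is strictly increasing in psi)."""
    sup = _support(r1, r2, c1)
    if len(sup) == 1:
        return math.nan  # degenerate margin: OR not identifiable
    if a == sup.start:
        return 0.0
    if a == sup[-1]:
        return math.inf
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _cond_mean(mid, r1, r2, c1) < a:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def fisher_exact_2x2(table, alternative: Alternative = "two_sided") -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p-value follows the probability-ordering rule: it sums
    the central hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one, using a
    ``1 + 1e-7`` relative tolerance on the comparison.  One-sided
    alternatives refer to the (1,1) cell: ``'greater'`` means a larger
    (1,1) count than expected under independence.
    """
    a, b, c, d = _validate_2x2(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    sup = _support(r1, r2, c1)
    degenerate = len(sup) == 1 or r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0

    if degenerate:
        return FisherResult(
            p=1.0, or_cmle=math.nan, table=((a, b), (c, d)), alternative=alternative,
            degenerate=True,
        )

    logp = {x: _log_hypergeom_pmf(x, r1, r2, c1) for x in sup}
    p_obs = math.exp(logp[a])
    if alternative == "two_sided":
        p = sum(math.exp(lp) for lp in logp.values() if math.exp(lp) <= p_obs * FISHER_REL_TOL)
    elif alternative == "greater":
        p = sum(math.exp(logp[x]) for x in sup if x >= a)
    elif alternative == "less":
        p = sum(math.exp(logp[x]) for x in sup if x <= a)
    else:  # pragma: no cover
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(1.0, p)
    return FisherResult(
        p=p,
        or_cmle=_conditional_mle_or(a, r1, r2, c1),
        table=((a, b), (c, d)),
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test for r x 2 tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RxCResult:
    """Exact (or Monte-Carlo) Fisher independence test on an r x 2 table."""

    p: float
    method: Literal["exact", "monte_carlo"]
    se: Optional[float] = None
    n_tables: Optional[int] = None


def _rx2_log_prob(xs: Sequence[int], rows: Sequence[int], c1: int, n: int) -> float:
    lp = -_lchoose(n, c1)
    for x, r in zip(xs, rows):
        lp += _lchoose(r, x)
    return lp


def _count_rx2_tables(rows: Sequence[int], c1: int) -> int:
    # number of non-negative integer vectors x with x_i <= rows_i, sum = c1
    counts = {0: 1}
    for r in rows:
        nxt: dict[int, int] = {}
        for s, cnt in counts.items():
            for x in range(0, min(r, c1 - s) + 1):
                nxt[s + x] = nxt.get(s + x, 0) + cnt
        counts = nxt
    return counts.get(c1, 0)


def fisher_exact_rxc(
    table,
    exact_limit: int = 1_000_000,
    mc_reps: int = 100_000,
    seed: Optional[int] = None,
) -> RxCResult:
    """Fisher's exact test of independence on an r x 2 contingency table.

    Enumerates every table sharing the observed margins when their number
    is at most ``exact_limit``; otherwise estimates the p-value by
    Monte-Carlo sampling from the margin-conditional (multivariate
    hypergeometric) null, reporting the estimate's standard error.
    All-zero rows are dropped (they carry no information).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("table must be r x 2 with r >= 1")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("table entries must be non-negative integers")
    arr = arr[arr.sum(axis=1) > 0].astype(int)
    if arr.shape[0] < 2:
        return RxCResult(p=1.0, method="exact", n_tables=1)
    rows = arr.sum(axis=1).tolist()
    c1 = int(arr[:, 0].sum())
    n = int(arr.sum())
    obs = arr[:, 0].tolist()
    lp_obs = _rx2_log_prob(obs, rows, c1, n)
    cutoff = lp_obs + math.log(FISHER_REL_TOL)

    n_tab = _count_rx2_tables(rows, c1)
    if n_tab <= exact_limit:
        total = 0.0
        xs = [0] * len(rows)

        def rec(i: int, remaining: int) -> None:
            nonlocal total
            if i == len(rows) - 1:
                if remaining <= rows[i]:
                    xs[i] = remaining
                    lp = _rx2_log_prob(xs, rows, c1, n)
                    if lp <= cutoff:
                        total += math.exp(lp)
                return
            tail_cap = sum(rows[i + 1:])
            for x in range(max(0, remaining - tail_cap), min(rows[i], remaining) + 1):
                xs[i] = x
                rec(i + 1, remaining - x)

        rec(0, c1)
        return RxCResult(p=min(1.0, total), method="exact", n_tables=n_tab)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(rows, c1, size=mc_reps)
    hits = 0
    for row in draws:
        if _rx2_log_prob(row.tolist(), rows, c1, n) <= cutoff:
            hits += 1
    p_hat = hits / mc_reps
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / mc_reps)
    return RxCResult(p=p_hat, method="monte_carlo", se=se, n_tables=n_tab)


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n: int
    m: int
    ties_present: bool
    p_exact: bool = False


def _ks_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    pooled = np.concatenate([xs, ys])
    pooled.sort(kind="mergesort")
    cdf_x = np.searchsorted(np.sort(xs), pooled, side="right") / xs.size
    cdf_y = np.searchsorted(np.sort(ys), pooled, side="right") / ys.size
    return float(np.abs(cdf_x - cdf_y).max())


def _ks_exact_sf(n: int, m: int, d: float) -> float:
    """Exact P(D >= d) for tie-free samples by lattice-path counting.

    Counts monotone paths (i, j) -> (n, m) whose running ECDF gap stays
    strictly below ``d`` throughout; the complement is the tail
    probability.  Integer arithmetic on |i*m - j*n| avoids rounding."""
    t = int(round(d * n * m))  # observed sup gap on the integer lattice
    # paths must keep |i*m - j*n| <= t - 1 to stay below d
    limit = t - 1
    prev = np.zeros(m + 1, dtype=float)
    prev[0] = 1.0
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] if abs(0 * m - j * n) <= limit else 0.0
    for i in range(1, n + 1):
        cur = np.zeros(m + 1, dtype=float)
        cur[0] = prev[0] if abs(i * m) <= limit else 0.0
        for j in range(1, m + 1):
            if abs(i * m - j * n) <= limit:
                cur[j] = cur[j - 1] + prev[j]
        prev = cur
    total = math.exp(_lchoose(n + m, n))
    return max(0.0, min(1.0, 1.0 - prev[m] / total))


def _kolmogorov_sf(lam: float) -> float:
    if lam <= 0:
        return 1.0
    s = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        s += term
        if abs(term) < 1e-12:
            break
    return max(0.0, min(1.0, s))


def ks_two_sample(xs: Iterable[float], ys: Iterable[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    ``D`` is the supremum gap between the two empirical CDFs evaluated at
    every pooled data point.  The p-value is exact (lattice-path
    enumeration) for tie-free samples with ``n*m <= 10_000``; otherwise the
    asymptotic Kolmogorov series is used and, when ties are present, the
    result is flagged approximate via ``ties_present``.
    """
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    d = _ks_statistic(x, y)
    n, m = int(x.size), int(y.size)
    if not ties and n * m <= 10_000:
        p = _ks_exact_sf(n, m, d)
        exact = True
    else:
        en = math.sqrt(n * m / (n + m))
        p = _kolmogorov_sf((en + 0.12 + 0.11 / en) * d)
        exact = False
    return KSResult(D=d, p=p, n=n, m=m, ties_present=ties, p_exact=exact)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    n_items: int


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Cohen's chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the agreement expected from the raters' marginal frequencies.
    Returns kappa = 1 when both raters agree perfectly even if p_e = 1.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label lists must have equal length")
    if not a:
        raise ValueError("label lists must be non-empty")
    n = len(a)
    p_o = sum(1 for u, v in zip(a, b) if u == v) / n
    cats = sorted(set(a) | set(b), key=repr)
    fa = {c: 0 for c in cats}
    fb = {c: 0 for c in cats}
    for u in a:
        fa[u] += 1
    for v in b:
        fb[v] += 1
    p_e = sum(fa[c] * fb[c] for c in cats) / (n * n)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, p_observed=p_o, p_expected=p_e, n_items=n)
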