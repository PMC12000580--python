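"""Exact contingency-table and rank statistics, from first principles.

Implements the inference toolbox used for centriole phenotype scoring:
the two-sided Fisher exact test (2x2 by hypergeometric enumeration; r x c
by full enumeration over tables with the observed margins, falling back
to seeded Monte Carlo for large totals), the two-sided unpaired Wilcoxon
rank-sum test (exact permutation enumeration for small samples, normal
approximation with tie-corrected variance and continuity correction
otherwise), and five-number box summaries with 10th/90th-percentile
whiskers.

Everything here is deliberately self-contained — scipy is used only for
ranking and the library implementations serve as independent oracles in
the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ContingencyTable",
    "TestResult",
    "BoxSummary",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "box_summary",
]

# relative slack when comparing table probabilities, as in R's fisher.test
_REL_EPS = 1e-7


@dataclass
class ContingencyTable:
    """Non-negative integer r x c table with optional labels."""

    counts: np.ndarray
    row_labels: Optional[Sequence[str]] = None
    col_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2:
            raise ValueError("table must be 2-dimensional")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)):
                raise ValueError("table entries must be integers")
            a = np.round(a).astype(int)
        if (a < 0).any():
            raise ValueError("table entries must be non-negative")
        if (a.sum(axis=1) == 0).any() or (a.sum(axis=0) == 0).any():
            raise ValueError("every row and column needs a positive margin")
        self.counts = a


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    mc_reps: Optional[int] = None
    mc_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class BoxSummary:
    """Median, quartiles and 10th/90th percentile whiskers."""

    median: float
    q1: float
    q3: float
    p10: float
    p90: float
    n: int


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray, lg_margins: float, lg_n: float) -> float:
    # P(T) = prod(ri!) prod(cj!) / (N! prod(nij!)) under fixed margins
    return lg_margins - lg_n - sum(math.lgamma(v + 1) for v in table.ravel())


def _fisher_2x2(a: np.ndarray, two_sided_method: str) -> Tuple[float, float]:
    r1, r2 = int(a[0].sum()), int(a[1].sum())
    c1 = int(a[:, 0].sum())
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    k_obs = int(a[0, 0])
    p_obs = probs[k_obs]
    if two_sided_method == "sum_smaller":
        p = sum(p for p in probs.values() if p <= p_obs * (1 + _REL_EPS))
    elif two_sided_method == "double_tail":
        low = sum(p for k, p in probs.items() if k <= k_obs)
        high = sum(p for k, p in probs.items() if k >= k_obs)
        p = min(1.0, 2 * min(low, high))
    else:
        raise ValueError(f"unknown two-sided method {two_sided_method!r}")
    # sample odds ratio as the reported statistic
    b, c, d = a[0, 1], a[1, 0], a[1, 1]
    if c * b == 0:
        stat = math.inf if k_obs * d > 0 else math.nan
    else:
        stat = (k_obs * d) / (b * c)
    return stat, min(1.0, p)


def _enumerate_tables(row_margins: Sequence[int], col_margins: Sequence[int]):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_margins), len(col_margins)

    def fill(row: int, cols_left: List[int], rows: List[List[int]]):
        if row == r - 1:
            if all(v >= 0 for v in cols_left) and sum(cols_left) == row_margins[row]:
                yield rows + [list(cols_left)]
            return
        target = row_margins[row]

        def fill_row(j: int, remaining: int, current: List[int]):
            if j == c - 1:
                if 0 <= remaining <= cols_left[j]:
                    yield current + [remaining]
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                yield from fill_row(j + 1, remaining - v, current + [v])

        for filled in fill_row(0, target, []):
            new_left = [cl - v for cl, v in zip(cols_left, filled)]
            yield from fill(row + 1, new_left, rows + [filled])

    yield from fill(0, list(col_margins), [])


def fisher_exact(
    table,
    mc_reps: Optional[int] = None,
    seed: Optional[int] = None,
    two_sided_method: str = "sum_smaller",
    enumeration_limit: int = 200,
) -> TestResult:
    """Two-sided Fisher exact test of independence.

    The two-sided p-value sums the probabilities of all tables with the
    observed margins that are at most as probable as the observed table
    (the R convention; ``two_sided_method='double_tail'`` doubles the
    smaller tail instead, 2x2 only).  r x c tables with grand total up to
    ``enumeration_limit`` are fully enumerated; larger tables use seeded
    Monte Carlo over margin-preserving permutations (``mc_reps`` draws,
    default 10000) with the add-one p-value estimator.
    """
    ct = table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))
    a = ct.counts
    if a.shape == (2, 2):
        stat, p = _fisher_2x2(a, two_sided_method)
        return TestResult(stat, p, "Fisher exact (2x2)", exact=True)
    if two_sided_method != "sum_smaller":
        raise ValueError("double_tail convention is defined for 2x2 tables only")
    row_m = [int(v) for v in a.sum(axis=1)]
    col_m = [int(v) for v in a.sum(axis=0)]
    n = int(a.sum())
    lg_margins = sum(math.lgamma(v + 1) for v in row_m + col_m)
    lg_n = math.lgamma(n + 1)
    logp_obs = _log_table_prob(a, lg_margins, lg_n)
    cutoff = logp_obs + math.log1p(_REL_EPS)
    if mc_reps is None and n <= enumeration_limit:
        total = 0.0
        for t in _enumerate_tables(row_m, col_m):
            lp = _log_table_prob(np.asarray(t), lg_margins, lg_n)
            if lp <= cutoff:
                total += math.exp(lp)
        return TestResult(float(logp_obs), min(1.0, total), "Fisher exact (r x c, enumeration)", exact=True)
    reps = mc_reps if mc_reps is not None else 10000
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(row_m)), row_m)
    cols = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(cols)
        t = np.zeros_like(a)
        np.add.at(t, (rows, perm), 1)
        if _log_table_prob(t, lg_margins, lg_n) <= cutoff:
            hits += 1
    p = (hits + 1) / (reps + 1)
    return TestResult(
        float(logp_obs), min(1.0, p), "Fisher exact (r x c, Monte Carlo)",
        exact=False, mc_reps=reps, mc_seed=seed,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(ranks: np.ndarray, m: int, w_obs: float) -> float:
    n_tot = ranks.size
    mu = m * (n_tot + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-12
    count = 0
    total = 0
    for idx in itertools.combinations(range(n_tot), m):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev:
            count += 1
    return count / total


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sided unpaired Wilcoxon (Mann-Whitney) rank-sum test.

    Mid-ranks are assigned to ties.  ``mode='exact'`` enumerates the
    permutation distribution of the rank sum (automatic for m + n <= 12
    with no ties); ``'normal_approx'`` uses the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.  The reported
    statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    m, n = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined, method="average")
    w = float(ranks[:m].sum())
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        mode = "exact" if (m + n <= 12 and not has_ties) else "normal_approx"
    if mode == "exact":
        p = _exact_rank_sum_p(ranks, m, w)
        return TestResult(w, min(1.0, p), "Wilcoxon rank-sum (exact)", exact=True)
    if mode != "normal_approx":
        raise ValueError(f"unknown mode {mode!r}")
    n_tot = m + n
    mu = m * (n_tot + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n_tot * (n_tot - 1))
    var = m * n / 12.0 * ((n_tot + 1) - tie_term)
    if var <= 0:  # all values identical
        return TestResult(w, 1.0, "Wilcoxon rank-sum (normal approximation)", exact=False)
    dev = abs(w - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(var)
    p = math.erfc(z / math.sqrt(2.0))
    return TestResult(w, min(1.0, p), "Wilcoxon rank-sum (normal approximation)", exact=False)


# ---------------------------------------------------------------------------
# box summaries
# ---------------------------------------------------------------------------


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number summary with 10th/90th-percentile whiskers.

    Percentiles use linear interpolation between order statistics
    (the type-7 convention, numpy's default).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        p10=float(p10), p90=float(p90), n=int(v.size),
    )
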