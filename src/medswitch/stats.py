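"""Rank statistics for comparing and trending switching-rate series.

Two statistics are provided, both tie-aware via midranks:

* :func:`mann_whitney` — the two-sample rank-sum test reported as ``W``, the
  sum of pooled ranks of the first group, with an exact permutation p-value
  for small samples (enumeration of all ways to assign the pooled ranks to
  group A) and a tie-corrected normal approximation otherwise.
* :func:`spearman_trend` — Spearman's rank correlation of a rate series
  against time order, with a permutation p-value (full enumeration for short
  series, seeded Monte-Carlo otherwise).

Two-sided p-values double the smaller tail, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

# exact enumeration is used whenever the number of rank assignments is modest;
# this always covers pooled samples of size <= 16 (C(16, 8) = 12870)
_EXACT_MAX_ASSIGNMENTS = 200_000


@dataclass(frozen=True)
class RankTestResult:
    W: float            #: sum of pooled midranks of group A
    U: float            #: W - n_A(n_A+1)/2
    p_value: float
    method: str         #: "exact-permutation" or "normal-approx"
    n_A: int
    n_B: int


@dataclass(frozen=True)
class TrendResult:
    rho: float
    n: int
    p_value: float
    method: str         #: "exact-permutation" or "mc-permutation"
    degenerate: bool = False


def _exact_tail_probs(ranks: np.ndarray, n_a: int, w_obs: float) -> tuple[float, float]:
    """P(W <= w_obs) and P(W >= w_obs) over all assignments of ranks to A."""
    n = len(ranks)
    le = ge = total = 0
    eps = 1e-9
    for comb in combinations(range(n), n_a):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return le / total, ge / total


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
) -> RankTestResult:
    """Rank-sum comparison of two samples; ``W`` is for the group passed first.

    ``method`` is ``"auto"`` (exact when the enumeration is small enough,
    which always includes pooled sizes up to 16), ``"exact"``, or
    ``"normal"``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    w = float(ranks[:n_a].sum())
    u = w - n_a * (n_a + 1) / 2.0

    if method == "auto":
        method = "exact" if math.comb(n, n_a) <= _EXACT_MAX_ASSIGNMENTS else "normal"
    if method == "exact":
        p_le, p_ge = _exact_tail_probs(ranks, n_a, w)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(w, u, p, "exact-permutation", n_a, n_b)
    if method != "normal":
        raise ValueError("method must be 'auto', 'exact' or 'normal'")

    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations tied
        return RankTestResult(w, u, 1.0, "normal-approx", n_a, n_b)
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)  # continuity-corrected
    p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
    return RankTestResult(w, u, p, "normal-approx", n_a, n_b)


def _perm_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two (mid)rank vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum()) * float((ry**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_trend(
    periods: Sequence,
    rates: Sequence[float],
    n_mc: int = 20_000,
    seed: int = 0,
) -> TrendResult:
    """Spearman rank correlation of ``rates`` against the order of ``periods``.

    ``periods`` is an ordered sequence of labels (assumed strictly
    increasing, so its ranks are 1..n); rates are midranked.  The two-sided
    p-value is computed by full permutation of the rate ranks for n <= 8 and
    by seeded Monte-Carlo permutation otherwise.  A constant rate vector has
    no defined rank correlation and is returned flagged as degenerate.
    """
    y = np.asarray(rates, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points for a trend")
    if len(periods) != n:
        raise ValueError("periods and rates must have equal length")
    rx = np.arange(1.0, n + 1.0)
    ry = rankdata(y, method="average")
    rho = _perm_rho(rx, ry)
    if math.isnan(rho):
        return TrendResult(float("nan"), n, float("nan"), "exact-permutation", True)

    eps = 1e-12
    if n <= 8:
        count = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_perm_rho(rx, np.asarray(perm))) >= abs(rho) - eps:
                count += 1
        return TrendResult(rho, n, count / total, "exact-permutation", False)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        if abs(_perm_rho(rx, rng.permutation(ry))) >= abs(rho) - eps:
            count += 1
    return TrendResult(rho, n, (1 + count) / (1 + n_mc), "mc-permutation", False)
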