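"""Set-overlap and enrichment statistics with log-space extreme p-values.

Genome-scale overlap tests routinely produce p-values below the double floor
(the kind of quantity printed as p < 1e-320), so every tail probability here is
accumulated in log space from log-pmfs and reported both as ``p`` (which may
underflow to 0.0) and ``log10_p`` (which never does for finite inputs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp


@dataclass(frozen=True)
class OverlapTest:
    """One-tailed hypergeometric overlap test between two gene sets."""

    universe_size: int
    setA_size: int
    setB_size: int
    overlap: int
    p_over: float
    p_under: float
    log10_p_over: float
    log10_p_under: float
    fold: float


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    n_target_in_category: int
    expected: float
    fold_enrichment: float
    p_raw: float
    log10_p_raw: float
    p_bonferroni: float


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Overlap of a size-K and a size-n set in a size-N universe, observed k.

    p_over = P[X >= k] and p_under = P[X <= k] for X ~ Hypergeom(N, K, n),
    both summed in log space so values far below the double floor survive.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    lo, hi = max(0, K + n - N), min(K, n)
    if not (lo <= k <= hi):
        raise ValueError(f"overlap k={k} outside feasible range [{lo}, {hi}]")
    support_hi = np.arange(k, hi + 1)
    support_lo = np.arange(lo, k + 1)
    log_p_over = float(logsumexp(sps.hypergeom.logpmf(support_hi, N, K, n)))
    log_p_under = float(logsumexp(sps.hypergeom.logpmf(support_lo, N, K, n)))
    log_p_over = min(log_p_over, 0.0)
    log_p_under = min(log_p_under, 0.0)
    expected = K * n / N if N > 0 else math.nan
    return OverlapTest(
        universe_size=N,
        setA_size=K,
        setB_size=n,
        overlap=k,
        p_over=math.exp(log_p_over),
        p_under=math.exp(log_p_under),
        log10_p_over=log_p_over / math.log(10),
        log10_p_under=log_p_under / math.log(10),
        fold=k / expected if expected > 0 else math.inf,
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-tailed Fisher exact test on a 2x2 table with a Woolf log-interval CI.

    The two-tailed p sums all tables (with the observed margins) whose
    probability does not exceed the observed table's. The odds ratio is the
    sample ratio ad/bc; if any cell is 0 the Haldane-Anscombe 0.5 correction is
    applied to the ratio and CI (flagged), while p stays exact.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in cells
    if haldane:
        a, b, c, d = (x + 0.5 for x in cells)
    odds_ratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(odds_ratio)
    z = sps.norm.ppf(0.975)
    return FisherResult(
        odds_ratio=odds_ratio,
        p=float(p),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        haldane_corrected=haldane,
    )


def binomial_enrichment(
    target: set[str],
    categories: Mapping[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """One-tailed binomial over-representation of each category in ``target``.

    expected = |target| * |category ∩ background| / |background|;
    p_raw = P[Bin(|target|, proportion) >= observed]; Bonferroni over the
    categories actually tested in this call. Categories may be arbitrary set
    algebra over gene sets (e.g. "cell cycle minus meiotic cell cycle") —
    they are plain sets by the time they arrive here.
    """
    if not background:
        raise ValueError("background set is empty")
    if not target <= background:
        raise ValueError("target must be a subset of background")
    m = len(categories)
    n = len(target)
    results = []
    for name, members in categories.items():
        in_bg = len(members & background)
        prop = in_bg / len(background)
        observed = len(target & members)
        expected = n * prop
        if prop == 0.0:
            log_p = 0.0 if observed == 0 else -math.inf
        else:
            support = np.arange(observed, n + 1)
            log_p = min(float(logsumexp(sps.binom.logpmf(support, n, prop))), 0.0)
        p_raw = math.exp(log_p)
        results.append(
            EnrichmentResult(
                category=name,
                n_target_in_category=observed,
                expected=expected,
                fold_enrichment=observed / expected if expected > 0 else math.inf,
                p_raw=p_raw,
                log10_p_raw=log_p / math.log(10),
                p_bonferroni=min(1.0, m * p_raw),
            )
        )
    return results


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U for x: pairs where x > y, ties counted half.
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


_EXACT_TOTAL = 16  # exact permutation enumeration up to |x| + |y| of this size


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of x against y; returns (U for x, p).

    ``alternative`` refers to x: "greater" tests whether x tends to exceed y.
    (A one-tailed test that y exceeds x is ``alternative="less"``.) Small
    samples (|x| + |y| <= 16) use exact enumeration of group assignments,
    which handles ties naturally; larger samples use the tie- and
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    u_obs = _u_statistic(x, y)
    if x.size + y.size <= _EXACT_TOTAL:
        pooled = np.concatenate([x, y])
        n = x.size
        idx = range(pooled.size)
        us = np.array(
            [
                _u_statistic(pooled[list(comb)], np.delete(pooled, list(comb)))
                for comb in itertools.combinations(idx, n)
            ]
        )
        eps = 1e-9
        p_greater = float(np.mean(us >= u_obs - eps))
        p_less = float(np.mean(us <= u_obs + eps))
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
    return u_obs, p


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def spearman_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a seeded permutation p-value.

    p = (1 + #{permutations with |rho*| >= |rho|}) / (1 + n_permutations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(rng)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(zx * zy))
    n_extreme = 0
    for _ in range(n_permutations):
        rho_perm = float(np.mean(zx * rng.permutation(zy)))
        if abs(rho_perm) >= abs(rho) - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (1 + n_permutations)
    return rho, p
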