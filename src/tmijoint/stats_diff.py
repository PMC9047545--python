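"""Rank-based two-sample testing, FDR control and benchmark metrics.

The Mann-Whitney U statistic is computed from mid-rank sums:

    U_A = N_A*N_B + N_A*(N_A+1)/2 - T_A
    U_B = N_A*N_B + N_B*(N_B+1)/2 - T_B

so that U_A + U_B = N_A*N_B always holds. P-values use exact enumeration
(dynamic-programming count over rank arrangements) when both samples have
fewer than 20 observations and there are no ties, and a tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class TwoSampleResult:
    U_A: float
    U_B: float
    U: float
    T_A: float
    T_B: float
    p_value: float
    method: str  # {"exact", "normal_approx"}


@lru_cache(maxsize=None)
def _exact_u_counts(n_a: int, n_b: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each value of U_A (no ties).

    Classic recursion c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u) over all
    C(n_a+n_b, n_a) equally likely arrangements.
    """
    max_u = n_a * n_b
    # dp[m][u] for current n; build up n from 0
    dp = np.zeros((n_b + 1, max_u + 1), dtype=object)
    dp[:, 0] = 1
    for n in range(1, n_a + 1):
        new = np.zeros_like(dp)
        for m in range(n_b + 1):
            for u in range(max_u + 1):
                total = dp[m][u - m] if u >= m else 0
                if m >= 1:
                    total += new[m - 1][u]
                new[m][u] = total
        dp = new
    return tuple(int(v) for v in dp[n_b])


def _exact_two_sided_p(u_min: float, n_a: int, n_b: int) -> float:
    counts = _exact_u_counts(n_a, n_b)
    total = sum(counts)
    k = int(math.floor(u_min + 1e-12))
    lower = sum(counts[: k + 1])
    return min(1.0, 2.0 * lower / total)


def _exact_two_sided_p_ties(u_min: float, ranks: np.ndarray, n_a: int) -> float:
    """Exact p with ties: enumerate every assignment of the observed mid-ranks
    to group A. Feasible only for small samples (C(n, n_a) arrangements)."""
    from itertools import combinations

    n = ranks.size
    n_b = n - n_a
    count = total = 0
    base = n_a * n_b + n_a * (n_a + 1) / 2.0
    for combo in combinations(range(n), n_a):
        t_a = float(ranks[list(combo)].sum())
        u_a = base - t_a
        total += 1
        if min(u_a, n_a * n_b - u_a) <= u_min + 1e-9:
            count += 1
    return min(1.0, count / total)


def mann_whitney_u(
    a, b, mode: str = "auto", continuity: bool = True
) -> TwoSampleResult:
    """Two-sided Mann-Whitney U test with mid-ranks for ties.

    ``mode`` selects the p-value branch: "exact" enumerates the null
    distribution of U (recursion without ties, full arrangement enumeration
    with ties — small samples only), "normal" uses the tie-corrected Gaussian
    approximation, "auto" picks exact when both N < 20 and the pooled data
    has no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks for ties
    t_a = float(ranks[:n_a].sum())
    t_b = float(ranks[n_a:].sum())
    u_a = n_a * n_b + n_a * (n_a + 1) / 2.0 - t_a
    u_b = n_a * n_b + n_b * (n_b + 1) / 2.0 - t_b
    u = min(u_a, u_b)

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (n_a < 20 and n_b < 20 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            if math.comb(n_a + n_b, n_a) > 200_000:
                raise ValueError(
                    "exact p-value with ties requires full enumeration; "
                    "samples too large — use mode='normal'"
                )
            p = _exact_two_sided_p_ties(u, ranks, n_a)
        else:
            p = _exact_two_sided_p(u, n_a, n_b)
        method = "exact"
    elif mode == "normal":
        n = n_a + n_b
        mu = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 if continuity else 0.0
            z = (u - mu + cc) / math.sqrt(var)
            p = min(1.0, 2.0 * norm.cdf(z))
        method = "normal_approx"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TwoSampleResult(u_a, u_b, u, t_a, t_b, p, method)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_table(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "auto",
    pct_denominator: str = "min",
) -> pd.DataFrame:
    """Per-feature Mann-Whitney + BH-FDR comparison of two sample groups.

    ``group_a``/``group_b`` are samples x features (e.g. normal vs tumor).
    Direction is "up" when the group_b mean exceeds the group_a mean. The
    percent difference divides |mean_b - mean_a| by the smaller group mean
    (``pct_denominator='min'``, which can exceed 100%), or by the group_a
    mean (``'a'``) or the larger mean (``'max'``).
    """
    features = [f for f in group_a.columns if f in set(group_b.columns)]
    if not features:
        raise ValueError("no shared features between groups")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for feat in features:
        a = group_a[feat].to_numpy(dtype=float)
        b = group_b[feat].to_numpy(dtype=float)
        constant = np.unique(np.concatenate([a, b])).size == 1
        if constant:
            u_stat, p = float(a.size * b.size / 2.0), 1.0
        else:
            res = mann_whitney_u(a, b, mode=mode)
            u_stat, p = res.U, res.p_value
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if pct_denominator == "min":
            denom = min(mean_a, mean_b)
        elif pct_denominator == "max":
            denom = max(mean_a, mean_b)
        elif pct_denominator == "a":
            denom = mean_a
        else:
            raise ValueError(f"unknown pct_denominator {pct_denominator!r}")
        pct = abs(mean_b - mean_a) / denom * 100.0 if denom > 0 else float("nan")
        rows.append(
            {
                "feature": feat,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "U": u_stat,
                "p": p,
                "direction": "up" if mean_b > mean_a else "down",
                "pct_diff": pct,
                "constant": constant,
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table[
        ["mean_a", "mean_b", "U", "p", "q", "direction", "pct_diff", "significant", "constant"]
    ]


def benchmark_metrics(truth, estimate) -> dict[str, float]:
    """RMSE, Pearson r and Spearman rs between a truth and an estimate vector.

    Spearman is Pearson applied to mid-ranked data. Correlations against a
    constant vector are undefined and reported as NaN with a warning.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("truth and estimate must be equal-length vectors (n >= 2)")
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))

    def _pearson(x: np.ndarray, y: np.ndarray) -> float:
        xd, yd = x - x.mean(), y - y.mean()
        denom = math.sqrt((xd**2).sum() * (yd**2).sum())
        if denom == 0:
            warnings.warn("correlation undefined for constant vector", stacklevel=3)
            return float("nan")
        return float((xd * yd).sum() / denom)

    return {
        "rmse": rmse,
        "pearson_r": _pearson(t, e),
        "spearman_rs": _pearson(rankdata(t), rankdata(e)),
    }
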