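"""Spearman rank correlation with exact small-sample p-values.

The tumour-cohort analyses correlate miRNA expression with a hypoxia marker
(CAIX staining percentage, n = 13) and with patient survival (n = 11). At
these sample sizes the Student-t approximation to Spearman's rho is rough, so
the exact two-sided p is computed from the full permutation distribution of
the rank statistic D = sum of squared rank differences. The distribution is
built by a dynamic program over subsets of assigned ranks (feasible through
n = 12) rather than naive enumeration of n! permutations.

Ties receive average ranks and rho is then the Pearson correlation of the
rank vectors, which reduces to the classic shortcut rho = 1 − 6*D/(n(n²−1))
in the tie-free case; the exact p is only defined for tie-free data.
"""

from __future__ import annotations

import dataclasses
import functools
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "spearman_test",
    "correlate_features_with_outcome",
    "ranks_with_sum_d2",
]

EXACT_MAX_N = 12


@dataclasses.dataclass
class CorrelationResult:
    """Spearman correlation of one variable pair.

    ``sum_d2`` is reported only on the tie-free path, where
    rho = 1 − 6·sum_d2/(n(n²−1)) holds exactly.
    """

    rho: float
    n: int
    sum_d2: float | None = None
    p: float | None = None
    method: str | None = None
    tie_corrected: bool = False


def _ranks(x: np.ndarray) -> tuple[np.ndarray, bool]:
    r = stats.rankdata(x, method="average")
    return r, len(np.unique(x)) < len(x)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho with average ranks for ties; no p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman's rho is undefined")
    rx, tx = _ranks(x)
    ry, ty = _ranks(y)
    tied = tx or ty
    rho = float(np.corrcoef(rx, ry)[0, 1])
    sum_d2 = None if tied else float(((rx - ry) ** 2).sum())
    return CorrelationResult(rho=rho, n=n, sum_d2=sum_d2, tie_corrected=tied)


@functools.lru_cache(maxsize=None)
def sum_d2_distribution(n: int) -> np.ndarray:
    """Counts of permutations of 1..n by D = sum_i (i − pi(i))².

    Returned array ``c`` has ``c[d]`` = number of permutations with D = d,
    d = 0 .. n(n²−1)/3; the counts sum to n!.
    Built by a subset dynamic program: positions are filled in order and the
    state is the set of ranks already used.
    """
    if not 1 <= n <= EXACT_MAX_N:
        raise ValueError(f"exact distribution supported for 1 <= n <= {EXACT_MAX_N}")
    max_d = n * (n * n - 1) // 3
    size = max_d + 1
    table: list[np.ndarray | None] = [None] * (1 << n)
    start = np.zeros(size, dtype=np.int64)
    start[0] = 1
    table[0] = start
    masks_by_count: list[list[int]] = [[] for _ in range(n + 1)]
    for mask in range(1 << n):
        masks_by_count[bin(mask).count("1")].append(mask)
    for k in range(n):
        for mask in masks_by_count[k]:
            arr = table[mask]
            if arr is None:
                continue
            for j in range(n):
                if mask >> j & 1:
                    continue
                d = (k - j) * (k - j)
                nxt = mask | (1 << j)
                if table[nxt] is None:
                    table[nxt] = np.zeros(size, dtype=np.int64)
                if d:
                    table[nxt][d:] += arr[:-d]
                else:
                    table[nxt] += arr
            table[mask] = None  # free as we go
    return table[(1 << n) - 1]


def _exact_two_sided_p(n: int, d_obs: float) -> float:
    counts = sum_d2_distribution(n)
    total = counts.sum()
    d_obs = int(round(d_obs))
    mean_d = n * (n * n - 1) / 6.0  # D at rho = 0
    if d_obs <= mean_d:
        tail = counts[: d_obs + 1].sum() / total  # towards positive rho
    else:
        tail = counts[d_obs:].sum() / total  # towards negative rho
    return float(min(1.0, 2.0 * tail))


def spearman_test(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> CorrelationResult:
    """Spearman's rho with a two-sided p-value.

    ``method``: ``exact`` enumerates the permutation distribution of D
    (tie-free data, n ≤ 12 only); ``approx`` uses the Student-t statistic
    t = rho·sqrt((n−2)/(1−rho²)) with n−2 df; ``auto`` picks exact whenever
    admissible. Two-sided p is min(1, 2 × one-sided tail) with the observed
    D included in its tail.
    """
    if method not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown method {method!r}")
    result = spearman_rho(x, y)
    exact_ok = (not result.tie_corrected) and result.n <= EXACT_MAX_N
    if method == "exact" and not exact_ok:
        raise ValueError(
            "exact p requires tie-free data with n <= "
            f"{EXACT_MAX_N}; use method='approx'"
        )
    use_exact = exact_ok if method == "auto" else method == "exact"
    if use_exact:
        result.p = _exact_two_sided_p(result.n, result.sum_d2)
        result.method = "exact"
    else:
        rho, n = result.rho, result.n
        if 1.0 - rho * rho <= 0:
            result.p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            result.p = float(2.0 * stats.t.sf(abs(t), n - 2))
        result.method = "t-approx"
    return result


def correlate_features_with_outcome(
    matrix,
    outcome: Sequence[float],
    method: str = "auto",
    adjust: bool = False,
) -> pd.DataFrame:
    """Feature-wise Spearman correlation of an expression matrix against a
    per-sample outcome, with optional BH adjustment across features."""
    outcome = np.asarray(outcome, dtype=float)
    if len(outcome) != matrix.n_samples:
        raise ValueError("outcome must be defined on all samples")
    rows = []
    for i, fid in enumerate(matrix.feature_ids):
        res = spearman_test(matrix.values[i], outcome, method=method)
        rows.append((fid, res.rho, res.n, res.p, res.method))
    df = pd.DataFrame(rows, columns=["feature_id", "rho", "n", "p", "method"])
    if adjust:
        from .feature_lm import bh_adjust

        df["q"] = bh_adjust(df["p"].tolist())
    return df


def ranks_with_sum_d2(n: int, target: int) -> tuple[list[int], list[int]]:
    """Construct tie-free rank vectors (x = 1..n, y a permutation) with the
    given sum of squared rank differences.

    Used to reconstruct data consistent with a printed rho via the shortcut
    formula. Deterministic depth-first search with min/max achievable-D
    pruning; raises if no permutation attains ``target``.
    """
    max_d = n * (n * n - 1) // 3
    if not 0 <= target <= max_d or target % 2:
        raise ValueError(f"sum_d2 must be even and in [0, {max_d}], got {target}")

    def bounds(pos: int, remaining: list[int]) -> tuple[int, int]:
        positions = list(range(pos, n + 1))
        asc = sorted(remaining)
        lo = sum((p - v) ** 2 for p, v in zip(positions, asc))
        hi = sum((p - v) ** 2 for p, v in zip(positions, reversed(asc)))
        return lo, hi

    y: list[int] = []

    def search(pos: int, acc: int, remaining: list[int]) -> bool:
        if pos > n:
            return acc == target
        for v in list(remaining):
            nxt = acc + (pos - v) ** 2
            if nxt > target:
                continue
            rest = [r for r in remaining if r != v]
            if rest:
                lo, hi = bounds(pos + 1, rest)
                if not (lo <= target - nxt <= hi):
                    continue
            y.append(v)
            if search(pos + 1, nxt, rest):
                return True
            y.pop()
        return False

    if not search(1, 0, list(range(1, n + 1))):
        raise ValueError(f"no permutation of 1..{n} attains sum_d2 = {target}")
    return list(range(1, n + 1)), y
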