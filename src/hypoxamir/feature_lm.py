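"""Per-feature linear models against oxygen tension, fold changes, FDR
adjustment, and the two-group tissue comparison.

Each feature's log2 expression is regressed on the ordinal oxygen covariate
(0 = 20.9%, 1 = 1%, 2 = 0.2%) plus cell line as a categorical nuisance term,
by ordinary least squares; the two-sided t-test on the oxygen coefficient
identifies features associated with oxygen tension after allowing for cell
line. The in vitro screen uses raw p < 0.05 (as the panel analysis did); the
tissue responder/non-responder comparison uses Welch's t with
Benjamini-Hochberg adjustment.

Alternative oxygen codings (`percent`, `log-percent`) are offered because an
ordinal recoding and the literal tension percentages span the same design
column space only up to affine equivalence — with three unequally spaced
tensions they give different slopes and p-values, and the choice is surfaced
as a flag rather than silently resolved.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, SampleMetadata

__all__ = [
    "FeatureModelResult",
    "fit_feature_models",
    "fold_changes_vs_reference",
    "bh_adjust",
    "differential_groups",
    "format_significant_fraction",
    "significant_fraction_pct",
    "results_frame",
]

_DEGENERATE_TOL = 1e-18


@dataclasses.dataclass
class FeatureModelResult:
    """Per-feature regression summary.

    ``beta_oxygen`` is the slope on the oxygen covariate (log2 units per
    ordinal step under the default coding); ``log2fc`` maps each non-reference
    oxygen percentage to the group-mean log2 fold change versus 20.9%.
    """

    feature_id: str
    beta_oxygen: float
    se: float
    tstat: float
    p: float
    log2fc: dict[float, float]
    significant: bool
    degenerate: bool = False


def _oxygen_covariate(meta: Sequence[SampleMetadata], coding: str) -> np.ndarray:
    if coding == "ordinal":
        return np.array([m.oxygen_code for m in meta], dtype=float)
    if coding == "percent":
        return np.array([m.oxygen_pct for m in meta], dtype=float)
    if coding == "log-percent":
        return np.log2([m.oxygen_pct for m in meta])
    raise ValueError(f"unknown oxygen coding {coding!r}")


def _design(meta: Sequence[SampleMetadata], coding: str) -> tuple[np.ndarray, list[str]]:
    tension = _oxygen_covariate(meta, coding)
    lines = sorted({m.cell_line for m in meta})
    cols = [np.ones(len(meta)), tension]
    names = ["intercept", f"oxygen[{coding}]"]
    for line in lines[1:]:  # first level is the baseline
        cols.append(np.array([1.0 if m.cell_line == line else 0.0 for m in meta]))
        names.append(f"cell_line[{line}]")
    return np.column_stack(cols), names


def fit_feature_models(
    matrix: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    alpha: float = 0.05,
    coding: str = "ordinal",
) -> list[FeatureModelResult]:
    """OLS of each feature on [intercept, oxygen covariate, cell-line dummies].

    All features share one design matrix, so the normal equations are solved
    once and applied to every feature. Features with (numerically) zero
    residual variance are flagged degenerate with p = 0.
    """
    if not matrix.is_log:
        raise ValueError("fit_feature_models expects log2-scale expression")
    if len(meta) != matrix.n_samples:
        raise ValueError("one metadata record per sample required")
    if len({m.oxygen_code for m in meta}) < 2:
        raise ValueError("need at least two oxygen tension levels")
    X, _ = _design(meta, coding)
    n, k = X.shape
    if n - k < 1:
        raise ValueError("residual degrees of freedom < 1")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design: oxygen tension confounded with cell line")

    xtx_inv = np.linalg.inv(X.T @ X)
    Y = matrix.values.T  # samples x features
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    df = n - k
    scale = np.maximum(1.0, (Y**2).sum(axis=0))
    degenerate = rss < _DEGENERATE_TOL * scale
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        tstat = np.where(se > 0, B[1] / se, np.inf * np.sign(B[1]))
    p = np.where(degenerate, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df))

    fc = fold_changes_vs_reference(matrix, meta, reference_level=max(m.oxygen_pct for m in meta))
    results = []
    for i, fid in enumerate(matrix.feature_ids):
        results.append(
            FeatureModelResult(
                feature_id=fid,
                beta_oxygen=float(B[1, i]),
                se=float(se[i]),
                tstat=float(tstat[i]),
                p=float(p[i]),
                log2fc={level: float(fc.loc[fid, level]) for level in fc.columns},
                significant=bool(p[i] < alpha),
                degenerate=bool(degenerate[i]),
            )
        )
    return results


def results_frame(results: Sequence[FeatureModelResult]) -> pd.DataFrame:
    """Tabular view of regression results, ordered by ascending p."""
    rows = []
    for r in sorted(results, key=lambda r: (r.p, r.feature_id)):
        row = {
            "feature_id": r.feature_id,
            "beta_oxygen": r.beta_oxygen,
            "se": r.se,
            "tstat": r.tstat,
            "p": r.p,
            "significant": r.significant,
        }
        for level, fc in sorted(r.log2fc.items(), reverse=True):
            row[f"log2fc_{level:g}pct"] = fc
        rows.append(row)
    return pd.DataFrame(rows)


def fold_changes_vs_reference(
    matrix: ExpressionMatrix,
    meta: Sequence[SampleMetadata],
    reference_level: float = 20.9,
) -> pd.DataFrame:
    """Group-mean log2 fold change of every oxygen level versus the reference
    (features × non-reference levels; log2 difference of group means)."""
    if not matrix.is_log:
        raise ValueError("fold changes are computed on log2-scale expression")
    levels = sorted({m.oxygen_pct for m in meta}, reverse=True)
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level} has no samples")
    means = {}
    for level in levels:
        cols = [i for i, m in enumerate(meta) if m.oxygen_pct == level]
        if not cols:
            raise ValueError(f"oxygen level {level} has no samples")
        means[level] = matrix.values[:, cols].mean(axis=1)
    out = {
        level: means[level] - means[reference_level]
        for level in levels
        if level != reference_level
    }
    return pd.DataFrame(out, index=matrix.feature_ids)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    q_(i) = p_(i)·n/i on the ascending-sorted p's, made monotone by a running
    minimum from the largest p down, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out.tolist()


def differential_groups(
    matrix: ExpressionMatrix,
    groups: Sequence[str],
    alpha: float = 0.05,
    positive_group: str | None = None,
) -> pd.DataFrame:
    """Welch two-sample t-test per feature with BH adjustment.

    ``positive_group`` names the group whose mean enters the fold change with
    a plus sign (default: "non-responder" when present, else the second
    sorted label), so FC > 0 means higher expression in that group.
    """
    if not matrix.is_log:
        raise ValueError("differential_groups expects log2-scale expression")
    groups = [str(g) for g in groups]
    if len(groups) != matrix.n_samples:
        raise ValueError("one group label per sample required")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    if positive_group is None:
        positive_group = "non-responder" if "non-responder" in levels else levels[1]
    if positive_group not in levels:
        raise ValueError(f"positive_group {positive_group!r} not among {levels}")
    other = next(l for l in levels if l != positive_group)
    a = matrix.values[:, [g == positive_group for g in groups]]
    b = matrix.values[:, [g == other for g in groups]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")

    fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(tt.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    degenerate = zero_var & (fc != 0)
    p[zero_var & (fc == 0)] = 1.0
    p[degenerate] = 0.0
    q = bh_adjust(p.tolist())
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "fold_change": fc,
            "p": p,
            "q": q,
            "significant": np.asarray(q) < alpha,
            "degenerate": degenerate,
        }
    )


def significant_fraction_pct(n_significant: int, n_total: int) -> float:
    """Percentage of significant features, rounded to one decimal place (the
    summary convention used for screen headlines, e.g. 41/1896 → 2.2)."""
    if n_total < 1 or not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total with n_total >= 1")
    return float(f"{100.0 * n_significant / n_total:.1f}")


def format_significant_fraction(n_significant: int, n_total: int) -> str:
    pct = significant_fraction_pct(n_significant, n_total)
    return f"{pct:g}% ({n_significant}/{n_total})"
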