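"""PLS-DA by NIPALS with cross-validated component selection and
factor dissection.

The screen's multivariate step supervises a partial-least-squares
discriminant model on one experimental factor (cell line) and then asks
whether any latent axis separates the samples by a *different*, unsupervised
factor (oxygen tension). Because cell-line differences dominate the variance,
an oxygen signal — if present — appears on a later axis once the supervised
axes have absorbed the cell-line structure.

The model regresses a column-centered one-hot class indicator Y on the
column-centered feature matrix X using the classic NIPALS PLS2 iteration:
for each component, weight/score updates are iterated to convergence, then X
is deflated by t·pᵀ and Y by t·qᵀ. Mean-centering only by default (no
unit-variance autoscaling); a deterministic sign convention (largest-|w|
weight element positive) makes outputs reproducible. The number of
components is chosen by stratified cross-validated Q² = 1 − PRESS/SS with the
rule A* = largest a with Q²(a) − Q²(a−1) > 0.01.

Axis separation of the unsupervised factor is quantified explicitly: a
one-way ANOVA F of the axis scores across factor levels, plus a Spearman
trend statistic against the ordinal factor codes, with nominal p-values and a
Bonferroni correction across axes in the dissection report.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .association import spearman_test
from .datamodel import ExpressionMatrix

__all__ = [
    "PLSModel",
    "AxisSeparation",
    "fit_plsda",
    "select_components_cv",
    "axis_separation",
    "dissect_factors",
    "rank_features_by_loading",
]

_NIPALS_TOL = 1e-10
# Balanced multi-class indicators give near-tied singular values, so the
# power iteration can legitimately need >>500 sweeps. When two directions are
# (almost) exactly tied, any vector in their span is an equally valid fixed
# point and the iterate drifts within it indefinitely; a stalled iterate whose
# per-sweep change is below the loose tolerance is therefore accepted at the
# cap, and only a genuinely non-converging iteration raises.
_NIPALS_MAX_ITER = 10000
_NIPALS_LOOSE_TOL = 1e-6


@dataclasses.dataclass
class PLSModel:
    """Fitted PLS2 discriminant model.

    Attributes follow the usual notation: scores ``T`` (samples × A),
    weights ``W`` and X-loadings ``P`` (features × A), Y-loadings ``Q``
    (classes × A). ``x_mean``/``y_mean`` are the centering vectors;
    ``q2`` holds per-component cross-validated Q² when selected by CV.
    """

    n_components: int
    scores: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    class_labels: list[str]
    sample_ids: list[str]
    feature_ids: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    q2: list[float] | None = None


@dataclasses.dataclass
class AxisSeparation:
    """Separation of one factor along one latent axis."""

    axis: int  # 1-based
    factor: str
    f_stat: float
    f_pvalue: float
    trend_rho: float | None = None
    trend_pvalue: float | None = None

    @property
    def pvalue(self) -> float:
        """The p-value used for ranking: the trend p when available."""
        return self.trend_pvalue if self.trend_pvalue is not None else self.f_pvalue


def _indicator(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(str(l) for l in labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes for PLS-DA")
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, index[str(l)]] = 1.0
    return Y, classes


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int):
    """NIPALS PLS2 on already-centered X (n×p) and Y (n×c)."""
    n, p = X.shape
    Xd = X.copy()
    Yd = Y.copy()
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    for a in range(n_components):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if np.linalg.norm(u) < 1e-300:
            raise ValueError(f"component {a + 1}: response fully deflated (rank exceeded)")
        w = np.zeros(p)
        delta = np.inf
        for _ in range(_NIPALS_MAX_ITER):
            w_new = Xd.T @ u / (u @ u)
            norm = np.linalg.norm(w_new)
            if norm < 1e-300:
                raise ValueError(f"component {a + 1}: X fully deflated (rank exceeded)")
            w_new /= norm
            t = Xd @ w_new
            tt = t @ t
            if tt < 1e-300:
                raise ValueError(f"component {a + 1}: degenerate score vector")
            q = Yd.T @ t / tt
            u = Yd @ q / (q @ q)
            delta = np.linalg.norm(w_new - w)
            w = w_new
            if delta < _NIPALS_TOL:
                break
        else:
            if delta >= _NIPALS_LOOSE_TOL:
                raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q = Yd.T @ t / tt
        # deterministic sign: largest-|w| element positive
        sign = np.sign(w[int(np.argmax(np.abs(w)))]) or 1.0
        w, t, p_load, q = sign * w, sign * t, sign * p_load, sign * q
        Xd -= np.outer(t, p_load)
        Yd -= np.outer(t, q)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, p_load, q
    return T, W, P, Q


def fit_plsda(
    X: ExpressionMatrix,
    labels: Sequence[str],
    n_components: int,
) -> PLSModel:
    """Fit a NIPALS PLS2 discriminant model of class labels on expression.

    ``X`` is feature × sample and is transposed internally; both the feature
    matrix and the one-hot indicator are column-centered before fitting.
    """
    if len(labels) != X.n_samples:
        raise ValueError("one label per sample required")
    Xs = X.values.T  # samples x features
    Y, classes = _indicator(labels)
    bound = min(Xs.shape[0] - 1, Xs.shape[1])
    if not 1 <= n_components <= bound:
        raise ValueError(f"n_components must be in [1, {bound}], got {n_components}")
    x_mean = Xs.mean(axis=0)
    y_mean = Y.mean(axis=0)
    T, W, P, Q = _nipals_pls2(Xs - x_mean, Y - y_mean, n_components)
    return PLSModel(
        n_components=n_components,
        scores=T,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        class_labels=classes,
        sample_ids=list(X.sample_ids),
        feature_ids=list(X.feature_ids),
        x_mean=x_mean,
        y_mean=y_mean,
    )


def _predict_indicator(
    Xc: np.ndarray, T: np.ndarray, W: np.ndarray, P: np.ndarray, Q: np.ndarray, a: int
) -> np.ndarray:
    """Predict the centered indicator for centered new data with a components."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    coef = Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)
    return Xc @ coef


def select_components_cv(
    X: ExpressionMatrix,
    labels: Sequence[str],
    max_components: int,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Choose the component count by stratified cross-validated Q².

    Q²(a) = 1 − PRESS(a)/SS(Y) from fold-held-out prediction of the class
    indicator; the selected A* is the largest a ≤ ``max_components`` with
    Q²(a) − Q²(a−1) > 0.01 (Q²(0) ≡ 0), falling back to 1 when no component
    clears the increment.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = [str(l) for l in labels]
    counts = pd.Series(labels).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples, fewer than {folds} folds"
        )
    Xs = X.values.T
    Y, _ = _indicator(labels)
    bound = min(Xs.shape[0] - int(np.ceil(Xs.shape[0] / folds)) - 1, Xs.shape[1])
    max_a = min(max_components, bound)
    if max_a < 1:
        raise ValueError("no admissible component count under this fold split")

    press = np.zeros(max_a)
    ss = 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(Xs, labels):
        x_mean = Xs[train].mean(axis=0)
        y_mean = Y[train].mean(axis=0)
        T, W, P, Q = _nipals_pls2(Xs[train] - x_mean, Y[train] - y_mean, max_a)
        Yc_test = Y[test] - y_mean
        ss += float((Yc_test**2).sum())
        Xc_test = Xs[test] - x_mean
        for a in range(1, max_a + 1):
            resid = Yc_test - _predict_indicator(Xc_test, T, W, P, Q, a)
            press[a - 1] += float((resid**2).sum())
    q2 = (1.0 - press / ss).tolist()
    increments = np.diff([0.0, *q2])
    passing = np.nonzero(increments > 0.01)[0]
    a_star = int(passing.max()) + 1 if passing.size else 1
    return a_star, q2


def axis_separation(
    model: PLSModel,
    factor: Sequence,
    axis: int,
    ordinal: bool = False,
    factor_name: str = "factor",
) -> AxisSeparation:
    """Quantify separation of a factor along one latent axis (1-based).

    Returns the one-way ANOVA F of the axis scores across factor levels, and
    — when the factor is ordinal — the Spearman trend of scores against the
    factor codes, with nominal p-values.
    """
    if not 1 <= axis <= model.n_components:
        raise ValueError(f"axis must be in [1, {model.n_components}]")
    values = list(factor)
    if len(values) != model.scores.shape[0]:
        raise ValueError("one factor value per sample required")
    if len(set(values)) < 2:
        raise ValueError("factor is constant; separation undefined")
    scores = model.scores[:, axis - 1]

    groups = [scores[[v == level for v in values]] for level in sorted(set(values))]
    grand = scores.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(scores) - len(groups)
    if ssw <= 1e-300:
        if ssb <= 1e-300:
            f_stat, f_p = 0.0, 1.0
        else:
            f_stat, f_p = float("inf"), 0.0
    else:
        f_stat = float((ssb / df1) / (ssw / df2))
        f_p = float(stats.f.sf(f_stat, df1, df2))

    trend_rho = trend_p = None
    if ordinal:
        if np.ptp(scores) == 0:
            trend_rho, trend_p = 0.0, 1.0
        else:
            res = spearman_test(scores, [float(v) for v in values], method="approx")
            trend_rho, trend_p = res.rho, res.p
    return AxisSeparation(
        axis=axis,
        factor=factor_name,
        f_stat=f_stat,
        f_pvalue=f_p,
        trend_rho=trend_rho,
        trend_pvalue=trend_p,
    )


def dissect_factors(
    X: ExpressionMatrix,
    supervised_factor: Sequence[str],
    unsupervised_factor: Sequence,
    max_components: int,
    folds: int = 5,
    seed: int = 0,
    ordinal: bool = True,
    factor_name: str = "unsupervised",
    extra_axes: int = 1,
) -> tuple[PLSModel, list[AxisSeparation]]:
    """Supervise on one factor, then rank latent axes by unsupervised
    separation of another.

    Fits PLS-DA on ``supervised_factor`` with a CV-selected component count
    plus ``extra_axes`` additional components, evaluates
    :func:`axis_separation` of ``unsupervised_factor`` on every axis, and
    returns the axes ranked by ascending trend p (ANOVA p when the factor is
    not ordinal), ties broken by descending F.

    The extra axes matter: a factor the supervision never saw cannot improve
    class prediction, so its signature typically surfaces on the first axis
    *after* the supervised structure is exhausted (with C well-separated
    classes, axis C−1+1).
    """
    a_star, q2 = select_components_cv(X, supervised_factor, max_components, folds, seed)
    n, p = X.n_samples, X.n_features
    n_axes = min(a_star + max(0, extra_axes), min(n - 1, p))
    model = fit_plsda(X, supervised_factor, n_axes)
    model.q2 = q2[:a_star]
    report = [
        axis_separation(model, unsupervised_factor, axis, ordinal=ordinal, factor_name=factor_name)
        for axis in range(1, n_axes + 1)
    ]
    report.sort(key=lambda r: (r.pvalue, -r.f_stat))
    return model, report


def bonferroni_min_p(report: Sequence[AxisSeparation]) -> float:
    """Smallest per-axis p after Bonferroni correction across the axes tested."""
    if not report:
        raise ValueError("empty separation report")
    return min(1.0, min(r.pvalue for r in report) * len(report))


def rank_features_by_loading(model: PLSModel, axis: int) -> pd.DataFrame:
    """Features ordered by descending |X-loading| on a (1-based) axis, sign
    reported, ties broken by feature ID."""
    if not 1 <= axis <= model.n_components:
        raise ValueError(f"axis must be in [1, {model.n_components}]")
    loading = model.x_loadings[:, axis - 1]
    order = sorted(
        range(len(loading)), key=lambda i: (-abs(loading[i]), model.feature_ids[i])
    )
    return pd.DataFrame(
        {
            "feature_id": [model.feature_ids[i] for i in order],
            "loading": [float(loading[i]) for i in order],
            "sign": [int(np.sign(loading[i])) for i in order],
        }
    )
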