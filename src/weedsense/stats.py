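"""Correlation, regression and canonical discriminant analysis of field samples.

Each sampling point yields an ultrasonic plant height plus per-group
(grass weed / broad-leaved weed / crop) height, density, dry biomass and
image-derived coverage, together with a binary weed-presence label and a
four-level infestation label (non-infested, grass, broad-leaved, mixture).

The analyses mirror common practice in proximal-sensing field studies:
pairwise Pearson correlation, multiple linear regression with standardized
coefficients and backward elimination, and canonical discriminant analysis
(CDA) with resubstitution confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from scipy import stats as _sps

__all__ = [
    "PearsonResult",
    "SimpleRegressionResult",
    "RegressionResult",
    "CDAModel",
    "ConfusionMatrix",
    "pearson",
    "simple_regression",
    "multiple_regression",
    "cda_fit",
    "cda_transform",
    "cda_classify",
    "confusion_percentages",
]

#: Canonical column order of a sample table (one row per sampling point).
SAMPLE_COLUMNS = [
    "sample_id", "infestation", "weed_presence", "ultrasonic_height",
    "weed_coverage", "grass_height", "bl_height", "crop_height",
    "grass_density", "bl_density", "crop_density",
    "grass_biomass", "bl_biomass", "crop_biomass",
]


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class SimpleRegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class RegressionResult:
    """Final model of a backward-eliminated multiple regression.

    ``table`` has one row per retained predictor with columns
    ``coef`` (raw), ``std_coef`` (coef * sd(x)/sd(y)), ``se`` and ``pvalue``;
    the intercept is reported separately.
    """

    table: pd.DataFrame
    intercept: float
    excluded: list[str]
    r_squared: float
    adj_r_squared: float
    nobs: int
    resid: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class CDAModel:
    """Canonical discriminant model.

    ``coef`` has shape (n_features, n_axes); projections ``X @ coef`` have
    unit pooled within-group variance on every canonical axis.  ``centroids``
    (n_groups, n_axes) are the projected group means; ``eigenvalues`` are the
    between/within variance ratios of the axes, sorted descending.
    """

    labels: list
    features: list[str]
    coef: np.ndarray
    eigenvalues: np.ndarray
    centroids: np.ndarray
    priors: np.ndarray


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized confusion matrix (rows = true group, in percent)."""

    percentages: pd.DataFrame
    counts: pd.DataFrame

    @property
    def accuracy(self) -> float:
        c = self.counts.to_numpy()
        return float(np.trace(c) / c.sum())


# ---------------------------------------------------------------------------
# Correlation and simple regression

def pearson(x, y) -> PearsonResult:
    """Product-moment correlation between two series (with r squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation is undefined for a constant series")
    res = _sps.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r=r, r_squared=r * r, p_value=float(res.pvalue))


def simple_regression(x, y, through_origin: bool = False,
                      fixed_intercept: float | None = None) -> SimpleRegressionResult:
    """Least-squares line, optionally constrained through the origin.

    ``through_origin=True`` omits the intercept entirely; alternatively a
    known ``fixed_intercept`` c fits ``y - c = b x``.  The reported r_squared
    is the squared Pearson correlation between fitted and observed y, which
    coincides with the usual coefficient of determination for the free fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct x values")
    if through_origin and fixed_intercept is not None:
        raise ValueError("through_origin and fixed_intercept are mutually exclusive")
    if through_origin or fixed_intercept is not None:
        c = 0.0 if through_origin else float(fixed_intercept)
        slope = float(np.sum(x * (y - c)) / np.sum(x * x))
        fitted = slope * x + c
        intercept = c
    else:
        res = _sps.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        fitted = slope * x + intercept
    if np.std(fitted) == 0 or np.std(y) == 0:
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return SimpleRegressionResult(slope=slope, intercept=intercept, r_squared=r2)


# ---------------------------------------------------------------------------
# Multiple regression with backward elimination

def _check_collinearity(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name predictors loading on the null space of the design
        _, s, vt = np.linalg.svd(arr, full_matrices=False)
        null = vt[s < s.max() * 1e-10]
        bad = sorted({X.columns[j - 1] for row in null
                      for j in np.nonzero(np.abs(row[1:]) > 1e-8)[0] + 1})
        raise ValueError(f"exactly collinear predictors: {bad}")


def multiple_regression(data: pd.DataFrame, response: str, predictors: list[str],
                        alpha_drop: float | None = 0.10) -> RegressionResult:
    """OLS with optional backward elimination of insignificant predictors.

    While the least-significant predictor has p-value > ``alpha_drop`` it is
    removed (largest p first, ties broken by predictor order) and the model
    refitted.  ``alpha_drop=None`` keeps every predictor.  Standardized
    coefficients are raw coefficients times sd(x)/sd(y).

    Raises ``ValueError`` on exact collinearity, naming the offending
    predictors.
    """
    data = data.dropna(subset=[response, *predictors])
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError("need more observations than predictors plus intercept")
    _check_collinearity(data[predictors])
    y = data[response].astype(float)
    retained = list(predictors)
    excluded: list[str] = []
    while True:
        X = sm.add_constant(data[retained].astype(float))
        fit = sm.OLS(y, X).fit()
        if alpha_drop is None or not retained:
            break
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()  # pandas idxmax: first of tied maxima, in column order
        if pvals[worst] > alpha_drop:
            retained.remove(worst)
            excluded.append(worst)
        else:
            break
    sd_y = y.std(ddof=1)
    rows = {}
    for name in retained:
        sd_x = data[name].astype(float).std(ddof=1)
        rows[name] = {
            "coef": fit.params[name],
            "std_coef": fit.params[name] * sd_x / sd_y,
            "se": fit.bse[name],
            "pvalue": fit.pvalues[name],
        }
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["coef", "std_coef", "se", "pvalue"])
    return RegressionResult(table=table, intercept=float(fit.params["const"]),
                            excluded=excluded, r_squared=float(fit.rsquared),
                            adj_r_squared=float(fit.rsquared_adj), nobs=n,
                            resid=np.asarray(fit.resid))


# ---------------------------------------------------------------------------
# Canonical discriminant analysis

def _group_scatter(X: np.ndarray, y: np.ndarray, labels: list):
    p = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = []
    for lab in labels:
        Xg = X[y == lab]
        mg = Xg.mean(axis=0)
        means.append(mg)
        dev = Xg - mg
        Sw += dev.T @ dev
        Sb += len(Xg) * np.outer(mg - grand, mg - grand)
    return Sw, Sb, np.array(means)


def cda_fit(data: pd.DataFrame, label_field: str, features: list[str],
            priors: str | dict = "equal") -> CDAModel:
    """Fit canonical discriminant axes from within/between-group scatter.

    Solves the generalized eigenproblem Sb a = lambda Sw a; axes are scaled
    so projections have unit pooled within-group variance, and at most
    min(groups - 1, features) axes are kept.  ``priors`` is ``"equal"``,
    ``"proportional"`` or a label->prior mapping.

    Raises ``ValueError`` when any group has < 2 members or the pooled
    within-group scatter is singular.
    """
    sub = data.dropna(subset=[label_field, *features])
    y = sub[label_field].to_numpy()
    labels = sorted(pd.unique(y).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    counts = np.array([(y == lab).sum() for lab in labels])
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    X = sub[features].to_numpy(dtype=float)
    n, p = X.shape
    Sw, Sb, means = _group_scatter(X, y, labels)
    if np.linalg.matrix_rank(Sw) < p:
        raise ValueError(
            "pooled within-group scatter is singular; drop redundant or constant features")
    evals, evecs = sla.eigh(Sb, Sw)  # ascending; vectors satisfy a' Sw a = 1
    order = np.argsort(evals)[::-1]
    k = min(len(labels) - 1, p)
    evals = np.clip(evals[order][:k], 0.0, None)
    A = evecs[:, order][:, :k] * np.sqrt(n - len(labels))  # unit pooled within-variance
    # deterministic sign: largest-magnitude loading positive
    for j in range(A.shape[1]):
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]
    if priors == "equal":
        pr = np.full(len(labels), 1.0 / len(labels))
    elif priors == "proportional":
        pr = counts / counts.sum()
    else:
        pr = np.array([priors[lab] for lab in labels], dtype=float)
        pr = pr / pr.sum()
    return CDAModel(labels=labels, features=list(features), coef=A,
                    eigenvalues=evals, centroids=means @ A, priors=pr)


def cda_transform(model: CDAModel, data: pd.DataFrame) -> np.ndarray:
    """Project samples onto the canonical axes."""
    missing = [f for f in model.features if f not in data.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    return data[model.features].to_numpy(dtype=float) @ model.coef


def cda_classify(model: CDAModel, data: pd.DataFrame) -> np.ndarray:
    """Assign each sample to the nearest group centroid in canonical space.

    The squared Euclidean distance is adjusted by -2 log(prior); distance
    ties resolve to the first group in label order.
    """
    Z = cda_transform(model, data)
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    scores = d2 - 2.0 * np.log(model.priors)[None, :]
    idx = np.argmin(scores, axis=1)  # argmin takes the first of tied minima
    return np.asarray(model.labels, dtype=object)[idx]


def confusion_percentages(true_labels, predicted_labels, labels=None) -> ConfusionMatrix:
    """Row-normalized confusion matrix in percent (rows = true group)."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.size == 0 or t.size != p.size:
        raise ValueError("label vectors must be non-empty and equal length")
    if labels is None:
        labels = sorted(set(t.tolist()) | set(p.tolist()))
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for ti, pi in zip(t, p):
        counts.loc[ti, pi] += 1
    row_sums = counts.sum(axis=1).replace(0, 1)
    pct = counts.div(row_sums, axis=0) * 100.0
    return ConfusionMatrix(percentages=pct, counts=counts)
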