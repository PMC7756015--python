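"""Diagnostic modelling and evaluation.

The combined diagnosis model is a two-feature logistic regression,

    P(CoA) = 1 / (1 + exp(-(a*f + b*s + c))),

fit by maximum likelihood (IRLS with step halving and complete-separation
detection).  Evaluation machinery: ROC/AUC with DeLong variance and
confidence intervals, the DeLong paired test for correlated AUCs,
threshold-based operating metrics with a Youden-optimal threshold rule,
the ESC narrowing-rate comparator (positive at >= 50% narrowing), and the
Spearman rank-correlation matrix of (PSPG, f, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ESC_NARROWING_THRESHOLD = 0.50

__all__ = [
    "InvalidLabelsError",
    "DiagnosticModel",
    "RocResult",
    "ClassificationReport",
    "SpearmanMatrix",
    "fit_logistic_model",
    "predict_coa_probability",
    "roc_auc",
    "delong_variance",
    "delong_compare",
    "classification_metrics",
    "youden_threshold",
    "esc_classifier",
    "spearman_matrix",
]


class InvalidLabelsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticModel:
    """Logistic coefficients on (f, s) plus a decision threshold."""

    a: float
    b: float
    c: float
    decision_threshold: float = 0.5
    separation_detected: bool = False
    converged: bool = True
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.a, self.b, self.c))):
            raise ValueError("coefficients must be finite")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must lie in (0, 1)")

    def linear_predictor(self, f, s):
        return self.a * np.asarray(f, float) + self.b * np.asarray(s, float) + self.c

    def predict(self, f, s):
        return _sigmoid(self.linear_predictor(f, s))


def _sigmoid(eta):
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_likelihood(eta, y):
    # stable sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_model(
    features: Sequence[tuple[float, float]] | np.ndarray,
    labels: Sequence[int],
    decision_threshold: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> DiagnosticModel:
    """Maximum-likelihood logistic fit of labels on (f, s).

    IRLS on internally standardized features (the MLE is invariant under
    the affine rescaling; standardization only conditions the solve).
    Convergence is declared when the log-likelihood improves by less than
    ``tol``.  Complete separation is detected when the current coefficients
    classify every point correctly with a saturated margin; iteration then
    stops with the coefficients capped at their current value and
    ``separation_detected`` set.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise InvalidLabelsError("features and labels differ in length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InvalidLabelsError("labels must be binary")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise InvalidLabelsError("both classes must be present")
    if not np.all(np.isfinite(X)):
        raise InvalidLabelsError("features must be finite")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.column_stack([(X - mu) / sd, np.ones(len(y))])
    k = Z.shape[1]

    beta = np.zeros(k)
    beta[-1] = math.log(n_pos / (len(y) - n_pos))  # intercept at the base rate
    ll = _log_likelihood(Z @ beta, y)
    separation = False
    converged = False
    for _ in range(max_iter):
        eta = Z @ beta
        p = _sigmoid(eta)
        w = p * (1.0 - p)
        margin = np.where(y == 1, eta, -eta)
        if np.all(margin > 0) and margin.min() > 30.0:
            separation = True  # fitted probabilities saturated on every point
            break
        grad = Z.T @ (y - p)
        H = (Z * np.maximum(w, 1e-12)[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        lam = 1.0
        for _ in range(50):
            beta_try = beta + lam * step
            ll_try = _log_likelihood(Z @ beta_try, y)
            if ll_try >= ll - 1e-14:
                break
            lam *= 0.5
        improvement = ll_try - ll
        beta, ll = beta_try, ll_try
        if abs(improvement) < tol:
            converged = True
            break
    # a converged fit that classifies every point with a saturated margin is
    # separated as well: the unconstrained MLE would diverge
    eta = Z @ beta
    margin = np.where(y == 1, eta, -eta)
    if np.all(margin > 0) and margin.min() > 10.0:
        separation = True

    # map back to the raw feature scale
    slopes = beta[:-1] / sd
    intercept = beta[-1] - float(np.dot(beta[:-1], mu / sd))
    coefs = list(slopes) + [intercept]
    if X.shape[1] == 1:
        a, b, c = coefs[0], 0.0, coefs[1]
    else:
        a, b, c = coefs[0], coefs[1], coefs[2]
    return DiagnosticModel(
        a=a, b=b, c=c,
        decision_threshold=decision_threshold,
        separation_detected=separation,
        converged=converged or separation,
        log_likelihood=ll,
    )


def predict_coa_probability(model: DiagnosticModel, f, s):
    """P(CoA) = sigmoid(a*f + b*s + c), overflow-safe."""
    return model.predict(f, s)


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    n_pos: int
    n_neg: int


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if not set(np.unique(y)) <= {0, 1}:
        raise InvalidLabelsError("labels must be binary")
    if y.sum() == 0 or y.sum() == len(y):
        raise InvalidLabelsError("both classes must be present")
    return y


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values (structural components) and the AUC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # pairwise comparison with ties counted 1/2
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)   # per positive
    v01 = cmp.mean(axis=0)   # per negative
    return float(cmp.mean()), v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimator)."""
    y = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    auc, v10, v01 = _placements(scores, y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC via the Mann-Whitney statistic; CI from the DeLong variance.

    The ROC curve itself is traced by sweeping the decision threshold over
    the observed scores (score >= threshold called positive).
    """
    y = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    auc, var = delong_variance(scores, y)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = np.sum(pred & (y == 1)) / y.sum()
        spec[i] = np.sum(~pred & (y == 0)) / (len(y) - y.sum())
    return RocResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high, variance=var,
        thresholds=thresholds, sensitivities=sens, specificities=spec,
        n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()),
    )


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong paired test for two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, z, two-sided p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must match in length")
    y = _check_binary(labels)
    auc_a, v10a, v01a = _placements(scores_a, y)
    auc_b, v10b, v01b = _placements(scores_b, y)
    m, n = len(v10a), len(v01a)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (d10.var(ddof=1) / m if m > 1 else 0.0) + \
          (d01.var(ddof=1) / n if n > 1 else 0.0)
    diff = auc_a - auc_b
    if diff == 0:
        return auc_a, auc_b, 0.0, 1.0
    if var <= 0:
        z = math.copysign(float("inf"), diff)
        return auc_a, auc_b, z, 0.0
    z = diff / math.sqrt(var)
    return auc_a, auc_b, z, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Operating-point metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


def classification_metrics(scores, labels, threshold: float) -> ClassificationReport:
    """Confusion metrics with score >= threshold called positive."""
    y = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return ClassificationReport(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on the given set.

    Candidates are the observed scores; ties broken toward the largest
    threshold (the most specific operating point with the same index).
    The returned cut sits at the midpoint between the optimal candidate and
    the next score below it, which leaves the training confusion counts
    unchanged but is robust for unseen scores near the decision boundary.
    """
    y = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    best_t, best_j = float("inf"), -np.inf
    for t in uniq[::-1]:
        rep = classification_metrics(scores, y, t)
        j = rep.sensitivity + rep.specificity - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    below = uniq[uniq < best_t]
    if len(below):
        return 0.5 * (best_t + float(below[-1]))
    return best_t


def esc_classifier(narrowing) -> np.ndarray | bool:
    """ESC class-II criterion: positive iff narrowing rate >= 50%."""
    arr = np.asarray(narrowing, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("narrowing rate must lie in [0, 1)")
    out = arr >= ESC_NARROWING_THRESHOLD
    return bool(out) if np.isscalar(narrowing) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class SpearmanMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    undefined: set[str] = field(default_factory=set)


def spearman_matrix(columns: Mapping[str, Sequence[float]]) -> SpearmanMatrix:
    """Pairwise Spearman rho with average-rank handling of ties.

    A constant column has no rank ordering; its correlations are reported
    as NaN and the column is listed in ``undefined`` rather than being
    silently set to zero.
    """
    names = list(columns)
    arrs = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    lengths = {len(a) for a in arrs.values()}
    if len(lengths) != 1:
        raise ValueError("all columns must have the same length")
    n = lengths.pop()
    if n < 3:
        raise ValueError("need at least three observations")
    undefined = {k for k, a in arrs.items() if np.all(a == a[0])}
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, ki in enumerate(names):
        pval.iloc[i, i] = 0.0
        for jj in range(i + 1, len(names)):
            kj = names[jj]
            if ki in undefined or kj in undefined:
                r, p = float("nan"), float("nan")
            else:
                res = stats.spearmanr(arrs[ki], arrs[kj])
                r, p = float(res.statistic), float(res.pvalue)
            rho.iloc[i, jj] = rho.iloc[jj, i] = r
            pval.iloc[i, jj] = pval.iloc[jj, i] = p
    for k in undefined:
        rho.loc[k, k] = float("nan")
    return SpearmanMatrix(rho=rho, p=pval, undefined=undefined)
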