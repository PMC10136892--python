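"""Logistic response model, ROC/AUC, and Youden-index cutpoints.

Per-feature (univariate) logistic models are the primary reported objects —
the clinical analysis reported per-feature AUCs — with the multivariate
signature model fitted alongside. The positive class is the adverse outcome
(non-response, or overall progression), so higher scores mean worse outcome.
Cutpoints are reported on the normalized [0, 1] feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateLabelsError


# --------------------------------------------------------------------------
# Logistic regression (IRLS with ridge fallback on separation)
# --------------------------------------------------------------------------

@dataclass
class LogisticFit:
    coef: np.ndarray
    intercept: float
    converged: bool
    n_iter: int
    log_likelihood: float
    separation_flag: bool
    ridge: float
    feature_names: list[str] = field(default_factory=list)

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(pd.DataFrame(X), dtype=float)
        return self.intercept + X @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.decision_function(X))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _irls(X: np.ndarray, y: np.ndarray, ridge: float,
          max_iter: int = 100, tol: float = 1e-10):
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Xd.T @ (y - mu) - ridge * beta
        hess = (Xd * w[:, None]).T @ Xd + ridge * np.eye(p + 1)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e6:
            break
    eta = Xd @ beta
    ll = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, None, 500)))))
    return beta, converged, it, ll


def fit_logistic(X, y, ridge: float = 1e-6, max_ridge: float = 10.0) -> LogisticFit:
    """Maximum-likelihood logistic fit via IRLS.

    On (quasi-)separation the MLE diverges; the fit is then repeated with an
    escalating ridge penalty until the coefficients are finite and the
    iteration converges, and the result is flagged.
    """
    Xdf = pd.DataFrame(X)
    names = [str(c) for c in Xdf.columns]
    Xv = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("logistic fit needs both classes")
    if Xv.shape[0] < Xv.shape[1] + 2:
        raise ValueError("need n >= p + 2 samples")

    lam = ridge
    separation = False
    while True:
        beta, converged, n_iter, ll = _irls(Xv, y, lam)
        ok = converged and np.max(np.abs(beta)) <= 30.0
        if ok or lam >= max_ridge:
            if not ok:
                separation = True
            break
        separation = True
        lam *= 100.0
    return LogisticFit(coef=beta[1:], intercept=float(beta[0]),
                       converged=converged, n_iter=n_iter, log_likelihood=ll,
                       separation_flag=separation, ridge=lam,
                       feature_names=names)


# --------------------------------------------------------------------------
# ROC / AUC / Youden
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray   # unique scores, descending; rule score >= t
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC by the tie-corrected Mann-Whitney rank estimator.

    The curve is scanned over all unique scores with the decision rule
    ``score >= threshold -> positive``. Youden ties are broken toward higher
    sensitivity, then toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("ROC needs both classes")

    ranks = rankdata(scores)  # average ranks: tie correction
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(scores)[::-1]
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    for k, t in enumerate(thresholds):
        sens[k] = np.mean(pos_scores >= t)
        spec[k] = np.mean(neg_scores < t)

    j = sens + spec - 1.0
    best_j = float(j.max())
    # ties: prefer higher sensitivity, then lower threshold
    cand = np.flatnonzero(np.isclose(j, best_j, atol=1e-12))
    cand = cand[sens[cand] == sens[cand].max()]
    best = cand[np.argmin(thresholds[cand])]
    return RocResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc),
                     youden_threshold=float(thresholds[best]),
                     youden_j=max(best_j, 0.0))


def youden_threshold(roc: RocResult) -> tuple[float, float]:
    return roc.youden_threshold, roc.youden_j


# --------------------------------------------------------------------------
# Signature evaluation
# --------------------------------------------------------------------------

def _univariate_report(x_train, y_train, x_test, y_test, name: str) -> dict:
    fit = fit_logistic(pd.DataFrame({name: x_train}), y_train)
    coef = float(fit.coef[0])
    # Orient so that higher oriented value = higher predicted risk; then the
    # Youden cut maps back to the original normalized feature scale.
    sign = 1.0 if coef >= 0 else -1.0
    roc = roc_auc(sign * np.asarray(x_test, float), y_test)
    thr = sign * roc.youden_threshold
    k = int(np.argmin(np.abs(roc.thresholds - roc.youden_threshold)))
    return {
        "feature": name,
        "coef": coef,
        "intercept": fit.intercept,
        "separation_flag": fit.separation_flag,
        "auc": roc.auc,
        "youden_threshold": float(thr),
        "youden_j": roc.youden_j,
        "sensitivity": float(roc.sensitivity[k]),
        "specificity": float(roc.specificity[k]),
        "high_risk_side": "above" if sign > 0 else "below",
    }


def evaluate_signature(train_X: pd.DataFrame, train_y, test_X: pd.DataFrame,
                       test_y, signature: list[str]) -> dict:
    """Univariate model per signature feature plus the multivariate model.

    Fitted on the training rows only; AUC and Youden cutpoints are evaluated
    on the held-out test rows. Univariate cutpoints are on the normalized
    feature scale; the multivariate cutpoint is on the predicted-probability
    scale.
    """
    train_y = np.asarray(train_y).astype(int)
    test_y = np.asarray(test_y).astype(int)
    per_feature = [
        _univariate_report(train_X[f].to_numpy(), train_y,
                           test_X[f].to_numpy(), test_y, f)
        for f in signature
    ]
    multi_fit = fit_logistic(train_X[signature], train_y)
    multi_roc = roc_auc(multi_fit.predict_proba(test_X[signature]), test_y)
    return {
        "per_feature": per_feature,
        "multivariate": {
            "features": list(signature),
            "coef": [float(c) for c in multi_fit.coef],
            "intercept": multi_fit.intercept,
            "separation_flag": multi_fit.separation_flag,
            "auc": multi_roc.auc,
            "youden_threshold_score_scale": multi_roc.youden_threshold,
            "youden_j": multi_roc.youden_j,
        },
    }
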