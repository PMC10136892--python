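"""Normalization, stratified split, Boruta selection, correlation pruning.

The reduction chain mirrors the clinical analysis: reader-merged features are
normalized to the unit interval, the cohort is split 70/30 stratified by the
outcome label, an all-relevant Boruta search (shadow features + random
forest) is run on the training half only, and closely correlated confirmed
features are pruned, keeping the more important of each pair.

Normalization is z-score standardization followed by min-max rescaling to
[0, 1] on the training data; the composition resolves the ambiguity of
"z-scores scaled to [0, 1]" (z-scores alone are unbounded). Scaling
parameters learned on the training set are reapplied, not refit, to test
rows, which may therefore fall slightly outside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import (DegenerateLabelsError, EmptyFeatureSpaceError,
                     UnsplittableStratumError)


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

class UnitIntervalScaler(BaseEstimator, TransformerMixin):
    """Per-feature z-score then min-max rescale to [0, 1], fit on train only.

    Constant features carry no information and are dropped with a warning.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "UnitIntervalScaler":
        X = pd.DataFrame(X)
        std = X.std(ddof=0)
        self.dropped_ = list(X.columns[std == 0.0])
        if self.dropped_:
            warnings.warn(f"dropping {len(self.dropped_)} constant feature(s): "
                          f"{self.dropped_[:5]}...", stacklevel=2)
        kept = X.drop(columns=self.dropped_)
        if kept.shape[1] == 0:
            raise EmptyFeatureSpaceError("all features are constant")
        self.mean_ = kept.mean()
        self.std_ = kept.std(ddof=0)
        z = (kept - self.mean_) / self.std_
        self.z_min_ = z.min()
        self.z_max_ = z.max()
        self.feature_names_in_ = np.asarray(X.columns)
        self.feature_names_out_ = list(kept.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = pd.DataFrame(X)[self.feature_names_out_]
        z = (X - self.mean_) / self.std_
        return (z - self.z_min_) / (self.z_max_ - self.z_min_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "mean_")
        return np.asarray(self.feature_names_out_)


def normalize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, UnitIntervalScaler]:
    """Fit-and-transform convenience; returns the scaler for reapplication."""
    if len(table) < 2:
        raise ValueError("normalization needs at least 2 patients")
    scaler = UnitIntervalScaler().fit(table)
    return scaler.transform(table), scaler


# --------------------------------------------------------------------------
# Stratified 70/30 split
# --------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    ratio: float
    stratify_by: str
    seed: int


def split_cohort(cohort: pd.DataFrame, ratio: float = 0.7, seed: int = 0,
                 stratify_by: str = "responder") -> SplitPlan:
    """Outcome-stratified train/test split of the patient ids.

    Within each stratum, round(ratio * n) patients go to training after a
    seeded shuffle, so class balance is preserved on both sides.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for _, group in cohort.groupby(stratify_by, sort=True):
        ids = list(group["patient_id"])
        if len(ids) < 2:
            raise UnsplittableStratumError(
                f"stratum of size {len(ids)} cannot be split"
            )
        rng.shuffle(ids)
        n_train = int(np.floor(ratio * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both sides nonempty
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return SplitPlan(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                     ratio=ratio, stratify_by=stratify_by, seed=seed)


# --------------------------------------------------------------------------
# Boruta
# --------------------------------------------------------------------------

@dataclass
class BorutaResult:
    decision: pd.Series            # confirmed / tentative / rejected
    hits: pd.Series
    n_iter: int
    importance_history: pd.DataFrame
    shadow_max_history: np.ndarray
    median_importance: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def confirmed(self) -> list[str]:
        return list(self.decision.index[self.decision == "confirmed"])


class BorutaSelector(BaseEstimator):
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends a column-wise permuted copy of every feature,
    fits a random-forest classifier on the augmented matrix, and scores a
    "hit" for every real feature whose importance exceeds the best shadow
    importance. Two-sided binomial tests at level ``alpha`` (Bonferroni-
    corrected over the full feature set) confirm clear winners and
    reject clear losers; the loop stops when nothing is undecided or
    ``max_iter`` is reached. Features still tentative at ``max_iter`` are
    additionally resolved by comparing their median importance with the
    median best-shadow importance (``resolved_decision_``); pass
    ``resolve_tentative=True`` to fold that rough fix into ``decision_``.
    """

    def __init__(self, n_trees: int = 500, max_iter: int = 100,
                 alpha: float = 0.01, importance: str = "impurity",
                 resolve_tentative: bool = False, random_state: int = 0):
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.alpha = alpha
        self.importance = importance
        self.resolve_tentative = resolve_tentative
        self.random_state = random_state

    def _importances(self, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        rf = RandomForestClassifier(n_estimators=self.n_trees,
                                    random_state=seed, n_jobs=1)
        rf.fit(X, y)
        if self.importance == "permutation":
            from sklearn.inspection import permutation_importance
            result = permutation_importance(rf, X, y, n_repeats=5,
                                            random_state=seed, n_jobs=1)
            return result.importances_mean
        return rf.feature_importances_

    def fit(self, X: pd.DataFrame, y) -> "BorutaSelector":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError("Boruta needs both outcome classes")
        if len(X) < 8:
            raise ValueError("Boruta needs at least 8 training samples")
        if X.shape[1] < 1:
            raise ValueError("Boruta needs at least one feature")
        names = list(X.columns)
        n_feat = len(names)
        rng = np.random.default_rng(self.random_state)
        Xv = X.to_numpy(dtype=float)

        hits = np.zeros(n_feat, dtype=int)
        status = np.full(n_feat, "tentative", dtype=object)
        history: list[np.ndarray] = []
        shadow_hist: list[float] = []

        it = 0
        while it < self.max_iter and np.any(status == "tentative"):
            it += 1
            shadow = Xv.copy()
            for col in range(n_feat):
                rng.shuffle(shadow[:, col])
            aug = np.hstack([Xv, shadow])
            seed = int(rng.integers(0, 2**31 - 1))
            imp = self._importances(aug, y, seed)
            real, sh = imp[:n_feat], imp[n_feat:]
            shadow_max = float(sh.max())
            hits += (real > shadow_max).astype(int)
            history.append(real)
            shadow_hist.append(shadow_max)

            # Two-sided binomial tests on hit counts vs a fair coin, Bonferroni
            # across the whole feature set (constant m: the correction must not
            # weaken as features get rejected) with alpha split over the tails.
            level = self.alpha / (2 * n_feat)
            for idx in np.flatnonzero(status == "tentative"):
                p_hi = binom.sf(hits[idx] - 1, it, 0.5)
                p_lo = binom.cdf(hits[idx], it, 0.5)
                if p_hi < level:
                    status[idx] = "confirmed"
                elif p_lo < level:
                    status[idx] = "rejected"

        hist = pd.DataFrame(history, columns=names)
        med_imp = hist.median(axis=0)
        med_shadow = float(np.median(shadow_hist)) if shadow_hist else 0.0
        raw = pd.Series(status.copy(), index=names)
        # Rough fix for features still tentative at max_iter: compare their
        # median importance with the median best-shadow importance. This is
        # weaker evidence than the binomial test (in-sample noise correlations
        # can pass it), so it is reported separately and only folded into the
        # main decisions on request.
        resolved = raw.copy()
        for name in names:
            if resolved[name] == "tentative":
                resolved[name] = ("confirmed" if med_imp[name] > med_shadow
                                  else "rejected")
        self.raw_decision_ = raw
        self.resolved_decision_ = resolved
        self.decision_ = resolved.copy() if self.resolve_tentative else raw.copy()
        self.hits_ = pd.Series(hits, index=names)
        self.n_iter_ = it
        self.importance_history_ = hist
        self.shadow_max_history_ = np.asarray(shadow_hist)
        self.median_importance_ = med_imp
        self.support_ = (self.decision_ == "confirmed").to_numpy()
        self.feature_names_in_ = np.asarray(names)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        return pd.DataFrame(X)[list(self.feature_names_in_[self.support_])]

    def result(self) -> BorutaResult:
        check_is_fitted(self, "support_")
        return BorutaResult(
            decision=self.decision_,
            hits=self.hits_,
            n_iter=self.n_iter_,
            importance_history=self.importance_history_,
            shadow_max_history=self.shadow_max_history_,
            median_importance=self.median_importance_,
            params={"n_trees": self.n_trees, "max_iter": self.max_iter,
                    "alpha": self.alpha, "random_state": self.random_state},
        )


def boruta_select(X: pd.DataFrame, y, n_trees: int = 500, max_iter: int = 100,
                  alpha: float = 0.01, seed: int = 0) -> BorutaResult:
    selector = BorutaSelector(n_trees=n_trees, max_iter=max_iter, alpha=alpha,
                              random_state=seed)
    return selector.fit(X, y).result()


# --------------------------------------------------------------------------
# Correlation pruning
# --------------------------------------------------------------------------

def correlation_prune(X: pd.DataFrame, confirmed: list[str],
                      importance: pd.Series, r_max: float = 0.8) -> list[str]:
    """Greedy pruning of near-duplicate confirmed features.

    Candidates are visited by decreasing Boruta median importance (name
    ascending on ties) and kept unless |Pearson r| >= r_max with an
    already-kept feature.
    """
    if not confirmed:
        raise ValueError("no confirmed features to prune")
    order = sorted(confirmed, key=lambda f: (-float(importance[f]), f))
    corr = X[order].corr().abs()
    kept: list[str] = []
    for feat in order:
        if all(corr.loc[feat, k] < r_max or np.isnan(corr.loc[feat, k])
               for k in kept):
            kept.append(feat)
    return kept
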