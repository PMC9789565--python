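"""Cross-validated AUC evaluation, feature-count sweeps, one-vs-rest
geography classification and the soft-vote ensemble.

AUC is computed by the Mann-Whitney rank statistic (ties counted half), so
it is exact under tied scores and invariant to monotone transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .abundance_io import OBESE, AbundanceTable
from .errors import ContractError, DataError, StratificationError
from .model_selectors import make_learner


@dataclass
class ClassifierModel:
    """A fitted probabilistic classifier over a fixed, ordered feature set."""

    learner: str
    estimator: object
    feature_ids: list[str]
    seed: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.feature_ids):
            raise ContractError(
                f"expected {len(self.feature_ids)} features, got {x.shape[1]}")
        return self.estimator.predict_proba(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    folds: int
    repeats: int
    seed: int


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise StratificationError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def fit_classifier(table: AbundanceTable, features: Sequence[str],
                   learner: str = "xgb", seed: int = 0,
                   positive: str = OBESE) -> ClassifierModel:
    """Fit one learner on the full table restricted to ``features``."""
    feats = list(features)
    sub = table.select_species(feats)
    y = sub.group_labels(positive=positive)
    if y.min() == y.max():
        raise DataError("both groups must be present")
    est = make_learner(learner, seed=seed)
    est.fit(sub.matrix(), y)
    return ClassifierModel(learner=learner, estimator=est,
                           feature_ids=feats, seed=seed)


def _cv_auc_arrays(x: np.ndarray, y: np.ndarray, learner: str, folds: int,
                   repeats: int, seed: int) -> CVResult:
    if y.min() == y.max():
        raise StratificationError("both classes must be present")
    fold_aucs: list[float] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in skf.split(x, y):
            y_tr, y_te = y[train_idx], y[test_idx]
            if y_tr.min() == y_tr.max() or y_te.min() == y_te.max():
                raise StratificationError("a fold lost one of the classes")
            est = make_learner(learner, seed=seed + r)
            est.fit(x[train_idx], y_tr)
            scores = est.predict_proba(x[test_idx])[:, 1]
            fold_aucs.append(auc_score(y_te, scores))
    mean = float(np.mean(fold_aucs))
    sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    return CVResult(fold_aucs=fold_aucs, mean_auc=mean, sd_auc=sd,
                    folds=folds, repeats=repeats, seed=seed)


def cross_validated_auc(table: AbundanceTable, features: Sequence[str],
                        learner: str = "xgb", folds: int = 5,
                        repeats: int = 10, seed: int = 0,
                        positive: str = OBESE) -> CVResult:
    """Repeated stratified k-fold AUC of one learner on a feature subset.

    Repeat r derives its shuffling and learner seed as ``seed + r``, so a
    fixed seed reproduces every fold AUC exactly.
    """
    feats = list(features)
    if not feats:
        raise DataError("features must be non-empty")
    sub = table.select_species(feats)
    return _cv_auc_arrays(sub.matrix(), sub.group_labels(positive=positive),
                          learner, folds, repeats, seed)


def auc_vs_feature_count(table: AbundanceTable, ranked_features: Sequence[str],
                         learner: str = "xgb", grid: Sequence[int] = (),
                         folds: int = 5, repeats: int = 1,
                         seed: int = 0) -> list[tuple[int, float]]:
    """Mean CV AUC at each ranking-prefix size in ``grid``."""
    ranked = list(ranked_features)
    grid = list(grid) or list(range(1, len(ranked) + 1))
    if max(grid) > len(ranked):
        raise DataError("grid values must be <= len(ranked_features)")
    curve = []
    for k in grid:
        res = cross_validated_auc(table, ranked[:k], learner, folds=folds,
                                  repeats=repeats, seed=seed)
        curve.append((int(k), res.mean_auc))
    return curve


def geography_ovr(table: AbundanceTable, learner: str = "rf", folds: int = 5,
                  repeats: int = 10, seed: int = 0) -> tuple[dict[str, float], float]:
    """One-vs-rest cohort classification AUC on all species.

    Returns per-cohort mean AUCs and their arithmetic mean.
    """
    cohorts = table.cohorts()
    if len(cohorts) < 2:
        raise DataError("geography classification needs >=2 cohorts")
    x = table.matrix()
    out: dict[str, float] = {}
    for cohort in cohorts:
        y = (table.cohort.to_numpy() == cohort).astype(int)
        if y.sum() < 2 * folds:
            raise DataError(f"cohort {cohort!r} has fewer than {2 * folds} samples")
        out[cohort] = _cv_auc_arrays(x, y, learner, folds, repeats, seed).mean_auc
    return out, float(np.mean(list(out.values())))


def ensemble_predict(models: Sequence[ClassifierModel], x: np.ndarray) -> np.ndarray:
    """Soft vote: arithmetic mean of member positive-class probabilities."""
    if not models:
        raise ContractError("ensemble needs at least one member")
    feature_ids = models[0].feature_ids
    for m in models[1:]:
        if m.feature_ids != feature_ids:
            raise ContractError("ensemble members disagree on feature_ids")
    probs = np.stack([m.predict_proba(x)[:, 1] for m in models])
    return probs.mean(axis=0)
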