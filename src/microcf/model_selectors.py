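"""Embedded and wrapper feature selection.

Embedded selection fits one of seven tree-ensemble learners — decision tree
(dt), random forest (rf), gradient-boosted trees (gbdt), XGBoost (xgb) and
its random-forest variant (xgbrf), AdaBoost (adaboost) and LightGBM (lgbm) —
on a cohort's abundances vs group labels and keeps the species whose
normalised impurity/gain importance is at least the uniform share 1/p.

Because single fits of these learners are noisy, a stability screen repeats
the cross-cohort ("regional") intersection over several seeds and rejects a
learner that returns an empty regional set, that saturates (selects nearly
all species), or whose cumulative intersection keeps decaying — the three
failure modes that disqualify learners in practice.

The wrapper is sequential forward selection over an importance ranking: the
cross-validated AUC of each ranking prefix is evaluated and the best prefix
(smallest on ties) wins; per cohort the best (learner, subset) pair is kept
and pooled across cohorts by union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

# lightgbm's sklearn wrapper names features internally even for ndarray input
# and sklearn then warns on every predict; the warning is cosmetic here since
# all fits and predictions go through the same ndarray interface.
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names",
    category=UserWarning)

from .abundance_io import AbundanceTable
from .errors import ConfigurationError, DataError, ModelError

LEARNER_NAMES = ("dt", "rf", "gbdt", "xgb", "xgbrf", "adaboost", "lgbm")


def make_learner(name: str, seed: int = 0):
    """Instantiate a named learner with library-default hyperparameters."""
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(random_state=seed)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if name == "gbdt":
        from sklearn.ensemble import GradientBoostingClassifier
        return GradientBoostingClassifier(random_state=seed)
    if name == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier
        return AdaBoostClassifier(random_state=seed)
    if name == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, random_state=seed, n_jobs=1,
                             verbosity=0, eval_metric="logloss",
                             tree_method="hist")
    if name == "xgbrf":
        from xgboost import XGBRFClassifier
        return XGBRFClassifier(n_estimators=100, random_state=seed, n_jobs=1,
                               verbosity=0, eval_metric="logloss",
                               tree_method="hist")
    if name == "lgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(n_estimators=100, random_state=seed, n_jobs=1,
                              verbose=-1, deterministic=True,
                              force_row_wise=True)
    raise ConfigurationError(f"unknown learner: {name!r} "
                             f"(expected one of {LEARNER_NAMES})")


@dataclass
class EmbeddedConfig:
    """Configuration for embedded selection and its stability screen.

    ``learner`` may also be a callable ``(table, cohort, seed) -> set`` which
    replaces the fitted model entirely (used to probe the screen itself).
    """

    learner: str | Callable = "xgb"
    n_repeats: int = 10
    importance_rule: str = "above_uniform"  # above_uniform | positive | top_k
    top_k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.importance_rule not in ("above_uniform", "positive", "top_k"):
            raise ConfigurationError(
                f"unknown importance_rule: {self.importance_rule!r}")

    @property
    def label(self) -> str:
        return self.learner if isinstance(self.learner, str) \
            else getattr(self.learner, "__name__", "custom")


@dataclass
class StabilityReport:
    """Accept/reject verdict of one learner across repeated regional selections."""

    learner: str
    verdict: str  # accepted | rejected
    reason: str   # ok | empty | saturated | unstable
    per_repeat_sets: list[set[str]]
    cumulative_intersection_sizes: list[int]

    def base_regional(self) -> set[str]:
        """The regional set of the base-seed repeat (the learner's selection)."""
        return set(self.per_repeat_sets[0]) if self.per_repeat_sets else set()

    def stable_core(self) -> set[str]:
        """Intersection of all per-repeat regional sets (diagnostic only)."""
        if not self.per_repeat_sets:
            return set()
        return set.intersection(*self.per_repeat_sets)


def _select_by_rule(importances: np.ndarray, rule: str, top_k: int) -> np.ndarray:
    p = importances.size
    if rule == "above_uniform":
        return importances >= 1.0 / p - 1e-12
    if rule == "positive":
        return importances > 0.0
    order = np.argsort(importances)[::-1][:top_k]
    mask = np.zeros(p, dtype=bool)
    mask[order] = True
    return mask


def embedded_select_cohort(table: AbundanceTable, cohort: str | None,
                           config: EmbeddedConfig,
                           seed: int | None = None) -> tuple[set[str], np.ndarray]:
    """Fit the configured learner on one cohort and select by importance.

    Returns the selected species set and the normalised importance vector
    (summing to 1 unless the fit assigns no importance at all).
    """
    sub = table.subset_cohort(cohort) if cohort is not None else table
    y = sub.group_labels()
    if y.min() == y.max():
        raise DataError(f"cohort {cohort!r} lacks one of the groups")
    seed = config.seed if seed is None else seed

    if callable(config.learner):
        selected = set(config.learner(table, cohort, seed))
        return selected, np.zeros(sub.n_species)

    model = make_learner(config.learner, seed=seed)
    x = sub.matrix()
    try:
        model.fit(x, y)
        importances = np.asarray(model.feature_importances_, dtype=float)
    except Exception as exc:  # noqa: BLE001 - re-raise with learner context
        raise ModelError(f"learner {config.learner!r} failed to fit: {exc}") from exc
    total = importances.sum()
    if total > 0:
        importances = importances / total
    mask = _select_by_rule(importances, config.importance_rule, config.top_k)
    species = np.asarray(sub.species_ids)
    return set(species[mask]), importances


def stability_screen(table: AbundanceTable, config: EmbeddedConfig,
                     saturation: float = 0.9,
                     decay_tolerance: float = 0.1) -> StabilityReport:
    """Repeat regional embedded selection and judge the learner's stability.

    Rejection reasons, checked in this order: ``empty`` (some repeat's
    regional intersection is empty), ``saturated`` (mean regional set exceeds
    ``saturation`` x n_species), ``unstable`` (the cumulative intersection
    still shrinks by more than ``decay_tolerance`` relative between the last
    two repeats).
    """
    cohorts = table.cohorts()
    if len(cohorts) < 2:
        raise DataError("stability screening needs >=2 cohorts")
    if config.n_repeats < 3:
        raise DataError("stability screening needs n_repeats >= 3")

    per_repeat: list[set[str]] = []
    for r in range(config.n_repeats):
        seed_r = config.seed + r
        sets = [embedded_select_cohort(table, c, config, seed=seed_r)[0]
                for c in cohorts]
        per_repeat.append(set.intersection(*sets))

    cumulative: list[int] = []
    running: set[str] | None = None
    for s in per_repeat:
        running = set(s) if running is None else running & s
        cumulative.append(len(running))

    p = table.n_species
    if any(len(s) == 0 for s in per_repeat):
        verdict, reason = "rejected", "empty"
    elif np.mean([len(s) for s in per_repeat]) > saturation * p:
        verdict, reason = "rejected", "saturated"
    else:
        prev, last = cumulative[-2], cumulative[-1]
        if last == 0:
            # per-repeat sets are non-empty here, so the cumulative
            # intersection decayed all the way: the limit of instability
            verdict, reason = "rejected", "unstable"
        elif prev > 0 and (prev - last) / prev > decay_tolerance:
            verdict, reason = "rejected", "unstable"
        else:
            verdict, reason = "accepted", "ok"
    return StabilityReport(learner=config.label, verdict=verdict, reason=reason,
                           per_repeat_sets=per_repeat,
                           cumulative_intersection_sizes=cumulative)


def sequential_forward_selection(table: AbundanceTable, cohort: str | None,
                                 ranked_features: Sequence[str],
                                 learner: str = "xgb", cv_folds: int = 5,
                                 seed: int = 0, return_sd: bool = False):
    """Sweep ranking prefixes and return the best prefix by mean CV AUC.

    ``auc_curve[k-1]`` is the mean cross-validated AUC using the top-k
    features; the best subset is the prefix maximising AUC, the smallest k
    winning exact ties.  With ``return_sd`` the per-prefix fold-AUC standard
    deviations are returned as a third element.
    """
    from .classification_eval import cross_validated_auc

    if not ranked_features:
        raise DataError("ranked_features must be non-empty")
    sub = table.subset_cohort(cohort) if cohort is not None else table
    aucs = np.empty(len(ranked_features))
    sds = np.empty(len(ranked_features))
    for k in range(1, len(ranked_features) + 1):
        res = cross_validated_auc(sub, ranked_features[:k], learner,
                                  folds=cv_folds, repeats=1, seed=seed)
        aucs[k - 1] = res.mean_auc
        sds[k - 1] = res.sd_auc
    best_k = int(np.argmax(aucs)) + 1  # argmax returns the first (smallest) max
    best = list(ranked_features[:best_k])
    return (best, aucs, sds) if return_sd else (best, aucs)


def wrapper_pool(per_cohort_results: dict[str, object]) -> set[str]:
    """Union of per-cohort best wrapper subsets.

    Each value is a ``(learner, best_subset, auc)`` tuple or a list of such
    candidate tuples, in which case the best AUC wins and ties go to the
    smaller subset (then lexicographic learner name, for determinism).
    """
    pool: set[str] = set()
    for cohort, entry in per_cohort_results.items():
        candidates = entry if isinstance(entry, list) else [entry]
        if not candidates:
            raise DataError(f"cohort {cohort!r} contributed no wrapper result")
        best = max(candidates,
                   key=lambda t: (t[2], -len(t[1]), _neg_name(t[0])))
        pool |= set(best[1])
    return pool


def _neg_name(name: str) -> tuple[int, ...]:
    """Order-reversing key so max() prefers lexicographically smaller names."""
    return tuple(-ord(ch) for ch in str(name))
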