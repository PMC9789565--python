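"""End-to-end biomarker discovery: prevalence filter -> per-cohort filter
consensus -> stability-screened embedded selection -> sequential-forward-
selection wrapper -> set aggregation.

The stages mirror the heterogeneous ensemble design: the filter family
contributes the cross-cohort intersection of its per-cohort consensus sets;
each stability-accepted embedded learner contributes the intersection of its
per-repeat regional sets (its stable core); the wrapper family contributes
the union over cohorts of the best (learner, prefix) subset found by
sequential forward selection on importance rankings.  The final biomarkers
are (filter ∪ embedded) ∩ wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .abundance_io import AbundanceTable, filter_low_prevalence
from .biomarker_aggregation import (SelectionOutcome, aggregate_final,
                                    regional_intersection)
from .errors import DataError
from .filter_selectors import FilterSelection, filter_select_cohort
from .model_selectors import (LEARNER_NAMES, EmbeddedConfig, StabilityReport,
                              embedded_select_cohort, sequential_forward_selection,
                              stability_screen, wrapper_pool)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the discovery pipeline, seedable end to end."""

    prevalence_threshold: float = 0.10
    alpha: float = 0.05
    min_votes: int = 4
    n_permutations: int = 999
    learners: tuple[str, ...] = LEARNER_NAMES
    n_repeats: int = 10
    saturation: float = 0.9
    decay_tolerance: float = 0.1
    wrapper_learner_scope: str = "all"  # all | accepted
    sfs_max_features: int = 25
    cv_folds: int = 5
    seed: int = 0


@dataclass
class DiscoveryResult:
    """Everything the pipeline decided, with provenance."""

    table: AbundanceTable                      # prevalence-filtered input
    filter_selections: dict[str, FilterSelection]
    filter_regional: set[str]
    stability_reports: dict[str, StabilityReport]
    embedded_regionals: dict[str, set[str]]    # accepted learners only
    wrapper_best: dict[str, tuple[str, list[str], float]]
    wrapper_pool: set[str]
    union_set: set[str]
    final: set[str]
    outcomes: list[SelectionOutcome] = field(default_factory=list)


def discover_biomarkers(table: AbundanceTable,
                        config: PipelineConfig | None = None) -> DiscoveryResult:
    """Run the full ensemble feature-selection pipeline on a multi-cohort table."""
    cfg = config or PipelineConfig()
    cohorts = table.cohorts()
    if len(cohorts) < 2:
        raise DataError("the pipeline needs >=2 cohorts")
    prepared = filter_low_prevalence(table, threshold=cfg.prevalence_threshold)
    logger.info("prevalence filter kept %d/%d species",
                prepared.n_species, table.n_species)
    outcomes: list[SelectionOutcome] = []

    # ---- filter family -------------------------------------------------
    filter_selections: dict[str, FilterSelection] = {}
    for cohort in cohorts:
        sel = filter_select_cohort(prepared, cohort, alpha=cfg.alpha,
                                   min_votes=cfg.min_votes,
                                   n_permutations=cfg.n_permutations,
                                   seed=cfg.seed)
        filter_selections[cohort] = sel
        outcomes.append(SelectionOutcome(
            "filter", "consensus", cohort, sel.selected,
            f"7-method vote >= {cfg.min_votes} at q < {cfg.alpha}"))
    filter_regional = regional_intersection(
        {c: s.selected for c, s in filter_selections.items()})
    outcomes.append(SelectionOutcome(
        "filter", "consensus", "regional", filter_regional,
        "intersection over cohorts"))

    # ---- embedded family with stability screen -------------------------
    stability_reports: dict[str, StabilityReport] = {}
    embedded_regionals: dict[str, set[str]] = {}
    for learner in cfg.learners:
        econf = EmbeddedConfig(learner=learner, n_repeats=cfg.n_repeats,
                               seed=cfg.seed)
        report = stability_screen(prepared, econf,
                                  saturation=cfg.saturation,
                                  decay_tolerance=cfg.decay_tolerance)
        stability_reports[learner] = report
        if report.verdict == "accepted":
            embedded_regionals[learner] = report.base_regional()
            outcomes.append(SelectionOutcome(
                "embedded", learner, "regional", report.base_regional(),
                f"base-seed regional set (stability over {cfg.n_repeats} repeats)"))
        else:
            logger.info("embedded learner %s rejected (%s)",
                        learner, report.reason)

    # ---- wrapper family -------------------------------------------------
    accepted = list(embedded_regionals)
    wrapper_learners = list(cfg.learners) if cfg.wrapper_learner_scope == "all" \
        else (accepted or list(cfg.learners))
    wrapper_best: dict[str, tuple[str, list[str], float]] = {}
    for cohort in cohorts:
        candidates = []
        for learner in wrapper_learners:
            econf = EmbeddedConfig(learner=learner, n_repeats=1, seed=cfg.seed)
            _, importances = embedded_select_cohort(prepared, cohort, econf)
            order = np.argsort(importances)[::-1][:cfg.sfs_max_features]
            ranked = [prepared.species_ids[j] for j in order]
            subset, aucs = sequential_forward_selection(
                prepared, cohort, ranked, learner=learner,
                cv_folds=cfg.cv_folds, seed=cfg.seed)
            candidates.append((learner, subset, float(np.max(aucs))))
        wrapper_best[cohort] = max(
            candidates, key=lambda t: (t[2], -len(t[1])))
        outcomes.append(SelectionOutcome(
            "wrapper", wrapper_best[cohort][0], cohort,
            set(wrapper_best[cohort][1]),
            f"best SFS prefix, AUC={wrapper_best[cohort][2]:.3f}"))
    pool = wrapper_pool(wrapper_best)
    outcomes.append(SelectionOutcome("wrapper", "pool", "regional", pool,
                                     "union over cohorts"))

    # ---- aggregation -----------------------------------------------------
    union_set, final = aggregate_final(filter_regional,
                                       list(embedded_regionals.values()), pool)
    outcomes.append(SelectionOutcome("aggregate", "final", "regional", final,
                                     "(filter ∪ embedded) ∩ wrapper"))
    return DiscoveryResult(
        table=prepared, filter_selections=filter_selections,
        filter_regional=filter_regional, stability_reports=stability_reports,
        embedded_regionals=embedded_regionals, wrapper_best=wrapper_best,
        wrapper_pool=pool, union_set=union_set, final=final,
        outcomes=outcomes)
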