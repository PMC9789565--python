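"""Embedded importance selection, the stability screen and the SFS wrapper."""

import numpy as np
import pandas as pd
import pytest

from microcf import (AbundanceTable, EmbeddedConfig, SimulationSpec,
                     embedded_select_cohort, sequential_forward_selection,
                     simulate_multicohort, stability_screen, wrapper_pool)
from microcf.errors import ConfigurationError, DataError
from microcf.model_selectors import LEARNER_NAMES, _select_by_rule, make_learner


def test_seven_learners_instantiate():
    assert len(LEARNER_NAMES) == 7
    for name in LEARNER_NAMES:
        est = make_learner(name, seed=0)
        assert hasattr(est, "fit")
    with pytest.raises(ConfigurationError):
        make_learner("svm")


def test_uniform_importances_all_selected():
    imp = np.full(8, 1.0 / 8)
    assert _select_by_rule(imp, "above_uniform", 3).all()


def test_perfect_feature_gets_top_importance(small_study):
    table, truth = small_study
    # plant a perfectly separating feature
    values = table.values.copy()
    y = table.group_labels()
    values["oracle_sp"] = np.where(y == 1, 0.9, 0.1)
    t2 = AbundanceTable(values / values.sum(axis=1).to_numpy()[:, None],
                        table.cohort, table.group)
    for learner in ("dt", "rf", "xgb"):
        sel, imp = embedded_select_cohort(
            t2, "cohort_0", EmbeddedConfig(learner=learner, seed=0))
        assert t2.species_ids[int(np.argmax(imp))] == "oracle_sp"
        assert "oracle_sp" in sel


def test_importances_normalised(small_study):
    table, _ = small_study
    _, imp = embedded_select_cohort(table, "cohort_0",
                                    EmbeddedConfig(learner="rf", seed=0))
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)


def test_embedded_deterministic(small_study):
    table, _ = small_study
    cfg = EmbeddedConfig(learner="xgb", seed=3)
    s1, i1 = embedded_select_cohort(table, "cohort_0", cfg)
    s2, i2 = embedded_select_cohort(table, "cohort_0", cfg)
    assert s1 == s2 and np.array_equal(i1, i2)


# ---------------------------------------------------------------------------
# stability screen: the three failure modes via stub learners
# ---------------------------------------------------------------------------

def _screen_with_stub(table, stub, n_repeats=5):
    cfg = EmbeddedConfig(learner=stub, n_repeats=n_repeats, seed=0)
    return stability_screen(table, cfg)


def test_empty_intersection_rejected(small_study):
    table, _ = small_study

    def empty_stub(tbl, cohort, seed):
        return set()

    report = _screen_with_stub(table, empty_stub)
    assert (report.verdict, report.reason) == ("rejected", "empty")


def test_saturating_learner_rejected(small_study):
    table, _ = small_study
    all_species = set(table.species_ids)

    def saturating_stub(tbl, cohort, seed):
        return set(all_species)

    report = _screen_with_stub(table, saturating_stub)
    assert (report.verdict, report.reason) == ("rejected", "saturated")


def test_unstable_learner_rejected(small_study):
    table, _ = small_study
    species = list(table.species_ids)
    per_repeat_cache = {}

    def random_half_stub(tbl, cohort, seed):
        # fresh random half per repeat, identical across cohorts of a repeat
        if seed not in per_repeat_cache:
            rng = np.random.default_rng(seed)
            per_repeat_cache[seed] = set(
                rng.choice(species, size=len(species) // 2, replace=False))
        return per_repeat_cache[seed]

    report = _screen_with_stub(table, random_half_stub, n_repeats=6)
    assert (report.verdict, report.reason) == ("rejected", "unstable")
    sizes = report.cumulative_intersection_sizes
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
    assert sizes[-1] < sizes[0]


def test_consistent_learner_accepted(small_study):
    table, _ = small_study
    stable = set(list(table.species_ids)[:6])

    def stable_stub(tbl, cohort, seed):
        return set(stable)

    report = _screen_with_stub(table, stable_stub)
    assert (report.verdict, report.reason) == ("accepted", "ok")
    assert report.stable_core() == stable


def test_cumulative_sizes_non_increasing_by_construction(small_study):
    table, _ = small_study
    cfg = EmbeddedConfig(learner="xgb", n_repeats=4, seed=1)
    report = stability_screen(table, cfg)
    sizes = report.cumulative_intersection_sizes
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def separable_table():
    spec = SimulationSpec(n_cohorts=1, n_per_group=40, n_species=10,
                          n_planted_shared=0, effect_size=0.0, seed=31)
    table, _ = simulate_multicohort(spec)
    values = table.values.copy()
    y = table.group_labels()
    values["oracle_sp"] = np.where(y == 1, 0.9, 0.1)
    return AbundanceTable(values / values.sum(axis=1).to_numpy()[:, None],
                         table.cohort, table.group)


def test_sfs_perfect_feature_wins_alone(separable_table):
    ranked = ["oracle_sp"] + [s for s in separable_table.species_ids
                              if s != "oracle_sp"][:5]
    best, curve = sequential_forward_selection(separable_table, "cohort_0",
                                               ranked, learner="dt", seed=0)
    assert best == ["oracle_sp"]
    assert curve[0] == pytest.approx(1.0)
    assert len(curve) == len(ranked)


def test_sfs_requires_features(separable_table):
    with pytest.raises(DataError):
        sequential_forward_selection(separable_table, "cohort_0", [],
                                     learner="dt")


def test_sfs_best_subset_is_prefix(separable_table):
    ranked = list(separable_table.species_ids)[:6]
    best, curve = sequential_forward_selection(separable_table, "cohort_0",
                                               ranked, learner="dt", seed=0)
    assert best == ranked[:len(best)]
    assert np.argmax(curve) + 1 == len(best)


# ---------------------------------------------------------------------------
# wrapper pooling
# ---------------------------------------------------------------------------

def test_wrapper_pool_union():
    pool = wrapper_pool({"c1": ("xgb", ["a", "b"], 0.9),
                         "c2": ("rf", ["b", "c"], 0.8)})
    assert pool == {"a", "b", "c"}
    assert wrapper_pool({"c1": ("xgb", ["a"], 0.9)}) == {"a"}


def test_wrapper_pool_tie_prefers_smaller_subset():
    pool = wrapper_pool({"c1": [("xgb", ["a", "b", "c"], 0.9),
                                ("rf", ["d"], 0.9)]})
    assert pool == {"d"}
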