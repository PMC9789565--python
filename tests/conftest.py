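"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

from microcf import AbundanceTable, SimulationSpec, simulate_multicohort


@pytest.fixture(scope="session")
def small_study():
    """Two cohorts, strong planted effects: quick but informative."""
    spec = SimulationSpec(n_cohorts=2, n_per_group=40, n_species=30,
                          n_planted_shared=5, effect_size=2.0,
                          cohort_effect_size=1.0, zero_inflation=0.2, seed=11)
    return simulate_multicohort(spec)


@pytest.fixture(scope="session")
def null_study():
    """No group effect anywhere: the null for calibration checks."""
    spec = SimulationSpec(n_cohorts=2, n_per_group=40, n_species=30,
                          n_planted_shared=5, effect_size=0.0,
                          cohort_effect_size=1.0, zero_inflation=0.2, seed=12)
    return simulate_multicohort(spec)


@pytest.fixture()
def toy_table():
    """Hand-built 6-sample, 3-species table over two cohorts."""
    values = pd.DataFrame(
        [[0.5, 0.3, 0.2],
         [0.6, 0.2, 0.2],
         [0.2, 0.5, 0.3],
         [0.1, 0.6, 0.3],
         [0.4, 0.4, 0.2],
         [0.3, 0.3, 0.4]],
        index=[f"s{i}" for i in range(6)],
        columns=["sp_a", "sp_b", "sp_c"],
    )
    cohort = pd.Series(["c1"] * 3 + ["c2"] * 3, index=values.index)
    group = pd.Series(["obese", "healthy"] * 3, index=values.index)
    return AbundanceTable(values, cohort, group)


@pytest.fixture(scope="session")
def linear_toy():
    """2-feature linearly separable classification task for the CF engine."""
    rng = np.random.default_rng(0)
    n = 200
    x0 = rng.normal([0.3, 0.3], 0.08, size=(n // 2, 2))  # class 0: healthy
    x1 = rng.normal([0.7, 0.7], 0.08, size=(n // 2, 2))  # class 1: obese
    x = np.clip(np.vstack([x0, x1]), 0.0, 1.0)
    y = np.concatenate([np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)])
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression().fit(x, y)
    return x, y, clf
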