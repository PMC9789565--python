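"""Diversity, distance, ordination and permutation-test statistics against
closed forms, exhaustive enumeration and independent library implementations.
"""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from microcf import (bray_curtis, pcoa, permanova, rank_sum_test,
                     shannon_index, DistanceMatrix)
from microcf.errors import DataError


# ---------------------------------------------------------------------------
# Shannon
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("vec,expected", [
    ([0.5, 0.5], math.log(2)),
    ([1.0, 0.0], 0.0),
    # direct evaluation of -sum p ln p
    ([0.2, 0.3, 0.5], -(0.2 * math.log(0.2) + 0.3 * math.log(0.3)
                        + 0.5 * math.log(0.5))),
])
def test_shannon_closed_forms(vec, expected):
    assert shannon_index(vec) == pytest.approx(expected, abs=1e-12)


def test_shannon_renormalises_and_rejects_zero():
    assert shannon_index([2.0, 2.0]) == pytest.approx(math.log(2))
    with pytest.raises(DataError):
        shannon_index([0.0, 0.0])


def test_shannon_matches_skbio(small_study):
    skbio_diversity = pytest.importorskip("skbio.diversity.alpha")
    table, _ = small_study
    row = table.matrix()[0]
    ours = shannon_index(row)  # nats, skbio's default base
    theirs = skbio_diversity.shannon(row)
    assert ours == pytest.approx(theirs, abs=1e-10)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def _dist_of(rows):
    from microcf import AbundanceTable
    values = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
    meta = pd.Series(["c"] * len(rows), index=values.index)
    grp = pd.Series(["obese"] * len(rows), index=values.index)
    return bray_curtis(AbundanceTable(values, meta, grp))


def test_bray_curtis_closed_forms():
    d = _dist_of([[1.0, 0.0], [0.0, 1.0]])
    assert d.values[0, 1] == pytest.approx(1.0)
    d = _dist_of([[0.6, 0.4], [0.2, 0.8]])
    assert d.values[0, 1] == pytest.approx(0.4)
    d = _dist_of([[0.3, 0.7], [0.3, 0.7]])
    assert d.values[0, 1] == pytest.approx(0.0)


def test_bray_curtis_matches_scipy(small_study):
    from scipy.spatial.distance import pdist, squareform
    table, _ = small_study
    sub = table.subset_samples(table.sample_ids[:10])
    ours = bray_curtis(sub).values
    theirs = squareform(pdist(sub.matrix(), metric="braycurtis"))
    assert np.abs(ours - theirs).max() < 1e-12


def test_bray_curtis_rejects_all_zero_sample():
    with pytest.raises(DataError):
        _dist_of([[0.0, 0.0], [0.5, 0.5]])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_collinear_points_recover_the_line():
    # three points on a line at 0, 1, 2
    d = DistanceMatrix(np.array([[0.0, 1.0, 2.0],
                                 [1.0, 0.0, 1.0],
                                 [2.0, 1.0, 0.0]]), ["a", "b", "c"])
    coords, eigvals = pcoa(d, k=2)
    axis1 = coords[:, 0]
    gaps = np.diff(np.sort(axis1))
    assert gaps == pytest.approx([1.0, 1.0], abs=1e-10)
    assert len(eigvals) == 1  # a line has a single positive axis


def test_pcoa_euclidean_distances_reproduced():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(12, 4))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    coords, _ = pcoa(DistanceMatrix(d, [str(i) for i in range(12)]), k=11)
    d_hat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    assert np.abs(d - d_hat).max() < 1e-8


def test_pcoa_duplicate_samples_coincide():
    d = DistanceMatrix(np.array([[0.0, 0.0, 1.0],
                                 [0.0, 0.0, 1.0],
                                 [1.0, 1.0, 0.0]]), ["a", "a2", "b"])
    coords, _ = pcoa(d, k=2)
    assert np.allclose(coords[0], coords[1], atol=1e-10)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _oracle_permanova_f(d, codes):
    """Independent pseudo-F from the squared-distance decomposition."""
    n = len(codes)
    d2 = d ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(codes):
        idx = [i for i in range(n) if codes[i] == g]
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    a = len(set(codes))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def test_permanova_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(6, 3))
    pts[:3] += 1.5
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    dist = DistanceMatrix(d, [f"s{i}" for i in range(6)])
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=dist.sample_ids)
    res = permanova(dist, labels, exact=True)
    # oracle: enumerate all C(6,3)=20 assignments from scratch
    f_obs = _oracle_permanova_f(d, [0, 0, 0, 1, 1, 1])
    fs = []
    for idx in combinations(range(6), 3):
        codes = [0 if i in idx else 1 for i in range(6)]
        fs.append(_oracle_permanova_f(d, codes))
    p_oracle = np.mean([f >= f_obs - 1e-12 for f in fs])
    assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
    assert res.pseudo_F == pytest.approx(f_obs, rel=1e-12)


def test_permanova_matches_skbio():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(16, 5))
    pts[:8] += 0.8
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"s{i}" for i in range(16)]
    labels = ["a"] * 8 + ["b"] * 8
    ours = permanova(DistanceMatrix(d, ids), pd.Series(labels, index=ids),
                     n_permutations=999, seed=0)
    dm = skbio_distance.DistanceMatrix(d, ids)
    theirs = skbio_distance.permanova(dm, grouping=labels, permutations=999)
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)
    assert abs(ours.p_value - theirs["p-value"]) < 0.05  # both Monte-Carlo


def test_permanova_identical_groups_show_no_structure():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(5, 3))
    coords = np.vstack([pts, pts])  # group b duplicates group a exactly
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    ids = [f"s{i}" for i in range(10)]
    labels = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
    res = permanova(DistanceMatrix(d, ids), labels, n_permutations=99, seed=1)
    assert abs(res.r_squared) < 1e-10
    assert res.p_value > 0.5


def test_permanova_determinism_and_small_group_error():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(10, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"s{i}" for i in range(10)]
    labels = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
    r1 = permanova(DistanceMatrix(d, ids), labels, n_permutations=199, seed=9)
    r2 = permanova(DistanceMatrix(d, ids), labels, n_permutations=199, seed=9)
    assert r1.p_value == r2.p_value
    bad = pd.Series(["a"] * 9 + ["b"], index=ids)
    with pytest.raises(DataError):
        permanova(DistanceMatrix(d, ids), bad)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def test_rank_sum_separated_samples():
    stat, p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1, abs=1e-12)  # 2 * 1/20


def test_rank_sum_identical_samples():
    _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_rank_sum_tied_case_matches_enumeration():
    from scipy.stats import rankdata
    a, b = [1.0, 1.0, 2.0], [1.0, 2.0, 2.0]
    stat, p = rank_sum_test(a, b)
    # oracle: enumerate C(6,3) index splits of the pooled midranks
    pooled = np.array(a + b)
    ranks = rankdata(pooled)
    w_obs = ranks[:3].sum()
    ws = [ranks[list(idx)].sum() for idx in combinations(range(6), 3)]
    le = np.mean([w <= w_obs + 1e-9 for w in ws])
    ge = np.mean([w >= w_obs - 1e-9 for w in ws])
    assert p == pytest.approx(min(1.0, 2 * min(le, ge)), abs=1e-12)


def test_rank_sum_exact_matches_scipy_no_ties():
    from scipy.stats import mannwhitneyu
    rng = np.random.default_rng(6)
    a = rng.normal(size=5)
    b = rng.normal(size=6) + 0.5
    _, p = rank_sum_test(a, b)
    ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
    assert p == pytest.approx(ref, abs=1e-12)


def test_rank_sum_large_samples_match_scipy_normal_approx():
    from scipy.stats import ranksums
    rng = np.random.default_rng(7)
    a = rng.normal(size=30)
    b = rng.normal(size=35) + 0.4
    _, p = rank_sum_test(a, b)
    ref = ranksums(a, b).pvalue
    assert p == pytest.approx(ref, abs=1e-6)
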