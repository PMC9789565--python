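"""Community-ecology statistics: Shannon diversity, Bray-Curtis distances,
principal-coordinates ordination and PERMANOVA, plus the two-sided Wilcoxon
rank-sum test.

All of these are implemented from first principles on numpy arrays; the test
suite cross-checks them against scipy / scikit-bio on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .abundance_io import AbundanceTable
from .errors import DataError

__all__ = [
    "DistanceMatrix", "PermanovaResult", "shannon_index", "bray_curtis",
    "pcoa", "permanova", "rank_sum_test",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DataError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t",
                                                     float_format="%.17g")


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def shannon_index(abundances: np.ndarray, base: str = "e") -> float:
    """Shannon diversity H = -sum p_i log p_i over renormalised nonzero entries.

    ``base`` is ``"e"`` (nats, default) or ``"2"`` (bits).
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise DataError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise DataError("all-zero abundance vector")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= np.log(2.0)
    return max(h, 0.0)


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances d(u,v) = sum|u-v| / sum(u+v)."""
    x = table.matrix()
    if x.shape[0] < 2:
        raise DataError("need >=2 samples")
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        bad = [table.sample_ids[i] for i in np.where(totals <= 0)[0][:5]]
        raise DataError(f"all-zero samples: {bad}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = totals[i] + totals[i + 1:]
        d[i, i + 1:] = d[i + 1:, i] = num / den
    return DistanceMatrix(d, table.sample_ids)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Returns sample coordinates on the first ``k`` positive-eigenvalue axes
    (fewer if the centred Gower matrix has fewer positive eigenvalues) and
    the retained eigenvalues in descending order.  Negative eigenvalues are
    dropped, not corrected.
    """
    n = dist.n
    if k > n - 1:
        raise DataError("k must be <= n - 1")
    b = _gower_center(dist.values)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-10 * abs(eigval[0]), 1e-12) if eigval[0] > 0 \
        else np.zeros_like(eigval, dtype=bool)
    keep = min(k, int(positive.sum()))
    vals = eigval[:keep]
    coords = eigvec[:, :keep] * np.sqrt(vals)
    return coords, vals


def _permanova_stat(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = n_groups
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _distinct_assignments(codes: np.ndarray, n_groups: int):
    """All distinct group assignments with the observed group sizes."""
    n = codes.size
    if n_groups == 2:
        n1 = int((codes == 1).sum())
        for idx in combinations(range(n), n1):
            out = np.zeros(n, dtype=int)
            out[list(idx)] = 1
            yield out
    else:
        seen = set()
        from itertools import permutations as _perms
        for perm in _perms(codes.tolist()):
            if perm not in seen:
                seen.add(perm)
                yield np.array(perm)


def permanova(dist: DistanceMatrix, labels: dict[str, str] | pd.Series,
              n_permutations: int = 999, seed: int = 0,
              exact: bool = False) -> PermanovaResult:
    """One-way PERMANOVA with free label permutation.

    Monte-Carlo p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    With ``exact=True`` every distinct group assignment is enumerated instead
    (feasible for tiny samples) and p is the exact tail fraction, the
    observed assignment included.
    """
    lab = pd.Series(labels).reindex(dist.sample_ids)
    if lab.isna().any():
        raise DataError("labels missing for some samples")
    codes, uniques = pd.factorize(lab)
    n_groups = len(uniques)
    if n_groups < 2:
        raise DataError("need >=2 groups")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        small = [str(uniques[g]) for g in np.where(counts < 2)[0]]
        raise DataError(f"groups with <2 samples: {small}")
    d2 = dist.values ** 2
    f_obs, r2 = _permanova_stat(d2, codes, n_groups)
    if exact:
        f_all = np.array([_permanova_stat(d2, a, n_groups)[0]
                          for a in _distinct_assignments(codes, n_groups)])
        p = float((f_all >= f_obs - 1e-12).mean())
        n_used = len(f_all)
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            f_perm, _ = _permanova_stat(d2, rng.permutation(codes), n_groups)
            if f_perm >= f_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        n_used = n_permutations
    return PermanovaResult(pseudo_F=float(f_obs), r_squared=float(r2),
                           p_value=float(p), n_permutations=n_used,
                           seed=seed)


#: largest pooled size for which the rank-sum null is enumerated exactly
_EXACT_LIMIT = 12


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the rank sum W of sample ``a`` (midranks under ties).
    For pooled sizes <= 12 the null is enumerated exactly over all
    C(n, n_a) assignments of the observed (possibly tied) ranks; otherwise a
    tie-corrected normal approximation is used.  Two-sided exact p is
    2 * min(P(W <= w), P(W >= w)) capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    ranks = rankdata(np.concatenate([a, b]))
    w = ranks[:na].sum()

    if n <= _EXACT_LIMIT:
        total = comb(n, na)
        le = ge = 0
        for idx in combinations(range(n), na):
            ws = ranks[list(idx)].sum()
            if ws <= w + 1e-9:
                le += 1
            if ws >= w - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return float(w), float(p)

    mean = na * (n + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(w), 1.0
    z = (w - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return float(w), p
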