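"""Maximal information coefficient (MIC).

MIC scores the strength of an arbitrary association between two variables by
gridding the scatter plot: for every x-by-y grid with ``a * b <= B(n)`` cells
(``B(n) = max(4, n^alpha)``), the mutual information of the induced discrete
joint distribution is normalised by ``log min(a, b)``; MIC is the maximum of
this characteristic matrix, a value in [0, 1] that reaches 1 on any noiseless
functional relationship.

Two evaluation strategies are used:

* **exact** — enumerate every admissible grid (cuts can only fall between
  distinct sorted values).  Used whenever the total number of candidate grids
  is small, so small-sample values are exact.
* **approximate** — the equipartition-seeded dynamic programme: one axis is
  equipartitioned into ``q`` rows, the other axis partition is optimised by a
  DP over value "clumps" (runs of tied values), in both orientations.  When a
  variable is binary (the group label, the common case here) the row axis is
  fixed by the two observed values and a single DP is exact up to clump
  capping.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, log

import numpy as np
from numba import njit

from .errors import DataError

__all__ = ["mic", "mic_binary_profile", "mic_binary_from_labels", "mic_binary_batch"]

#: hard floor on the grid-cell budget; n^0.6 < 4 for the smallest allowed n
MIN_BUDGET = 4.0
#: switch to the DP approximation above this many candidate grids
EXACT_ENUM_LIMIT = 50_000


def _grid_budget(n: int, alpha: float) -> float:
    return max(MIN_BUDGET, float(n) ** alpha)


def _mutual_information(counts: np.ndarray) -> float:
    """MI (nats) of a 2-D contingency table of counts."""
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def _admissible_shapes(budget: float) -> list[tuple[int, int]]:
    shapes = []
    a = 2
    while a * 2 <= budget:
        b = 2
        while a * b <= budget:
            shapes.append((a, b))
            b += 1
        a += 1
    return shapes


def _enumeration_cost(dx: int, dy: int, budget: float) -> int:
    total = 0
    for a, b in _admissible_shapes(budget):
        if a - 1 > dx - 1 or b - 1 > dy - 1:
            continue
        total += comb(dx - 1, a - 1) * comb(dy - 1, b - 1)
        if total > EXACT_ENUM_LIMIT:
            return total
    return total


def _mic_exact(x: np.ndarray, y: np.ndarray, budget: float) -> float:
    xs = np.unique(x)
    ys = np.unique(y)
    xcuts_all = (xs[:-1] + xs[1:]) / 2.0
    ycuts_all = (ys[:-1] + ys[1:]) / 2.0
    best = 0.0
    for a, b in _admissible_shapes(budget):
        if a - 1 > len(xcuts_all) or b - 1 > len(ycuts_all):
            continue
        norm = log(min(a, b))
        for xc in combinations(xcuts_all, a - 1):
            xbin = np.digitize(x, xc)
            for yc in combinations(ycuts_all, b - 1):
                ybin = np.digitize(y, yc)
                counts = np.zeros((a, b))
                np.add.at(counts, (xbin, ybin), 1.0)
                best = max(best, _mutual_information(counts) / norm)
    return min(best, 1.0)


@njit(cache=True)
def _dp_column_scores(pref: np.ndarray, lmax: int) -> np.ndarray:
    """Best additive column score for partitions into exactly t columns.

    ``pref`` is the (m+1, q) prefix-sum matrix of per-clump row counts.  The
    additive per-column term is -(n_c/n) log(n_c/n) + sum_r (n_cr/n) log(n_cr/n);
    the total over columns plus H(rows) is the grid mutual information.
    Returns f[t] for t = 0..lmax (unreachable entries are -inf).
    """
    m = pref.shape[0] - 1
    q = pref.shape[1]
    n = 0.0
    for r in range(q):
        n += pref[m, r]

    # phi[j, i] for a column spanning clumps j..i-1
    phi = np.full((m + 1, m + 1), -np.inf)
    for j in range(m):
        for i in range(j + 1, m + 1):
            nc = 0.0
            s = 0.0
            for r in range(q):
                ncr = pref[i, r] - pref[j, r]
                nc += ncr
                if ncr > 0.0:
                    s += (ncr / n) * np.log(ncr / n)
            val = s
            if nc > 0.0:
                val -= (nc / n) * np.log(nc / n)
            phi[j, i] = val

    f = np.full((lmax + 1, m + 1), -np.inf)
    for i in range(1, m + 1):
        f[1, i] = phi[0, i]
    for t in range(2, lmax + 1):
        for i in range(t, m + 1):
            best = -np.inf
            for j in range(t - 1, i):
                v = f[t - 1, j] + phi[j, i]
                if v > best:
                    best = v
            f[t, i] = best

    out = np.full(lmax + 1, -np.inf)
    for t in range(1, min(lmax, m) + 1):
        out[t] = f[t, m]
    return out


def _clump_ids(sorted_vals: np.ndarray) -> np.ndarray:
    ids = np.zeros(len(sorted_vals), dtype=np.int64)
    if len(sorted_vals) > 1:
        ids[1:] = np.cumsum(np.diff(sorted_vals) > 0)
    return ids


def _cap_clumps(ids: np.ndarray, max_clumps: int) -> np.ndarray:
    """Merge clumps into at most ``max_clumps`` superclumps by equipartition."""
    m = ids[-1] + 1
    if m <= max_clumps:
        return ids
    n = len(ids)
    # boundaries of the original clumps in point space
    starts = np.searchsorted(ids, np.arange(m))
    target = n / max_clumps
    super_of = np.minimum((starts / target).astype(np.int64), max_clumps - 1)
    # re-densify
    _, dense = np.unique(super_of, return_inverse=True)
    return dense[ids]


def _equipartition_rows(sorted_ids: np.ndarray, q: int) -> np.ndarray:
    """Assign tied blocks of a sorted axis to ~equal-size rows (MINE-style)."""
    n = len(sorted_ids)
    m = sorted_ids[-1] + 1
    sizes = np.bincount(sorted_ids, minlength=m)
    rows = np.zeros(m, dtype=np.int64)
    curr, used, placed = 0, 0, 0
    for b in range(m):
        share = (n - placed) / (q - curr)
        if used > 0 and curr < q - 1 and \
                abs(used + sizes[b] - share) > abs(used - share):
            placed += used
            curr += 1
            used = 0
        rows[b] = curr
        used += sizes[b]
    return rows[sorted_ids]


def _counts_prefix(clump_ids: np.ndarray, rows: np.ndarray, q: int) -> np.ndarray:
    m = clump_ids[-1] + 1
    cnt = np.zeros((m, q))
    np.add.at(cnt, (clump_ids, rows), 1.0)
    pref = np.zeros((m + 1, q))
    pref[1:] = np.cumsum(cnt, axis=0)
    return pref


def _row_entropy(rows: np.ndarray) -> float:
    counts = np.bincount(rows).astype(float)
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _approx_orientation(x: np.ndarray, y: np.ndarray, budget: float, c: int) -> float:
    """Max normalised MI with y equipartitioned and the x partition optimised."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    clumps = _clump_ids(xs)
    yorder = np.argsort(ys, kind="stable")
    ysorted_ids = _clump_ids(ys[yorder])
    best = 0.0
    q = 2
    while 2 * q <= budget:
        lmax = int(budget // q)
        if lmax < 2:
            break
        rows_sorted = _equipartition_rows(ysorted_ids, q)
        rows = np.empty_like(rows_sorted)
        rows[yorder] = rows_sorted
        capped = _cap_clumps(clumps, max(c * lmax, q))
        pref = _counts_prefix(capped, rows, q)
        hq = _row_entropy(rows)
        f = _dp_column_scores(pref, lmax)
        for t in range(2, lmax + 1):
            if np.isfinite(f[t]):
                best = max(best, (hq + f[t]) / log(min(t, q)))
        q += 1
    return best


def mic(x: np.ndarray, y: np.ndarray, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of two equal-length vectors.

    ``alpha`` sets the grid budget B(n) = max(4, n^alpha); ``c`` bounds the
    number of candidate clumps per optimised axis in the approximation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    n = x.size
    if n < 8:
        raise DataError("MIC needs at least 8 observations")
    dx, dy = len(np.unique(x)), len(np.unique(y))
    if dx < 2 or dy < 2:
        return 0.0
    budget = _grid_budget(n, alpha)
    if _enumeration_cost(dx, dy, budget) <= EXACT_ENUM_LIMIT:
        return _mic_exact(x, y, budget)
    out = max(_approx_orientation(x, y, budget, c),
              _approx_orientation(y, x, budget, c))
    return float(min(out, 1.0))


@njit(cache=True)
def _dp_binary_best(pref0: np.ndarray, pref1: np.ndarray, lmax: int,
                    xlx: np.ndarray, hq: float) -> float:
    """Binary-target DP: max over t<=lmax columns of normalised MI.

    ``pref0``/``pref1`` are integer prefix counts of the two label rows over
    x-clumps; ``xlx[k] = (k/n) log(k/n)`` is a lookup table, so the additive
    column term needs no transcendental calls.
    """
    m = pref0.shape[0] - 1
    ln2 = np.log(2.0)
    phi = np.full((m + 1, m + 1), -np.inf)
    for j in range(m):
        for i in range(j + 1, m + 1):
            c0 = pref0[i] - pref0[j]
            c1 = pref1[i] - pref1[j]
            phi[j, i] = xlx[c0] + xlx[c1] - xlx[c0 + c1]
    fprev = np.full(m + 1, -np.inf)
    for i in range(1, m + 1):
        fprev[i] = phi[0, i]
    best = -np.inf
    fcurr = np.full(m + 1, -np.inf)
    for t in range(2, lmax + 1):
        for i in range(t, m + 1):
            b = -np.inf
            for j in range(t - 1, i):
                v = fprev[j] + phi[j, i]
                if v > b:
                    b = v
            fcurr[i] = b
        if fcurr[m] > best:
            best = fcurr[m]
        fprev, fcurr = fcurr, fprev
        if t > m:
            break
    if not np.isfinite(best):
        return 0.0
    val = (hq + best) / ln2
    if val < 0.0:
        val = 0.0
    if val > 1.0:
        val = 1.0
    return val


# ---------------------------------------------------------------------------
# fast path for permutation tests against a binary target
# ---------------------------------------------------------------------------

class _BinaryMicProfile:
    """Precomputed, label-independent structure for MIC against binary labels."""

    __slots__ = ("order", "clumps", "m", "lmax", "n", "xlx")

    def __init__(self, order: np.ndarray, clumps: np.ndarray, lmax: int, n: int):
        self.order = order
        self.clumps = clumps
        self.m = int(clumps[-1] + 1)
        self.lmax = lmax
        self.n = n
        k = np.arange(n + 1, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            xlx = (k / n) * np.log(k / n)
        xlx[0] = 0.0
        self.xlx = xlx


def mic_binary_profile(x: np.ndarray, alpha: float = 0.6, c: int = 15) -> _BinaryMicProfile:
    """Precompute the sorted order and clump structure of one feature."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    budget = _grid_budget(n, alpha)
    lmax = max(int(budget // 2), 2)
    order = np.argsort(x, kind="stable")
    clumps = _cap_clumps(_clump_ids(x[order]), max(c * lmax, 2))
    return _BinaryMicProfile(order, clumps, lmax, n)


def mic_binary_from_labels(profile: _BinaryMicProfile, y: np.ndarray) -> float:
    """MIC of the profiled feature against a binary 0/1 label vector.

    With a binary target the only y partition has two rows, so every
    admissible grid is (l columns x 2 rows) and the clump DP alone is
    optimal; the normalisation is log 2 throughout.
    """
    ys = np.asarray(y, dtype=np.int64)[profile.order]
    n1 = int(ys.sum())
    if n1 <= 0 or n1 >= profile.n:
        return 0.0
    cnt1 = np.bincount(profile.clumps, weights=ys, minlength=profile.m)
    sizes = np.bincount(profile.clumps, minlength=profile.m)
    pref1 = np.zeros(profile.m + 1, dtype=np.int64)
    pref1[1:] = np.cumsum(cnt1.astype(np.int64))
    pref_n = np.zeros(profile.m + 1, dtype=np.int64)
    pref_n[1:] = np.cumsum(sizes)
    pref0 = pref_n - pref1
    p1 = n1 / profile.n
    hq = -(p1 * log(p1) + (1 - p1) * log(1 - p1))
    return float(_dp_binary_best(pref0, pref1, profile.lmax, profile.xlx, hq))


@njit(cache=True)
def _mic_binary_many(labels_sorted: np.ndarray, clumps: np.ndarray, m: int,
                     lmax: int, xlx: np.ndarray) -> np.ndarray:
    """MIC of one profiled feature against many binary label vectors.

    ``labels_sorted`` is (n_vectors, n) with each row already reordered by
    the feature's sorted order.
    """
    n_vec, n = labels_sorted.shape
    out = np.zeros(n_vec)
    for v in range(n_vec):
        pref0 = np.zeros(m + 1, dtype=np.int64)
        pref1 = np.zeros(m + 1, dtype=np.int64)
        c0 = np.zeros(m, dtype=np.int64)
        c1 = np.zeros(m, dtype=np.int64)
        for i in range(n):
            if labels_sorted[v, i] > 0:
                c1[clumps[i]] += 1
            else:
                c0[clumps[i]] += 1
        t0 = 0
        t1 = 0
        for b in range(m):
            t0 += c0[b]
            t1 += c1[b]
            pref0[b + 1] = t0
            pref1[b + 1] = t1
        n1 = t1
        if n1 <= 0 or n1 >= n:
            out[v] = 0.0
            continue
        p1 = n1 / n
        hq = -(p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
        out[v] = _dp_binary_best(pref0, pref1, lmax, xlx, hq)
    return out


def mic_binary_batch(profile: _BinaryMicProfile, labels: np.ndarray) -> np.ndarray:
    """Vectorised :func:`mic_binary_from_labels` over rows of ``labels``."""
    lab = np.asarray(labels, dtype=np.int64)
    if lab.ndim == 1:
        lab = lab[None, :]
    return _mic_binary_many(np.ascontiguousarray(lab[:, profile.order]),
                            profile.clumps, profile.m, profile.lmax,
                            profile.xlx)
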