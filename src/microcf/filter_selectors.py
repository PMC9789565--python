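"""Filter-family feature selection: seven association statistics with
permutation significance and a per-cohort consensus vote.

The seven statistics scored against the binary obese/healthy label are
Pearson, Spearman and Kendall (tau-b) correlation, the maximal information
coefficient, and Pearson/Spearman/Kendall partial correlations that condition
each species on all other candidate species through the inverse of a shrunk
association matrix (species tables routinely have more features than
samples, so the feature block is shrunk toward the identity before
inversion).

Significance is assessed by label permutation with one shared permutation
matrix across species and methods, Benjamini-Hochberg adjusted across
species within each method; a species is selected when at least
``min_votes`` of the seven methods reach ``q < alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance_io import AbundanceTable
from .errors import DataError, DegenerateInputError, NumericalError
from .mic import mic_binary_batch, mic_binary_profile

FILTER_METHODS = (
    "pearson", "spearman", "kendall", "mic",
    "pearson_partial", "spearman_partial", "kendall_partial",
)


def correlation(x: np.ndarray, y: np.ndarray, method: str) -> float:
    """Plain pairwise association: Pearson, Spearman (midranks) or Kendall tau-b."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "kendall":
        return float(stats.kendalltau(x, y, variant="b").statistic)
    raise DataError(f"unknown method: {method}")


# ---------------------------------------------------------------------------
# vectorised statistics against (possibly many) binary label vectors
# ---------------------------------------------------------------------------

def _normalize_columns(x: np.ndarray) -> np.ndarray:
    """Center and scale columns to unit norm; constant columns become 0."""
    xc = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xc, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return xc / norms


def _pearson_vs_labels(xn: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Correlation of each unit-norm column with each binary label row.

    Returns (n_label_rows, p).  All permutations of a binary label share the
    same mean and norm, so one centering serves every row.
    """
    yc = labels - labels.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(yc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return (yc / norms) @ xn


def _kendall_vs_labels(ranks: np.ndarray, tie_pairs: np.ndarray,
                       labels: np.ndarray) -> np.ndarray:
    """Kendall tau-b of each column against binary label rows.

    With a binary target, concordant-minus-discordant equals 2U - n1*n0
    where U is the midrank Mann-Whitney statistic, and the tie term of the
    label contributes n1*n0 pairs; ``tie_pairs`` holds sum t(t-1)/2 per column.
    """
    n = ranks.shape[0]
    n1 = labels.sum(axis=1, keepdims=True).astype(float)
    n0 = n - n1
    u = labels @ ranks - n1 * (n1 + 1) / 2.0
    cd = 2.0 * u - n1 * n0
    total_pairs = n * (n - 1) / 2.0
    denom = np.sqrt((total_pairs - tie_pairs)[None, :] * (n1 * n0))
    denom[denom == 0] = np.inf
    return cd / denom


def _tie_pairs(x: np.ndarray) -> np.ndarray:
    """sum t(t-1)/2 over tied groups, per column."""
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        _, counts = np.unique(x[:, j], return_counts=True)
        out[j] = (counts * (counts - 1) / 2.0).sum()
    return out


def _kendall_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise tau-b association matrix of the columns of x."""
    p = x.shape[1]
    m = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if np.ptp(x[:, i]) == 0 or np.ptp(x[:, j]) == 0:
                tau = 0.0
            else:
                tau = stats.kendalltau(x[:, i], x[:, j], variant="b").statistic
                if not np.isfinite(tau):
                    tau = 0.0
            m[i, j] = m[j, i] = tau
    return m


def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    xn = _normalize_columns(x)
    m = xn.T @ xn
    np.fill_diagonal(m, 1.0)
    return m


def _auto_shrinkage_products(x: np.ndarray) -> float:
    """Ledoit-Wolf-style intensity for a correlation matrix.

    gamma* = sum var-hat(r_ij) / sum r_ij^2 over off-diagonals, with the
    variance of each entry estimated from the per-sample products of
    standardised scores (Schafer-Strimmer).
    """
    n, p = x.shape
    if p < 2:
        return 0.0
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    s = z.T @ z / (n - 1)  # correlation matrix
    w2 = (z ** 2).T @ (z ** 2)
    var_hat = n / float((n - 1) ** 3) * (w2 - (z.T @ z) ** 2 / n)
    off = ~np.eye(p, dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_hat[off].sum() / denom, 0.0, 1.0))


def _auto_shrinkage_kendall(tau: np.ndarray, n: int) -> float:
    """Shrinkage intensity for a tau-b matrix from the asymptotic null variance."""
    p = tau.shape[0]
    if p < 2:
        return 0.0
    var0 = 2.0 * (2 * n + 5) / (9.0 * n * (n - 1))
    off = ~np.eye(p, dtype=bool)
    denom = (tau[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(p * (p - 1) * var0 / denom, 0.0, 1.0))


def _shrink(m: np.ndarray, gamma: float) -> np.ndarray:
    out = (1.0 - gamma) * m
    np.fill_diagonal(out, 1.0)
    return out


def _partial_from_blocks(a_inv: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Partial correlation of each feature with the target given the rest.

    ``a_inv`` is the inverse of the (shrunk) feature association matrix and
    ``s`` the feature-target association vector(s), shape (p,) or (m, p).
    Uses the Schur complement of the bordered matrix, so the feature block is
    inverted once and reused across permutations.
    """
    single = s.ndim == 1
    sm = np.atleast_2d(s)
    u = sm @ a_inv  # (m, p)
    # s must arrive pre-shrunk by the same intensity as the feature block so
    # that the bordered matrix stays positive definite.
    pyy_inv = 1.0 - np.einsum("ij,ij->i", sm, u)
    # pyy_inv -> 0 when the conditioning set explains the target completely;
    # the clamp keeps the Schur complement finite, and features orthogonal to
    # the residual still come out ~0 because their numerator vanishes too.
    pyy_inv = np.maximum(pyy_inv, 1e-12)
    diag = np.diag(a_inv)
    denom = np.sqrt(pyy_inv[:, None] * diag[None, :] + u ** 2)
    denom[denom == 0] = np.inf
    out = np.clip(u / denom, -1.0, 1.0)
    return out[0] if single else out


def partial_correlation(features: np.ndarray, target: np.ndarray,
                        method: str = "pearson",
                        shrinkage: float | str = "auto") -> np.ndarray:
    """Association of each feature with the target given all other features.

    The pairwise association matrix of the features (mid-rank transformed
    for Spearman, pairwise tau-b for Kendall) is shrunk toward the identity
    by ``shrinkage`` (a fraction, or "auto" for an analytic intensity) and
    inverted; with a single feature this reduces to the plain statistic.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise DataError("features must be (n_samples, p) aligned with target")
    n, p = x.shape
    if n <= 3:
        raise DataError("need more than 3 samples")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant target")

    if method in ("pearson", "spearman"):
        xw = stats.rankdata(x, axis=0) if method == "spearman" else x
        yw = stats.rankdata(y) if method == "spearman" else y
        r_xx = _correlation_matrix(xw)
        xn = _normalize_columns(xw)
        s = _pearson_vs_labels(xn, yw[None, :])[0]
        gamma = _auto_shrinkage_products(xw) if shrinkage == "auto" else float(shrinkage)
    elif method == "kendall":
        r_xx = _kendall_matrix(x)
        s = np.array([
            stats.kendalltau(x[:, j], y, variant="b").statistic
            if np.ptp(x[:, j]) > 0 else 0.0
            for j in range(p)
        ])
        s = np.nan_to_num(s)
        gamma = _auto_shrinkage_kendall(r_xx, n) if shrinkage == "auto" else float(shrinkage)
    else:
        raise DataError(f"unknown method: {method}")

    r_sh = _shrink(r_xx, gamma)
    try:
        a_inv = np.linalg.inv(r_sh)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"feature association matrix not invertible "
                             f"after shrinkage gamma={gamma:.3f}") from exc
    return _partial_from_blocks(a_inv, (1.0 - gamma) * s)


# ---------------------------------------------------------------------------
# per-cohort consensus selection
# ---------------------------------------------------------------------------

@dataclass
class FilterSelection:
    """Outcome of the seven-method consensus on one cohort."""

    cohort: str
    selected: set[str]
    scores: pd.DataFrame  # species, method, statistic, p_value, q_value, selected
    alpha: float
    min_votes: int
    n_permutations: int
    seed: int

    def votes(self) -> pd.Series:
        per = self.scores.groupby("species")["selected"].sum()
        return per.reindex(sorted(per.index))


def _permutation_pvalues(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """p = (1 + #{|null| >= |obs|}) / (1 + n_perm), columnwise."""
    exceed = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
    return (1.0 + exceed) / (1.0 + null.shape[0])


def filter_select_cohort(table: AbundanceTable, cohort: str | None = None,
                         alpha: float = 0.05, min_votes: int = 4,
                         n_permutations: int = 999, seed: int = 0,
                         shrinkage: float | str = "auto",
                         mic_alpha: float = 0.6, mic_c: int = 15) -> FilterSelection:
    """Run all seven filter statistics on one cohort and take the vote.

    For each species and method the statistic is computed against the binary
    group label together with a label-permutation p-value (one shared
    permutation set), BH-adjusted across species within the method; a method
    votes for a species at ``q < alpha`` and the species is selected at
    ``votes >= min_votes``.
    """
    sub = table.subset_cohort(cohort) if cohort is not None else table
    label = cohort if cohort is not None else "all"
    y = sub.group_labels()
    if y.min() == y.max():
        raise DataError(f"cohort {label!r} lacks one of the groups")
    x = sub.matrix()
    n, p = x.shape
    species = sub.species_ids

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=np.int64)
    for i in range(n_permutations):
        perms[i] = y[rng.permutation(n)]
    all_labels = np.vstack([y[None, :], perms])  # row 0 = observed

    stats_by_method: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # pearson / spearman via one matmul each
    xn = _normalize_columns(x)
    r_all = _pearson_vs_labels(xn, all_labels.astype(float))
    stats_by_method["pearson"] = (r_all[0], r_all[1:])

    xr = stats.rankdata(x, axis=0)
    xrn = _normalize_columns(xr)
    rs_all = _pearson_vs_labels(xrn, all_labels.astype(float))
    stats_by_method["spearman"] = (rs_all[0], rs_all[1:])

    tie = _tie_pairs(x)
    tau_all = _kendall_vs_labels(xr, tie, all_labels.astype(float))
    stats_by_method["kendall"] = (tau_all[0], tau_all[1:])

    mic_all = np.empty((all_labels.shape[0], p))
    for j in range(p):
        if np.ptp(x[:, j]) == 0:
            mic_all[:, j] = 0.0
            continue
        prof = mic_binary_profile(x[:, j], alpha=mic_alpha, c=mic_c)
        mic_all[:, j] = mic_binary_batch(prof, all_labels)
    stats_by_method["mic"] = (mic_all[0], mic_all[1:])

    # partials: invert the shrunk feature block once, reuse across labels
    for method, base in (("pearson", x), ("spearman", xr)):
        r_xx = _correlation_matrix(base)
        gamma = _auto_shrinkage_products(base) if shrinkage == "auto" else float(shrinkage)
        a_inv = np.linalg.inv(_shrink(r_xx, gamma))
        obs_s, null_s = stats_by_method[method]
        s_stack = (1.0 - gamma) * np.vstack([obs_s[None, :], null_s])
        part = _partial_from_blocks(a_inv, s_stack)
        stats_by_method[f"{method}_partial"] = (part[0], part[1:])

    r_xx = _kendall_matrix(x)
    gamma = _auto_shrinkage_kendall(r_xx, n) if shrinkage == "auto" else float(shrinkage)
    a_inv = np.linalg.inv(_shrink(r_xx, gamma))
    part = _partial_from_blocks(a_inv, (1.0 - gamma) * tau_all)
    stats_by_method["kendall_partial"] = (part[0], part[1:])

    records = []
    votes = np.zeros(p, dtype=int)
    for method in FILTER_METHODS:
        obs, null = stats_by_method[method]
        pvals = _permutation_pvalues(obs, null)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        sel = qvals < alpha
        votes += sel.astype(int)
        for j in range(p):
            records.append((species[j], method, float(obs[j]),
                            float(pvals[j]), float(qvals[j]), bool(sel[j])))
    selected = {species[j] for j in range(p) if votes[j] >= min_votes}
    scores = pd.DataFrame(records, columns=["species", "method", "statistic",
                                            "p_value", "q_value", "selected"])
    return FilterSelection(cohort=label, selected=selected, scores=scores,
                           alpha=alpha, min_votes=min_votes,
                           n_permutations=n_permutations, seed=seed)
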