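"""Distance matrices and permutation dissimilarity tests (ANOSIM, Adonis,
MRPP) plus a generic Mantel test.

All permutation p-values use the add-one estimator
``p = (1 + #{permuted at-least-as-extreme}) / (1 + n_permutations)`` and are
reproducible for a fixed seed.  Permutation labels are drawn uniformly (with
possible repeats of the identity), which keeps the estimator unbiased.

The per-statistic definitions:

* ANOSIM ``R = (rbar_between - rbar_within) / (M/2)`` on ranked distances,
  ``M = n(n-1)/2``; large R indicates group separation.
* Adonis (PERMANOVA) pseudo-F from the distance-based partition of sums of
  squares: ``SS_total = sum d^2 / n``, ``SS_within = sum_g sum_{i<j in g}
  d_ij^2 / n_g``; ``R^2 = 1 - SS_within/SS_total``.
* MRPP ``delta = sum_g (n_g/N) * mean within-group distance``; small delta
  indicates within-group tightness; the chance-corrected agreement is
  ``A = 1 - delta / E[delta under permutation]``.
* Mantel ``r``: Pearson or Spearman correlation of paired distance entries
  (upper triangle in matrix mode), null by simultaneous row/column
  permutation of one matrix, or by element permutation in vector mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from menanet.otu_io import OtuTable
from menanet.result import TestResult

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "anosim",
    "adonis",
    "mrpp",
    "mantel",
    "anosim_statistic",
    "adonis_statistic",
    "mrpp_statistic",
]


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative pairwise distances."""

    ids: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def distance_matrix(table: OtuTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample dissimilarities: bray_curtis, jaccard, or euclidean.

    Bray-Curtis is ``sum|x-y| / sum(x+y)``; Jaccard operates on
    presence/absence.
    """
    X = table.counts.astype(float)
    if metric == "bray_curtis":
        if np.any(X.sum(axis=1) == 0):
            raise ValueError("Bray-Curtis undefined for zero-total samples")
        d = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(X > 0, metric="jaccard")
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(table.sample_ids), squareform(d), metric)


# ---------------------------------------------------------------------------
# statistic kernels (observed labels or batches of permuted labels)
# ---------------------------------------------------------------------------

def _encode_groups(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, dict):
        labels = [groups[s] for s in dm.ids]
    else:
        labels = list(groups)
        if len(labels) != dm.n:
            raise ValueError("groups length does not match distance matrix")
    _, codes = np.unique(np.asarray(labels, dtype=object).astype(str), return_inverse=True)
    if codes.max() < 1:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 members")
    return codes


def _pair_indices(n: int):
    return np.triu_indices(n, k=1)

def anosim_statistic(dm: DistanceMatrix, groups) -> float:
    """ANOSIM R for the observed grouping."""
    codes = _encode_groups(dm, groups)
    iu = _pair_indices(dm.n)
    ranks = rankdata(dm.values[iu])
    return float(_anosim_batch(ranks, iu, codes[None, :])[0])


def _anosim_batch(ranks: np.ndarray, iu, P: np.ndarray) -> np.ndarray:
    """R for each row of label matrix P (shape n_perm x n)."""
    within = P[:, iu[0]] == P[:, iu[1]]
    m = ranks.size
    total = ranks.sum()
    sw = within @ ranks
    cw = within.sum(axis=1)
    rw = sw / cw
    rb = (total - sw) / (m - cw)
    return (rb - rw) / (m / 2.0)


def adonis_statistic(dm: DistanceMatrix, groups) -> tuple[float, float]:
    """(pseudo-F, R^2) for the observed grouping."""
    codes = _encode_groups(dm, groups)
    iu = _pair_indices(dm.n)
    d2 = dm.values[iu] ** 2
    f, r2 = _adonis_batch(d2, iu, codes[None, :], dm.n)
    return float(f[0]), float(r2[0])


def _adonis_batch(d2: np.ndarray, iu, P: np.ndarray, n: int):
    k = P.max() + 1
    sizes = np.bincount(P[0], minlength=k)  # group sizes invariant under permutation
    ss_total = d2.sum() / n
    ss_within = np.zeros(P.shape[0])
    for g in range(k):
        mask = (P[:, iu[0]] == g) & (P[:, iu[1]] == g)
        ss_within += (mask @ d2) / sizes[g]
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):  # ss_within = 0 gives F = inf
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total
    return f, r2


def mrpp_statistic(dm: DistanceMatrix, groups) -> float:
    """Weighted mean within-group distance delta for the observed grouping."""
    codes = _encode_groups(dm, groups)
    iu = _pair_indices(dm.n)
    return float(_mrpp_batch(dm.values[iu], iu, codes[None, :])[0])


def _mrpp_batch(d: np.ndarray, iu, P: np.ndarray) -> np.ndarray:
    k = P.max() + 1
    sizes = np.bincount(P[0], minlength=k)
    n = sizes.sum()
    delta = np.zeros(P.shape[0])
    for g in range(k):
        mask = (P[:, iu[0]] == g) & (P[:, iu[1]] == g)
        n_pairs = sizes[g] * (sizes[g] - 1) / 2
        delta += (sizes[g] / n) * (mask @ d) / n_pairs
    return delta


def _permute_labels(codes: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)


def _addone_p(perm_stats: np.ndarray, observed: float, direction: str) -> float:
    if direction == "greater":
        count = int(np.sum(perm_stats >= observed))
    else:
        count = int(np.sum(perm_stats <= observed))
    return (1 + count) / (1 + perm_stats.size)


# ---------------------------------------------------------------------------
# public tests
# ---------------------------------------------------------------------------

def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Analysis of similarities; large R means between-group > within-group."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = _encode_groups(dm, groups)
    iu = _pair_indices(dm.n)
    ranks = rankdata(dm.values[iu])
    obs = float(_anosim_batch(ranks, iu, codes[None, :])[0])
    rng = np.random.default_rng(seed)
    P = _permute_labels(codes, n_perm, rng)
    perm = _anosim_batch(ranks, iu, P)
    return TestResult("R", obs, _addone_p(perm, obs, "greater"), n_perm, seed)


def adonis(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Distance-based multivariate ANOVA (PERMANOVA); reports pseudo-F and R^2."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = _encode_groups(dm, groups)
    iu = _pair_indices(dm.n)
    d2 = dm.values[iu] ** 2
    f_obs, r2 = _adonis_batch(d2, iu, codes[None, :], dm.n)
    obs = float(f_obs[0])
    rng = np.random.default_rng(seed)
    P = _permute_labels(codes, n_perm, rng)
    perm, _ = _adonis_batch(d2, iu, P, dm.n)
    return TestResult(
        "pseudo_F", obs, _addone_p(perm, obs, "greater"), n_perm, seed,
        extra={"R2": float(r2[0])},
    )


def mrpp(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> TestResult:
    """Multi-response permutation procedure; small delta means tight groups.

    The chance-corrected within-group agreement ``A = 1 - delta/E[delta]``
    (expectation over sampled permutations) is reported in ``extra``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = _encode_groups(dm, groups)
    iu = _pair_indices(dm.n)
    d = dm.values[iu]
    obs = float(_mrpp_batch(d, iu, codes[None, :])[0])
    rng = np.random.default_rng(seed)
    P = _permute_labels(codes, n_perm, rng)
    perm = _mrpp_batch(d, iu, P)
    a = 1.0 - obs / float(perm.mean())
    return TestResult(
        "delta", obs, _addone_p(perm, obs, "less"), n_perm, seed, extra={"A": a}
    )


def _as_paired_vectors(a, b):
    """Return (x, y, ids_or_None, mode) for matrix or vector Mantel input."""
    if isinstance(a, DistanceMatrix) and isinstance(b, DistanceMatrix):
        if a.ids != b.ids:
            raise ValueError("distance matrices have mismatched ids")
        return a, b, "matrix"
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vector Mantel needs two equal-length 1-D vectors")
    return a, b, "vector"


def mantel(a, b, n_perm: int = 999, seed: int = 0, method: str = "pearson") -> TestResult:
    """Mantel correlation between two distance matrices or two vectors.

    Matrix mode permutes rows/columns of ``a`` simultaneously; vector mode
    permutes elements of ``a``.  One-sided (positive association).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    a, b, mode = _as_paired_vectors(a, b)
    rng = np.random.default_rng(seed)
    if mode == "matrix":
        n = a.n
        iu = _pair_indices(n)
        av_full = a.values
        x = av_full[iu]
        y = b.values[iu]
        P = _permute_labels(np.arange(n), n_perm, rng)
        xp = av_full[P[:, iu[0]], P[:, iu[1]]]
    else:
        x, y = a, b
        n = x.size
        if n < 3:
            raise ValueError("need at least 3 paired observations")
        P = _permute_labels(np.arange(n), n_perm, rng)
        xp = x[P]
    if method == "spearman":
        x = rankdata(x)
        y = rankdata(y)
        xp = rankdata(xp, axis=1)
    ys = (y - y.mean()) / y.std()
    xs = (x - x.mean()) / x.std()
    obs = float((xs * ys).mean())
    xp_c = xp - xp.mean(axis=1, keepdims=True)
    xp_sd = xp.std(axis=1)
    perm = (xp_c @ ys) / xp.shape[1] / xp_sd
    return TestResult("r", obs, _addone_p(perm, obs, "greater"), n_perm, seed)
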