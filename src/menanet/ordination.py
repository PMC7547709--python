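"""Correspondence-analysis ordination: CA, DCA and CCA.

Correspondence analysis (CA) eigen-decomposes the chi-square standardised
abundance matrix ``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` (``P`` the
proportion matrix, ``r``/``c`` its row/column mass vectors); eigenvalues are
the squared singular values of ``S`` and total inertia is ``||S||_F^2``.

Detrended correspondence analysis (DCA) removes the arch artifact by
detrending each higher axis against axis 1: the axis-1 range is cut into
equal-width segments and the segment mean of the higher-axis site scores is
subtracted.  Optional rescaling expresses axes in within-segment
standard-deviation units.

Canonical correspondence analysis (CCA) constrains the site scores to linear
combinations of (internally standardised) environmental variables via a
weighted least-squares projection inside the CA decomposition; the residual
space yields the unconstrained axes, and the constrained + unconstrained
eigenvalues partition the total inertia exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from menanet.otu_io import EnvTable, OtuTable
from menanet.result import TestResult

__all__ = ["CaResult", "CcaResult", "correspondence_analysis", "dca", "cca",
           "cca_permutation_test"]

_EPS = 1e-12


@dataclass
class CaResult:
    """(Detrended) correspondence analysis output."""

    eigenvalues: np.ndarray
    site_scores: np.ndarray        # samples x axes, principal coordinates
    species_scores: np.ndarray     # OTUs x axes
    total_inertia: float
    sample_ids: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)
    detrended: bool = False


@dataclass
class CcaResult:
    """Canonical correspondence analysis output."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: np.ndarray        # LC scores (constrained axes)
    species_scores: np.ndarray
    biplot_scores: np.ndarray      # variables x constrained axes
    pct_explained_axis: np.ndarray # per constrained axis, % of total inertia
    cumulative_pct: np.ndarray
    total_inertia: float
    sample_ids: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)
    variables: list[str] = field(default_factory=list)

    @property
    def constrained_pct(self) -> float:
        """Percent of total inertia captured by all constrained axes."""
        return 100.0 * float(self.constrained_eigenvalues.sum()) / self.total_inertia


def _drop_empty(table: OtuTable):
    X = table.counts.astype(float)
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn(
            f"dropping {int((~row_ok).sum())} empty sample(s) and "
            f"{int((~col_ok).sum())} empty OTU(s) before ordination",
            UserWarning,
            stacklevel=3,
        )
    X = X[np.ix_(row_ok, col_ok)]
    samples = [s for s, k in zip(table.sample_ids, row_ok) if k]
    otus = [o for o, k in zip(table.otu_ids, col_ok) if k]
    return X, samples, otus


def _chi_square_standardize(X: np.ndarray):
    """Return (S, r, c): standardized matrix and row/column masses."""
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return S, r, c


def _fix_signs(site_scores: np.ndarray, species_scores: np.ndarray,
               sample_ids: list[str]):
    """Flip each axis so the lexicographically smallest sample id scores >= 0."""
    order = np.argsort(np.asarray(sample_ids, dtype=object).astype(str))
    for k in range(site_scores.shape[1]):
        col = site_scores[:, k]
        for i in order:
            if abs(col[i]) > _EPS:
                if col[i] < 0:
                    site_scores[:, k] = -site_scores[:, k]
                    species_scores[:, k] = -species_scores[:, k]
                break
    return site_scores, species_scores


def correspondence_analysis(table: OtuTable, n_axes: int | None = None) -> CaResult:
    """Plain CA of an OTU table.

    Site and species scores are principal coordinates
    (``F = D_r^{-1/2} U Sigma``, ``G = D_c^{-1/2} V Sigma``), which satisfy
    the reciprocal-averaging relation
    ``F_ik = sigma_k^{-1} * sum_j (p_ij/r_i) G_jk``.
    """
    X, samples, otus = _drop_empty(table)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 non-empty samples and 2 non-empty OTUs")
    S, r, c = _chi_square_standardize(X)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    total_inertia = float((sv ** 2).sum())
    rank = int(np.sum(sv > 1e-9))
    if n_axes is None:
        n_axes = rank
    n_axes = min(n_axes, rank) if rank else 1
    sv = sv[:n_axes]
    F = (U[:, :n_axes] * sv) / np.sqrt(r)[:, None]
    G = (Vt[:n_axes].T * sv) / np.sqrt(c)[:, None]
    F, G = _fix_signs(F, G, samples)
    return CaResult(sv ** 2, F, G, total_inertia, samples, otus)


def _detrend_by_segments(axis1: np.ndarray, higher: np.ndarray,
                         n_segments: int) -> np.ndarray:
    lo, hi = axis1.min(), axis1.max()
    edges = np.linspace(lo, hi, n_segments + 1)
    seg = np.clip(np.searchsorted(edges, axis1, side="right") - 1, 0, n_segments - 1)
    out = higher.copy()
    for s in np.unique(seg):
        mask = seg == s
        out[mask] -= out[mask].mean()
    return out


def dca(table: OtuTable, n_segments: int = 26, rescale: bool = False,
        n_axes: int = 4) -> CaResult:
    """Detrended correspondence analysis.

    Axis 1 is the CA axis 1 (ordering preserved exactly); axes 2+ are the CA
    axes detrended by segment-wise mean centering against axis 1.  With
    ``rescale`` set, each axis is divided by its weighted standard deviation
    so scores are in SD units.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    ca_res = correspondence_analysis(table, n_axes=n_axes)
    F = ca_res.site_scores.copy()
    for k in range(1, F.shape[1]):
        F[:, k] = _detrend_by_segments(F[:, 0], F[:, k], n_segments)
    if rescale:
        sd = F.std(axis=0)
        sd[sd < _EPS] = 1.0
        F = F / sd
    # species scores by weighted averaging of the (detrended) site scores
    X = table.to_dataframe().loc[ca_res.sample_ids, ca_res.otu_ids].to_numpy(float)
    colsum = X.sum(axis=0)
    G = (X.T @ F) / colsum[:, None]
    return CaResult(ca_res.eigenvalues, F, G, ca_res.total_inertia,
                    ca_res.sample_ids, ca_res.otu_ids, detrended=True)


def _standardize_env(env_values: np.ndarray, weights: np.ndarray,
                     variables: list[str]) -> np.ndarray:
    """Weighted-center and scale env variables; error on constant columns."""
    w = weights / weights.sum()
    mu = w @ env_values
    E = env_values - mu
    sd = np.sqrt(w @ (E ** 2))
    bad = [v for v, s in zip(variables, sd) if s < 1e-12]
    if bad:
        raise ValueError(f"constant environmental variable(s): {bad}")
    return E / sd


def _check_collinear(Y: np.ndarray, variables: list[str], tol: float = 1e8) -> None:
    gram = Y.T @ Y
    cond = np.linalg.cond(gram)
    if cond > tol:
        # name the variables loading on the near-null space
        w, v = np.linalg.eigh(gram)
        load = np.abs(v[:, 0])
        names = [variables[i] for i in np.argsort(load)[::-1][:3] if load[i] > 0.1]
        raise ValueError(
            f"environmental matrix is collinear (condition number {cond:.3g}); "
            f"suspect variables: {names}"
        )


def cca(table: OtuTable, env: EnvTable, n_axes: int | None = None) -> CcaResult:
    """Canonical correspondence analysis of a community against env variables."""
    X, samples, otus = _drop_empty(table)
    if samples != list(env.sample_ids):
        if set(samples) <= set(env.sample_ids):
            env = env.select_samples(samples)
        else:
            raise ValueError("env table does not cover the community samples")
    n, q = X.shape[0], len(env.variables)
    if n <= q + 1:
        raise ValueError(
            f"CCA needs n_samples > n_variables + 1 (got n={n}, q={q})"
        )
    S, r, c = _chi_square_standardize(X)
    total_inertia = float((S ** 2).sum())
    if q == 0:
        # empty constraint set: degenerate to plain CA in the residual space
        Y = np.zeros((n, 0))
        S_fit = np.zeros_like(S)
    else:
        E = _standardize_env(env.values, r, list(env.variables))
        Y = np.sqrt(r)[:, None] * E          # row-weighted env design
        _check_collinear(Y, list(env.variables))
        H = Y @ np.linalg.solve(Y.T @ Y, Y.T)
        S_fit = H @ S
    U, sv, Vt = np.linalg.svd(S_fit, full_matrices=False)
    rank_c = min(q, int(np.sum(sv > 1e-9)))
    if n_axes is None:
        n_axes = rank_c
    n_axes = min(n_axes, rank_c) if rank_c else 1
    sv_c = sv[:n_axes]
    eig_c = sv[:rank_c] ** 2
    # residual (unconstrained) axes
    S_res = S - S_fit
    sv_res = np.linalg.svd(S_res, compute_uv=False)
    eig_u = sv_res[sv_res > 1e-9] ** 2
    # LC site scores (principal coordinates of the fitted space)
    F = (U[:, :n_axes] * sv_c) / np.sqrt(r)[:, None]
    G = (Vt[:n_axes].T * sv_c) / np.sqrt(c)[:, None]
    F, G = _fix_signs(F, G, samples)
    # biplot scores: weighted correlation of each env variable with each axis
    axis_std = U[:, :n_axes]             # unit-norm site axes in weighted space
    biplot = np.empty((q, n_axes))
    for j in range(q):
        yj = Y[:, j] / np.linalg.norm(Y[:, j])
        biplot[j] = yj @ axis_std
    pct = 100.0 * eig_c[:n_axes] / total_inertia
    cum = np.cumsum(100.0 * eig_c / total_inertia)[:n_axes]
    return CcaResult(eig_c, eig_u, F, G, biplot, pct, cum, total_inertia,
                     samples, otus, list(env.variables))


def cca_permutation_test(table: OtuTable, env: EnvTable, n_perm: int = 999,
                         seed: int = 0) -> TestResult:
    """Permutation significance of the constrained inertia share.

    Permutes sample rows of the environmental table and recomputes the
    fraction of total inertia captured by the constrained space.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = cca(table, env)
    obs = res.constrained_pct
    rng = np.random.default_rng(seed)
    count = 0
    vals = env.values
    for _ in range(n_perm):
        perm = rng.permutation(len(env.sample_ids))
        env_p = EnvTable(list(env.sample_ids), list(env.variables), vals[perm])
        stat = cca(table, env_p).constrained_pct
        if stat >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("constrained_pct", obs, p, n_perm, seed)
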