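"""Random-Matrix-Theory (RMT) molecular ecological network analysis.

The pipeline mirrors the established RMT approach to co-occurrence network
construction: OTU counts are log10-transformed after a prevalence filter
("lg matrix"), pairwise Pearson correlations give a similarity matrix
``s = |r|`` (signs kept separately), and a hard threshold is chosen
automatically from the matrix spectrum.  At a series of candidate
thresholds, entries below the threshold are zeroed and the nearest-neighbour
spacing distribution (NNSD) of the unfolded eigenvalues is tested: below the
transition the NNSD follows the Gaussian orthogonal ensemble (GOE, Wigner
surmise ``(pi/2) d exp(-pi d^2/4)``); once the surviving structure is
modular/local it follows Poisson statistics ``exp(-d)``.  The smallest
threshold whose NNSD is accepted as Poisson defines the adjacency matrix.

The resulting signed, unweighted network is summarised by mean degree
(connectivity), average shortest-path distance over connected pairs, mean
local clustering coefficient, and modularity of a greedy modularity-maximising
partition.  Node topological roles follow the within-module degree z-score
(Zi) and the among-module participation coefficient (Pi), with the usual
cutoffs Zi >= 2.5 (module hub) and Pi >= 0.62 (connector).

Gene significance (GS) of a node for an environmental variable is the
squared Pearson correlation of its abundance profile with the variable; a
vector-mode Mantel test links node connectivity (degree) to GS per variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats
from scipy.interpolate import PchipInterpolator

from menanet.community_tests import mantel
from menanet.otu_io import EnvTable, OtuTable
from menanet.result import TestResult

__all__ = [
    "LogAbundanceMatrix",
    "SimilarityMatrix",
    "ThresholdScanResult",
    "EcologicalNetwork",
    "NetworkStats",
    "NodeRole",
    "RmtScanError",
    "prepare_log_matrix",
    "similarity_matrix",
    "unfold_spectrum",
    "nnsd_chi_square",
    "rmt_threshold_scan",
    "build_network",
    "detect_modules",
    "topology",
    "node_roles",
    "gene_significance",
    "connectivity_gs_test",
    "write_edge_list",
    "write_graphml",
    "write_node_roles",
    "write_network_stats",
    "write_threshold_scan",
]


class RmtScanError(RuntimeError):
    """Raised when no threshold in the scan grid passes the Poisson test."""


@dataclass
class LogAbundanceMatrix:
    """Prevalence-filtered log10 abundances, OTUs x samples."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_otus, n_samples), finite

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match (otus, samples)")
        if not np.all(np.isfinite(v)):
            raise ValueError("log-abundance matrix must be finite")
        self.values = v


@dataclass
class SimilarityMatrix:
    """|Pearson r| similarity with the correlation signs kept separately."""

    otu_ids: list[str]
    s: np.ndarray
    sign: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        n = len(self.otu_ids)
        if s.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self.s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.s, 1.0)
        self.sign = np.sign(np.asarray(self.sign, dtype=float)).astype(np.int8)
        self.sign[self.sign == 0] = 1

    @property
    def n(self) -> int:
        return len(self.otu_ids)


@dataclass
class ThresholdScanResult:
    thresholds: np.ndarray
    chi_square_poisson: np.ndarray
    p_poisson: np.ndarray
    chi_square_goe: np.ndarray
    p_goe: np.ndarray
    n_spacings: np.ndarray
    chosen_threshold: float
    spacings: dict[float, np.ndarray] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_spacings": self.n_spacings,
                "chi_square_poisson": self.chi_square_poisson,
                "p_poisson": self.p_poisson,
                "chi_square_goe": self.chi_square_goe,
                "p_goe": self.p_goe,
            }
        )


@dataclass
class EcologicalNetwork:
    """Signed undirected co-occurrence graph with an optional module partition."""

    graph: nx.Graph
    otu_ids: list[str]                      # nodes, degree >= 1
    threshold: float
    modules: list[set] | None = None        # partition of nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def module_of(self) -> dict:
        if self.modules is None:
            raise ValueError("modules not yet detected")
        return {n: i for i, mod in enumerate(self.modules) for n in mod}


@dataclass
class NetworkStats:
    total_nodes: int
    total_links: int
    positive_link_pct: float
    avg_connectivity: float
    avg_path_distance: float
    avg_clustering_coefficient: float
    modularity: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Total nodes": self.total_nodes,
                "Total links": self.total_links,
                "Positive link percentage (%)": self.positive_link_pct,
                "Connectivity": self.avg_connectivity,
                "Average path distance": self.avg_path_distance,
                "Clustering coefficient": self.avg_clustering_coefficient,
                "Modularity": self.modularity,
            }
        )


@dataclass
class NodeRole:
    otu_id: str
    module: int
    degree: int
    zi: float
    pi: float
    role: str


# ---------------------------------------------------------------------------
# similarity construction
# ---------------------------------------------------------------------------

def prepare_log_matrix(table: OtuTable, min_prevalence_fraction: float = 0.5,
                       zero_fill: float = 0.01) -> LogAbundanceMatrix:
    """Prevalence-filter OTUs and log10-transform counts (the "lg matrix").

    OTUs present (count > 0) in fewer than ``min_prevalence_fraction`` of
    samples are dropped; remaining zeros are replaced by ``zero_fill`` before
    log10 so the output is finite.
    """
    if not 0 < min_prevalence_fraction <= 1:
        raise ValueError("min_prevalence_fraction must be in (0, 1]")
    if zero_fill <= 0:
        raise ValueError("zero_fill must be positive")
    X = table.counts.T.astype(float)  # OTUs x samples
    prevalence = (X > 0).mean(axis=1)
    keep = prevalence >= min_prevalence_fraction
    if not np.any(keep):
        raise ValueError(
            f"no OTU present in >= {min_prevalence_fraction:.0%} of samples"
        )
    X = X[keep]
    X[X == 0] = zero_fill
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return LogAbundanceMatrix(otu_ids, list(table.sample_ids), np.log10(X))


def similarity_matrix(logmat: LogAbundanceMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation across samples, split into |r| and sign."""
    if len(logmat.sample_ids) < 3:
        raise ValueError("need at least 3 samples for correlations")
    V = logmat.values
    sd = V.std(axis=1)
    keep = sd > 1e-12
    if not np.all(keep):
        dropped = [o for o, k in zip(logmat.otu_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} constant OTU(s) with undefined correlation",
            UserWarning,
            stacklevel=2,
        )
        V = V[keep]
    otu_ids = [o for o, k in zip(logmat.otu_ids, keep) if k]
    if len(otu_ids) < 2:
        raise ValueError("fewer than 2 non-constant OTUs")
    r = np.corrcoef(V)
    r = np.clip(r, -1.0, 1.0)
    return SimilarityMatrix(otu_ids, np.abs(r), np.sign(r))


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------

def unfold_spectrum(eigenvalues, method: str = "cdf_spline", degree: int = 5,
                    n_knots: int = 20) -> np.ndarray:
    """Map eigenvalues to unit-mean nearest-neighbour spacings.

    ``cdf_spline`` (default) fits a monotone piecewise-cubic interpolant
    through ~``n_knots`` quantile knots of the empirical cumulative spectral
    function and evaluates it at every eigenvalue; ``polynomial`` fits a
    degree-``degree`` polynomial to the empirical CDF instead.  Spacings are
    differences of the unfolded values, rescaled to exact unit mean.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    n = lam.size
    if n < 20:
        raise ValueError(f"need >= 20 eigenvalues for an NNSD, got {n}")
    positions = np.arange(1, n + 1, dtype=float)
    if method == "cdf_spline":
        # knots must stay sparse relative to n, else the interpolant passes
        # through every point and the spacing fluctuations are destroyed
        k = max(3, min(n_knots, n // 10))
        step = max(2, int(np.ceil(n / k)))
        idx = np.unique(np.r_[np.arange(0, n, step), n - 1])
        xk, yk = [lam[idx[0]]], [positions[idx[0]]]
        for i in idx[1:]:
            if lam[i] > xk[-1] + 1e-12:
                xk.append(lam[i])
                yk.append(positions[i])
        if len(xk) < 3:
            raise ValueError("spectrum too degenerate to unfold")
        cdf = PchipInterpolator(np.asarray(xk), np.asarray(yk))
        e = cdf(lam)
    elif method == "polynomial":
        coeffs = np.polynomial.polynomial.polyfit(lam, positions, degree)
        e = np.polynomial.polynomial.polyval(lam, coeffs)
    else:
        raise ValueError(f"unknown unfolding method {method!r}")
    d = np.diff(np.sort(e))
    mean = d.mean()
    if mean <= 0:
        raise ValueError("degenerate unfolded spectrum")
    return d / mean


def _reference_bin_edges(reference: str, n_bins: int) -> np.ndarray:
    """Equal-probability bin edges under the reference spacing density."""
    q = np.linspace(0, 1, n_bins + 1)[1:-1]
    if reference == "poisson":        # CDF 1 - exp(-s)
        inner = -np.log1p(-q)
    elif reference == "goe":          # Wigner surmise CDF 1 - exp(-pi s^2/4)
        inner = np.sqrt(-4.0 * np.log1p(-q) / np.pi)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return np.r_[0.0, inner, np.inf]


def nnsd_chi_square(spacings, reference: str = "poisson",
                    n_bins: int | None = None) -> tuple[float, float]:
    """Chi-square goodness of fit of unit-mean spacings to Poisson or GOE.

    Bins are equal-probability under the reference density (matched bin
    masses), so expected counts are uniform and no bin merging is needed.
    Returns ``(statistic, p)`` with ``df = n_bins - 1``.
    """
    d = np.asarray(spacings, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 spacings")
    if n_bins is None:
        n_bins = int(np.clip(d.size // 20, 5, 40))
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    edges = _reference_bin_edges(reference, n_bins)
    observed, _ = np.histogram(d, bins=edges)
    expected = d.size / n_bins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=n_bins - 1))
    return chi2, p


def _thresholded_unique_eigenvalues(s: np.ndarray, threshold: float,
                                    decimals: int = 8) -> np.ndarray:
    W = np.where(s >= threshold, s, 0.0)
    np.fill_diagonal(W, 1.0)
    lam = np.linalg.eigvalsh(W)
    return np.unique(np.round(lam, decimals))


def rmt_threshold_scan(sim: SimilarityMatrix, s_min: float = 0.30,
                       s_max: float = 0.99, step: float = 0.01,
                       alpha: float = 0.05, min_eigenvalues: int = 20,
                       unfold_method: str = "cdf_spline") -> ThresholdScanResult:
    """Scan thresholds and choose the smallest whose NNSD is Poisson.

    At each grid threshold, similarity entries below it are zeroed, the
    eigenvalues of the thresholded matrix are deduplicated (degenerate
    eigenvalues carry no spacing information), unfolded, and the NNSD is
    chi-square-tested against both Poisson and GOE references.  The chosen
    threshold is the smallest grid value with Poisson p > ``alpha``.

    A threshold that leaves fewer than ``min_eigenvalues`` distinct
    eigenvalues produces a (near-)diagonal matrix, which has no level
    correlations by construction; such thresholds are accepted as already
    decorrelated (their test statistics are reported as NaN).
    """
    if not (0 <= s_min < s_max <= 1):
        raise ValueError("need 0 <= s_min < s_max <= 1")
    grid = np.round(np.arange(s_min, s_max + step / 2, step), 10)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    chi_p = np.full(grid.size, np.nan)
    p_p = np.full(grid.size, np.nan)
    chi_g = np.full(grid.size, np.nan)
    p_g = np.full(grid.size, np.nan)
    n_sp = np.zeros(grid.size, dtype=int)
    spacings_by_t: dict[float, np.ndarray] = {}
    chosen = None
    for i, t in enumerate(grid):
        lam = _thresholded_unique_eigenvalues(sim.s, t)
        accepted = False
        if lam.size < min_eigenvalues:
            accepted = True  # spectrum too degenerate to carry correlations
        else:
            try:
                d = unfold_spectrum(lam, method=unfold_method)
            except ValueError:
                accepted = True
                d = None
            if d is not None:
                n_sp[i] = d.size
                spacings_by_t[float(t)] = d
                chi_p[i], p_p[i] = nnsd_chi_square(d, "poisson")
                chi_g[i], p_g[i] = nnsd_chi_square(d, "goe")
                accepted = p_p[i] > alpha
        if chosen is None and accepted:
            chosen = float(t)
    if chosen is None:
        raise RmtScanError(
            "no threshold in the grid passed the Poisson NNSD test; "
            "widen the grid or check that the similarity matrix has structure"
        )
    return ThresholdScanResult(grid, chi_p, p_p, chi_g, p_g, n_sp, chosen,
                               spacings_by_t)


# ---------------------------------------------------------------------------
# network construction & topology
# ---------------------------------------------------------------------------

def build_network(sim: SimilarityMatrix, threshold: float) -> EcologicalNetwork:
    """Adjacency by hard threshold: edge iff ``s_ij >= threshold`` (i != j).

    Edge attributes: ``sign`` (+1/-1 from the correlation sign) and
    ``similarity``.  Isolated nodes are removed; an empty edge set is an
    error.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    g = nx.Graph()
    n = sim.n
    iu, ju = np.triu_indices(n, k=1)
    mask = sim.s[iu, ju] >= threshold
    if not np.any(mask):
        raise ValueError(f"no edge survives threshold {threshold}")
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(
            sim.otu_ids[i],
            sim.otu_ids[j],
            sign=int(sim.sign[i, j]),
            similarity=float(sim.s[i, j]),
        )
    nodes = [o for o in sim.otu_ids if o in g]
    return EcologicalNetwork(g, nodes, float(threshold))


class _PartitionState:
    """Incremental modularity bookkeeping for local refinement moves."""

    def __init__(self, g: nx.Graph, modules: list[set]):
        self.g = g
        self.m = g.number_of_edges()
        self.comm_of = {v: i for i, mod in enumerate(modules) for v in mod}
        self.comms: dict[int, set] = {i: set(mod) for i, mod in enumerate(modules)}
        self.deg_sum = {i: sum(g.degree(v) for v in mod)
                        for i, mod in self.comms.items()}
        self.next_id = len(modules)

    def links_to(self, v) -> dict[int, int]:
        k_to: dict[int, int] = {}
        for nb in self.g.neighbors(v):
            c = self.comm_of[nb]
            k_to[c] = k_to.get(c, 0) + 1
        return k_to

    def gain(self, v, b: int, k_to: dict[int, int]) -> float:
        """Modularity change of moving v to community b (-1 = new singleton)."""
        a = self.comm_of[v]
        d_v = self.g.degree(v)
        k_va = k_to.get(a, 0)
        k_vb = 0 if b == -1 else k_to.get(b, 0)
        d_b = 0 if b == -1 else self.deg_sum[b]
        return (k_vb - k_va) / self.m \
            - d_v * (d_b - (self.deg_sum[a] - d_v)) / (2.0 * self.m * self.m)

    def move(self, v, b: int) -> None:
        if b == -1:
            b = self.next_id
            self.comms[b] = set()
            self.deg_sum[b] = 0
            self.next_id += 1
        a = self.comm_of[v]
        d_v = self.g.degree(v)
        self.comms[a].discard(v)
        self.deg_sum[a] -= d_v
        self.comms[b].add(v)
        self.deg_sum[b] += d_v
        self.comm_of[v] = b
        if not self.comms[a]:
            del self.comms[a], self.deg_sum[a]

    def partition(self) -> list[set]:
        return [set(mod) for mod in self.comms.values() if mod]

    def snapshot(self):
        return ({v: c for v, c in self.comm_of.items()},
                {i: set(s) for i, s in self.comms.items()},
                dict(self.deg_sum), self.next_id)

    def restore(self, snap) -> None:
        self.comm_of, self.comms, self.deg_sum, self.next_id = (
            dict(snap[0]), {i: set(s) for i, s in snap[1].items()},
            dict(snap[2]), snap[3])


def _refine_partition(g: nx.Graph, modules: list[set],
                      max_passes: int = 100) -> list[set]:
    """Deterministic local refinement of a partition by modularity.

    Alternates two move types until neither improves Q: (1) sweeps of
    single-node moves to a neighbouring community or a fresh singleton;
    (2) community dissolution, where every member of a community is
    reassigned to its best alternative and the dissolution is kept only if
    the combined change raises Q (this escapes the pairwise local optima
    single moves cannot).
    """
    state = _PartitionState(g, modules)
    order = sorted(g.nodes, key=str)
    for _ in range(max_passes):
        improved = False
        # phase 1: single-node moves
        for _ in range(max_passes):
            moved = False
            for v in order:
                k_to = state.links_to(v)
                a = state.comm_of[v]
                candidates = sorted(set(k_to) - {a})
                if len(state.comms[a]) > 1:
                    candidates.append(-1)
                best_gain, best_c = 1e-12, None
                for b in candidates:
                    gain = state.gain(v, b, k_to)
                    if gain > best_gain:
                        best_gain, best_c = gain, b
                if best_c is not None:
                    state.move(v, best_c)
                    moved = improved = True
            if not moved:
                break
        # phase 2: try dissolving each community wholesale
        for cid in sorted(state.comms, key=lambda c: (len(state.comms[c]), c)):
            if cid not in state.comms or len(state.comms[cid]) < 2:
                continue
            snap = state.snapshot()
            total_gain = 0.0
            members = sorted(state.comms[cid], key=str)
            for v in members:
                k_to = state.links_to(v)
                candidates = sorted(set(k_to) - {cid}) or [-1]
                gains = [(state.gain(v, b, k_to), b) for b in candidates]
                gain, b = max(gains, key=lambda x: (x[0], -x[1]))
                state.move(v, b)
                total_gain += gain
            if total_gain > 1e-12:
                improved = True
            else:
                state.restore(snap)
        if not improved:
            break
    return state.partition()


def detect_modules(net: EcologicalNetwork,
                   method: str = "greedy_modularity") -> tuple[list[set], float]:
    """Greedy modularity-maximising partition with local refinement.

    Deterministic agglomeration (Clauset-Newman-Moore) followed by a sweep
    of single-node moves that strictly increase modularity.  The partition
    is stored on the network and returned with its modularity.  Modules are
    ordered by decreasing size, ties broken by smallest member.
    """
    if method != "greedy_modularity":
        raise ValueError(f"unknown module detection method {method!r}")
    comms = nx_community.greedy_modularity_communities(net.graph)
    modules = _refine_partition(net.graph, [set(c) for c in comms])
    modules.sort(key=lambda m: (-len(m), min(str(x) for x in m)))
    q = nx_community.modularity(net.graph, modules)
    net.modules = modules
    return modules, float(q)


def topology(net: EcologicalNetwork, modules: list[set] | None = None) -> NetworkStats:
    """Whole-network summary statistics (Table-5-shaped).

    Connectivity is the mean degree 2E/N; the average path distance is the
    mean shortest-path length over connected pairs only (fragmented
    co-occurrence graphs have no finite global diameter); clustering is the
    mean local coefficient with 0 for degree < 2; modularity refers to the
    greedy partition (detected on the fly if absent).
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    if modules is None:
        if net.modules is None:
            detect_modules(net)
        modules = net.modules
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0)
    total_len = 0.0
    total_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        m = len(comp)
        if m < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(lengths.values())
        total_pairs += m * (m - 1)
    avg_path = total_len / total_pairs if total_pairs else 0.0
    return NetworkStats(
        total_nodes=n,
        total_links=e,
        positive_link_pct=100.0 * pos / e,
        avg_connectivity=2.0 * e / n,
        avg_path_distance=avg_path,
        avg_clustering_coefficient=float(nx.average_clustering(g)),
        modularity=float(nx_community.modularity(g, modules)),
    )


def node_roles(net: EcologicalNetwork, partition: list[set] | None = None,
               zi_cutoff: float = 2.5, pi_cutoff: float = 0.62) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    ``Zi = (k_within - mean_module) / sd_module`` (0 where the module sd is
    0); ``Pi = 1 - sum_m (k_m / k)^2``.  Roles: module_hub (Zi >= cutoff),
    connector (Pi >= cutoff), network_hub (both), else peripheral.
    """
    if partition is None:
        if net.modules is None:
            detect_modules(net)
        partition = net.modules
    g = net.graph
    node_module = {node: m for m, mod in enumerate(partition) for node in mod}
    if set(node_module) != set(g.nodes):
        raise ValueError("partition does not cover the network nodes")
    n_modules = len(partition)
    # within-module degree per node, and per-module distribution
    k_within = {}
    k_by_module = {}
    for node in g.nodes:
        counts = np.zeros(n_modules)
        for nb in g.neighbors(node):
            counts[node_module[nb]] += 1
        k_by_module[node] = counts
        k_within[node] = counts[node_module[node]]
    mod_stats = {}
    for m, mod in enumerate(partition):
        vals = np.array([k_within[node] for node in mod], dtype=float)
        mod_stats[m] = (vals.mean(), vals.std())
    roles = []
    for node in net.otu_ids:
        m = node_module[node]
        mu, sd = mod_stats[m]
        zi = 0.0 if sd < 1e-12 else (k_within[node] - mu) / sd
        k = g.degree(node)
        pi = 1.0 - float(((k_by_module[node] / k) ** 2).sum())
        hub = zi >= zi_cutoff
        conn = pi >= pi_cutoff
        role = ("network_hub" if hub and conn else
                "module_hub" if hub else
                "connector" if conn else "peripheral")
        roles.append(NodeRole(node, m, int(k), float(zi), float(pi), role))
    return roles


# ---------------------------------------------------------------------------
# environment linkage
# ---------------------------------------------------------------------------

def gene_significance(logmat: LogAbundanceMatrix, env: EnvTable) -> pd.DataFrame:
    """GS[i, v] = squared Pearson correlation of OTU i's abundance with env v.

    Rows are OTUs, columns environmental variables; values lie in [0, 1].
    """
    if list(logmat.sample_ids) != list(env.sample_ids):
        if set(logmat.sample_ids) <= set(env.sample_ids):
            env = env.select_samples(list(logmat.sample_ids))
        else:
            raise ValueError("sample ids of log matrix and env table differ")
    V = logmat.values
    E = env.values
    Vc = V - V.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=0, keepdims=True)
    vn = np.linalg.norm(Vc, axis=1)
    en = np.linalg.norm(Ec, axis=0)
    if np.any(vn < 1e-12) or np.any(en < 1e-12):
        raise ValueError("constant OTU or environmental variable in GS input")
    r = (Vc @ Ec) / np.outer(vn, en)
    gs = np.clip(r, -1.0, 1.0) ** 2
    return pd.DataFrame(gs, index=logmat.otu_ids, columns=env.variables)


def connectivity_gs_test(net: EcologicalNetwork, gs: pd.DataFrame, variable: str,
                         n_perm: int = 999, seed: int = 0) -> TestResult:
    """Vector-mode Mantel test of node degree against GS for one variable.

    This is the Table-6-style linkage: ``r`` is the Pearson correlation of
    the degree vector with the GS column over network nodes; the null
    permutes node labels.
    """
    if variable not in gs.columns:
        raise ValueError(f"variable {variable!r} not in GS matrix")
    nodes = [o for o in net.otu_ids if o in gs.index]
    if len(nodes) < 4:
        raise ValueError("need at least 4 network nodes with GS values")
    degree = np.array([net.graph.degree(o) for o in nodes], dtype=float)
    gs_col = gs.loc[nodes, variable].to_numpy(float)
    return mantel(degree, gs_col, n_perm=n_perm, seed=seed, method="pearson")


def connectivity_gs_table(net: EcologicalNetwork, gs: pd.DataFrame,
                          n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Per-variable connectivity-GS Mantel results (Table-6-shaped)."""
    rows = []
    for i, var in enumerate(gs.columns):
        res = connectivity_gs_test(net, gs, var, n_perm=n_perm, seed=seed + i)
        rows.append({"variable": var, "r": res.statistic, "P": res.p_value})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_edge_list(net: EcologicalNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsign\tsimilarity\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['sign']}\t{d['similarity']:.6f}\n")


def write_graphml(net: EcologicalNetwork, path) -> None:
    """GraphML export for Cytoscape import (module id attached if present)."""
    g = net.graph.copy()
    if net.modules is not None:
        for m, mod in enumerate(net.modules):
            for node in mod:
                g.nodes[node]["module"] = m
    nx.write_graphml(g, path)


def write_node_roles(roles: list[NodeRole], path) -> None:
    df = pd.DataFrame(
        [
            {"otu": r.otu_id, "module": r.module, "degree": r.degree,
             "Zi": r.zi, "Pi": r.pi, "role": r.role}
            for r in roles
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_network_stats(stats_by_name: dict[str, NetworkStats], path) -> None:
    df = pd.DataFrame({k: v.to_series() for k, v in stats_by_name.items()}).T
    df.index.name = "Network"
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_threshold_scan(scan: ThresholdScanResult, path) -> None:
    scan.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")
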