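"""Synthetic community, environment and FASTQ generators.

Every generator is a pure function of its spec + seed.  The defaults emulate
the study design the analyses downstream assume: a two-treatment comparison
(reseeding grassland "RG" vs natural grassland "NG"), 9 sites x 3 subplots
per treatment (54 samples), every sample at a fixed sequencing depth of 1500
reads, and a phylum profile in which four dominant phyla (Proteobacteria,
Acidobacteria, Actinobacteria, Bacteroidetes) jointly account for ~80% of
the community.

Counts are drawn Dirichlet-multinomial per sample around group-level mean
compositions: the Dirichlet concentration (``dispersion``) controls
overdispersion while the multinomial draw keeps per-sample depth exact.
``group_effect`` scales all between-group differences (phylum-profile
contrasts and OTU-level log-normal perturbations), so ``group_effect = 0``
makes the groups exchangeable — the null configuration used to check that
every downstream permutation test is calibrated.

Correlated OTU blocks (fixtures for the co-occurrence network stage) are
multivariate normal in log10-abundance space and exponentiated to counts, so
the planted correlations survive the downstream "lg matrix" transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from menanet.otu_io import EnvTable, OtuTable

__all__ = [
    "CommunitySpec",
    "BlockSpec",
    "EnvLinkSpec",
    "simulate_community",
    "simulate_correlated_blocks",
    "simulate_env_linked",
    "simulate_fastq",
    "rg_like_block_spec",
    "ng_like_block_spec",
    "DEFAULT_PHYLUM_PROFILE",
    "DEFAULT_ENV_PROFILE",
]

# Per-group expected phylum relative abundances (group 0 = RG-like,
# group 1 = NG-like).  The four dominant phyla sum to 0.81 / 0.79.
DEFAULT_PHYLUM_PROFILE: dict[str, tuple[float, float]] = {
    "Proteobacteria": (0.33, 0.28),
    "Acidobacteria": (0.23, 0.20),
    "Actinobacteria": (0.12, 0.20),
    "Bacteroidetes": (0.13, 0.11),
    "Chloroflexi": (0.05, 0.06),
    "Firmicutes": (0.04, 0.05),
    "Verrucomicrobia": (0.03, 0.03),
    "Planctomycetes": (0.03, 0.03),
    "Gemmatimonadetes": (0.02, 0.02),
    "Nitrospirae": (0.01, 0.01),
    "Crenarchaeota": (0.01, 0.01),
}

DOMINANT_PHYLA = ("Proteobacteria", "Acidobacteria", "Actinobacteria", "Bacteroidetes")

# variable -> (group-0 mean, group-1 mean, sd); soil chemistry scales typical
# of temperate meadow topsoil.
DEFAULT_ENV_PROFILE: dict[str, tuple[float, float, float]] = {
    "pH": (6.34, 7.26, 0.32),
    "SM": (37.62, 25.67, 8.7),
    "SOC": (68.24, 59.86, 11.0),
    "TN": (5.66, 5.38, 1.2),
    "TP": (605.86, 664.75, 37.7),
    "AN": (486.64, 407.35, 41.9),
    "AP": (18.22, 43.67, 12.0),
    "NH4N": (12.15, 6.88, 3.0),
    "NO3N": (43.56, 54.69, 7.9),
    "Richness": (9.3, 12.5, 1.0),
}


def _normalize_profile(profile, n_groups: int) -> tuple[list[str], np.ndarray]:
    """Return (phyla, matrix groups x phyla of expected relative abundance)."""
    phyla = list(profile)
    mat = np.empty((n_groups, len(phyla)))
    for j, ph in enumerate(phyla):
        v = profile[ph]
        if np.isscalar(v):
            mat[:, j] = float(v)
        else:
            v = np.asarray(v, dtype=float)
            if v.size == 1:
                mat[:, j] = v[0]
            elif v.size == n_groups:
                mat[:, j] = v
            else:
                raise ValueError(
                    f"phylum {ph!r}: expected 1 or {n_groups} abundances, got {v.size}"
                )
    sums = mat.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError(f"phylum profile must sum to 1 per group, got {sums}")
    return phyla, mat


@dataclass
class CommunitySpec:
    """Design of a synthetic two-treatment community experiment."""

    n_otus: int = 300
    n_groups: int = 2
    sites_per_group: int = 9
    subplots_per_site: int = 3
    depth: int = 1500
    phylum_profile: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_PROFILE))
    group_effect: float = 1.0
    otu_effect_sd: float = 0.3
    dispersion: float = 200.0
    block_spec: "BlockSpec | None" = None
    block_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.sites_per_group < 1 or self.subplots_per_site < 1:
            raise ValueError("design dimensions must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.group_effect < 0:
            raise ValueError("group_effect must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        _normalize_profile(self.phylum_profile, self.n_groups)

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.sites_per_group * self.subplots_per_site

    def group_names(self) -> list[str]:
        if self.n_groups == 2:
            return ["RG", "NG"]
        return [f"G{i + 1}" for i in range(self.n_groups)]


@dataclass
class BlockSpec:
    """Planted correlated OTU blocks for the network stage.

    ``blocks`` is a list of ``(size, rho)``; with ``decay`` unset the
    within-block correlation is compound-symmetric at rho, with ``decay`` set
    it is the AR(1) band ``rho^|i-j|``.
    """

    blocks: list[tuple[int, float]]
    n_noise_otus: int = 0
    n_samples: int = 100
    decay: bool = False
    log_mean: float = 2.0
    log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for size, rho in self.blocks:
            if size < 2:
                raise ValueError("block sizes must be >= 2")
            if not 0 < rho <= 1:
                raise ValueError("block rho must be in (0, 1]")
        if self.n_noise_otus < 0 or self.n_samples < 3:
            raise ValueError("need n_noise_otus >= 0 and n_samples >= 3")

    @property
    def n_otus(self) -> int:
        return sum(size for size, _ in self.blocks) + self.n_noise_otus


@dataclass
class EnvLinkSpec:
    """Planted OTU-environment correlations.

    ``driver_map``: variable -> (driver OTU indices, target |r|), where the
    target may be a scalar shared by all drivers of that variable or one
    value per driver.  The targets must satisfy sum r_i^2 < 1.
    """

    driver_map: dict[str, tuple[list[int], object]]
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for var, (idx, r) in self.driver_map.items():
            if len(set(idx)) != len(idx):
                raise ValueError(f"variable {var!r}: duplicate driver OTU indices")
            rs = np.atleast_1d(np.asarray(r, dtype=float))
            if rs.size not in (1, len(idx)):
                raise ValueError(f"variable {var!r}: one target |r| per driver")
            if np.any((rs <= 0) | (rs >= 1)):
                raise ValueError(f"variable {var!r}: target |r| must be in (0, 1)")
            total = float((rs ** 2).sum()) if rs.size == len(idx) \
                else float(len(idx) * rs[0] ** 2)
            if total >= 1:
                raise ValueError(f"variable {var!r}: sum of squared targets must be < 1")


def _block_correlation(spec: BlockSpec) -> np.ndarray:
    n = spec.n_otus
    corr = np.eye(n)
    start = 0
    for size, rho in spec.blocks:
        idx = np.arange(start, start + size)
        if spec.decay:
            sub = rho ** np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
        else:
            sub = np.full((size, size), rho)
            np.fill_diagonal(sub, 1.0)
        corr[np.ix_(idx, idx)] = sub
        start += size
    return corr


def _mvn_from_correlation(corr: np.ndarray, n_samples: int,
                          rng: np.random.Generator) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n_samples, len(corr)))
    return z @ chol.T


def simulate_community(spec: CommunitySpec) -> tuple[OtuTable, list[str]]:
    """Draw a Dirichlet-multinomial community for the configured design.

    Returns the OTU table (with taxonomy down to phylum) and the per-sample
    group labels.  Sample ids encode the group/site/subplot structure
    ("RG.S3.P2"); no random site effect is added, so the default null
    (``group_effect = 0``) is exchangeable.
    """
    rng = np.random.default_rng(spec.seed)
    phyla, prof = _normalize_profile(spec.phylum_profile, spec.n_groups)
    mean_prof = prof.mean(axis=0)
    # interpolate group profiles toward/away from the pooled mean
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(mean_prof > 0, np.log(prof / mean_prof), 0.0)
    eff_prof = mean_prof * np.exp(spec.group_effect * log_ratio)
    eff_prof = eff_prof / eff_prof.sum(axis=1, keepdims=True)

    # assign OTUs to phyla proportionally to the pooled mean profile
    n_per = np.maximum(1, np.round(mean_prof * spec.n_otus).astype(int))
    while n_per.sum() > spec.n_otus:
        n_per[np.argmax(n_per)] -= 1
    while n_per.sum() < spec.n_otus:
        n_per[np.argmax(mean_prof)] += 1
    otu_phylum = np.repeat(np.arange(len(phyla)), n_per)
    n_otus = otu_phylum.size

    # within-phylum species-abundance weights (log-normal, shared by groups)
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_otus)
    # OTU-level group contrast, scaled by group_effect
    eta = rng.normal(0.0, spec.otu_effect_sd, size=(spec.n_groups, n_otus))
    group_probs = np.empty((spec.n_groups, n_otus))
    for g in range(spec.n_groups):
        w = weights * np.exp(spec.group_effect * eta[g])
        for ph in range(len(phyla)):
            mask = otu_phylum == ph
            group_probs[g, mask] = eff_prof[g, ph] * w[mask] / w[mask].sum()
    group_probs /= group_probs.sum(axis=1, keepdims=True)

    block_corr = None
    if spec.block_spec is not None:
        if spec.block_spec.n_otus > n_otus:
            raise ValueError("block_spec has more OTUs than the community")
        block_corr = _block_correlation(spec.block_spec)

    names = spec.group_names()
    sample_ids, labels = [], []
    counts = np.empty((spec.n_samples, n_otus), dtype=np.int64)
    i = 0
    for g in range(spec.n_groups):
        for s in range(spec.sites_per_group):
            for p in range(spec.subplots_per_site):
                sample_ids.append(f"{names[g]}.S{s + 1}.P{p + 1}")
                labels.append(names[g])
                alpha = spec.dispersion * group_probs[g]
                comp = rng.dirichlet(alpha)
                if block_corr is not None:
                    nb = block_corr.shape[0]
                    z = _mvn_from_correlation(block_corr, 1, rng)[0]
                    comp = comp.copy()
                    comp[:nb] *= np.exp(spec.block_sigma * z)
                    comp /= comp.sum()
                counts[i] = rng.multinomial(spec.depth, comp)
                i += 1

    otu_ids = [f"OTU{j + 1:04d}" for j in range(n_otus)]
    taxonomy = {
        otu_ids[j]: f"d__Bacteria;p__{phyla[otu_phylum[j]]}" for j in range(n_otus)
    }
    table = OtuTable(sample_ids, otu_ids, counts, taxonomy)
    return table, labels


def simulate_correlated_blocks(spec: BlockSpec) -> OtuTable:
    """Counts whose log10 abundances carry planted block correlations.

    OTU ids encode membership: ``B<k>_OTU<j>`` for block ``k`` (1-based) and
    ``N_OTU<j>`` for independent noise OTUs.
    """
    rng = np.random.default_rng(spec.seed)
    corr = _block_correlation(spec)
    z = _mvn_from_correlation(corr, spec.n_samples, rng)
    log_abund = spec.log_mean + spec.log_sd * z
    counts = np.maximum(1, np.round(10.0 ** log_abund)).astype(np.int64)
    otu_ids = []
    for k, (size, _) in enumerate(spec.blocks):
        otu_ids += [f"B{k + 1}_OTU{j + 1}" for j in range(size)]
    otu_ids += [f"N_OTU{j + 1}" for j in range(spec.n_noise_otus)]
    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    return OtuTable(sample_ids, otu_ids, counts)


def block_membership(table: OtuTable) -> dict[str, int]:
    """Planted block label per OTU id from a simulate_correlated_blocks table.

    Noise OTUs map to -1.
    """
    out = {}
    for o in table.otu_ids:
        out[o] = -1 if o.startswith("N_") else int(o.split("_")[0][1:])
    return out


def simulate_env_linked(table_spec: CommunitySpec,
                        link: EnvLinkSpec) -> tuple[OtuTable, EnvTable]:
    """Community plus an environment table with planted OTU-env correlations.

    Driver variables are built as ``sum_i a_i z_i + noise`` over the
    standardised log10 abundances ``z_i`` of their driver OTUs, with
    coefficients chosen so the population correlation with each driver hits
    its target |r| (assuming near-independent drivers); they are then
    rescaled to the realistic mean/SD of the named variable.  Variables
    without drivers are group-mean + Gaussian noise per DEFAULT_ENV_PROFILE.
    """
    table, labels = simulate_community(table_spec)
    rng = np.random.default_rng(link.seed)
    n = table.n_samples
    logged = np.log10(np.where(table.counts > 0, table.counts, 0.01))
    variables = list(DEFAULT_ENV_PROFILE)
    for var in link.driver_map:
        if var not in variables:
            variables.append(var)
    values = np.empty((n, len(variables)))
    names = table_spec.group_names()
    gidx = np.array([names.index(g) for g in labels])
    for j, var in enumerate(variables):
        mu0, mu1, sd = DEFAULT_ENV_PROFILE.get(var, (0.0, 0.0, 1.0))
        means = np.array([mu0, mu1] + [mu0] * max(0, table_spec.n_groups - 2))
        if var in link.driver_map:
            idx, r = link.driver_map[var]
            idx = np.asarray(idx, dtype=int)
            if np.any((idx < 0) | (idx >= table.n_otus)):
                raise ValueError(f"variable {var!r}: driver index out of range")
            rs = np.atleast_1d(np.asarray(r, dtype=float))
            if rs.size == 1:
                rs = np.repeat(rs, idx.size)
            z = logged[:, idx]
            z = (z - z.mean(axis=0)) / z.std(axis=0)
            # residual sd calibrated so that at noise_sd = 1 the population
            # correlation with each (near-independent) driver equals its
            # target; noise_sd -> 0 makes the linkage deterministic (GS -> 1)
            resid_sd = link.noise_sd * np.sqrt(1.0 - (rs ** 2).sum())
            raw = z @ rs + resid_sd * rng.standard_normal(n)
            raw = (raw - raw.mean()) / raw.std()
            values[:, j] = mu0 + sd * raw  # no group offset: drivers carry the signal
        else:
            values[:, j] = means[gidx] + sd * rng.standard_normal(n)
    env = EnvTable(list(table.sample_ids), variables, values)
    return table, env


_PHRED_MAX = 41


def simulate_fastq(n_reads: int, read_length: int, gc_fraction: float,
                   q_profile, seed: int, path) -> None:
    """Write a synthetic Phred+33 FASTQ file.

    ``q_profile`` is a probability vector over Phred scores 0..41 (or a dict
    score -> probability); bases are iid with P(G)+P(C) = ``gc_fraction``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    if isinstance(q_profile, dict):
        probs = np.zeros(_PHRED_MAX + 1)
        for k, v in q_profile.items():
            if not 0 <= int(k) <= _PHRED_MAX:
                raise ValueError(f"Phred score {k} outside 0..{_PHRED_MAX}")
            probs[int(k)] = v
    else:
        probs = np.asarray(q_profile, dtype=float)
        if probs.size != _PHRED_MAX + 1:
            raise ValueError(f"q_profile must have {_PHRED_MAX + 1} entries")
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("q_profile must be a probability vector")
    rng = np.random.default_rng(seed)
    base_p = np.array([(1 - gc_fraction) / 2, (1 - gc_fraction) / 2,
                       gc_fraction / 2, gc_fraction / 2])
    bases = np.array(list("ATGC"))
    with open(path, "w") as fh:
        for i in range(n_reads):
            seq = "".join(bases[rng.choice(4, size=read_length, p=base_p)])
            quals = rng.choice(_PHRED_MAX + 1, size=read_length, p=probs)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@read{i + 1}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# network-contrast presets
# ---------------------------------------------------------------------------

def rg_like_block_spec(seed: int = 0, n_samples: int = 80) -> BlockSpec:
    """Denser, slowly-decaying correlation bands: an RG-like network preset."""
    return BlockSpec(blocks=[(25, 0.985)] * 3, n_noise_otus=30,
                     n_samples=n_samples, decay=True, seed=seed)


def ng_like_block_spec(seed: int = 0, n_samples: int = 80) -> BlockSpec:
    """Sparser, fast-decaying correlation bands: an NG-like network preset."""
    return BlockSpec(blocks=[(25, 0.90)] * 3, n_noise_otus=30,
                     n_samples=n_samples, decay=True, seed=seed)
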