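"""OTU-table and sample-metadata data model, I/O, rarefaction and transforms.

The central object is :class:`OtuTable`: an integer count matrix of shape
(samples x OTUs) with ordered unique sample and OTU identifiers and optional
taxonomy lineage strings per OTU.  On disk the dominant convention is the
transpose (OTU rows x sample columns, first column the OTU id, optional last
column ``taxonomy``); readers normalise to samples x OTUs in memory.

Rarefaction draws, for each sample, a without-replacement subsample of reads
down to a common depth (multivariate hypergeometric), removing library-size
effects before diversity or dissimilarity analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "EnvTable",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_env_table",
    "write_env_table",
    "read_groups",
    "write_groups",
    "rarefy",
    "relative_abundance",
    "aggregate_by_taxonomy",
    "TAXONOMIC_RANKS",
]

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


class OtuTableError(ValueError):
    """Raised for malformed OTU/metadata files or invalid table operations."""


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise OtuTableError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with optional per-OTU taxonomy.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample labels (rows of ``counts``).
    otu_ids : list of str
        Ordered, unique OTU labels (columns of ``counts``).
    counts : ndarray of int, shape (n_samples, n_otus)
        Non-negative read counts.
    taxonomy : dict, optional
        Map ``otu_id -> lineage string`` (ranks joined by ``;``, optional
        Greengenes/SILVA-style prefixes like ``p__``).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.otu_ids)} OTUs)"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise OtuTableError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if self.counts.size and self.counts.min() < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise OtuTableError(
                f"negative count at sample {self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise OtuTableError(f"taxonomy for unknown OTUs: {sorted(unknown)[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x OTUs counts as a DataFrame."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(self, sample_ids=list(sample_ids), counts=self.counts[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )


@dataclass
class EnvTable:
    """Samples x environmental-variables real matrix (pH, SM, SOC, ...)."""

    sample_ids: list[str]
    variables: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variables = [str(v) for v in self.variables]
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(self.sample_ids), len(self.variables)):
            raise OtuTableError(
                f"values shape {values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.variables)} variables)"
            )
        if not np.all(np.isfinite(values)):
            raise OtuTableError("environmental values must be finite")
        self.values = values
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.variables, "variable")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variables)

    def select_samples(self, sample_ids: list[str]) -> "EnvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return EnvTable(list(sample_ids), list(self.variables), self.values[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variables == other.variables
            and np.allclose(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv", orientation: str = "otus_as_rows") -> OtuTable:
    """Read an OTU table from ``tsv`` or BIOM 1.0 JSON (``biom-json``).

    TSV dialect: first column OTU ids, header row sample ids, optional final
    ``taxonomy`` column.  ``orientation`` may be ``"otus_as_rows"`` (default,
    the dominant on-disk convention) or ``"samples_as_rows"``.
    """
    if format == "tsv":
        return _read_tsv(path, orientation)
    if format == "biom-json":
        return _read_biom_json(path)
    raise OtuTableError(f"unknown format {format!r}")


def _read_tsv(path, orientation: str) -> OtuTable:
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise OtuTableError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):  # pandas silently mangles duplicates
        dup = sorted({h for h in header if header.count(h) > 1})
        raise OtuTableError(f"duplicate column id(s) in header: {dup}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False, comment=None)
    df.index = df.index.astype(str)
    taxonomy = None
    if len(df.columns) and str(df.columns[-1]).lower() == "taxonomy":
        if orientation != "otus_as_rows":
            raise OtuTableError("a taxonomy column requires otus_as_rows orientation")
        taxonomy = {str(o): t for o, t in df.iloc[:, -1].items() if t != ""}
        df = df.iloc[:, :-1]
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df.iloc[:, j]):
                try:
                    float(v)
                except ValueError:
                    raise OtuTableError(
                        f"non-numeric count {v!r} at row {df.index[i]!r}, column {col!r}"
                    ) from exc
        raise
    if np.any(mat < 0):
        i, j = np.argwhere(mat < 0)[0]
        raise OtuTableError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "otus_as_rows":
        return OtuTable(col_ids, row_ids, mat.T, taxonomy)
    return OtuTable(row_ids, col_ids, mat, taxonomy)


def _read_biom_json(path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        rows = doc["rows"]
        cols = doc["columns"]
        shape = doc["shape"]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise OtuTableError(f"BIOM JSON missing field {exc}") from exc
    n_obs, n_samp = int(shape[0]), int(shape[1])
    mat = np.zeros((n_obs, n_samp))
    if mtype == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    elif mtype == "dense":
        mat = np.asarray(data, dtype=float)
    else:
        raise OtuTableError(f"unsupported BIOM matrix_type {mtype!r}")
    otu_ids = [str(r["id"]) for r in rows]
    sample_ids = [str(c["id"]) for c in cols]
    taxonomy = {}
    for r in rows:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax is not None:
            if isinstance(tax, (list, tuple)):
                tax = ";".join(str(t) for t in tax)
            taxonomy[str(r["id"])] = str(tax)
    return OtuTable(sample_ids, otu_ids, mat.T, taxonomy or None)


def write_otu_table(table: OtuTable, path, format: str = "tsv",
                    orientation: str = "otus_as_rows") -> None:
    """Write a table so that :func:`read_otu_table` recovers an equal table."""
    if format != "tsv":
        raise OtuTableError(f"unsupported write format {format!r}")
    if orientation != "otus_as_rows":
        raise OtuTableError("writing uses the otus_as_rows convention")
    df = pd.DataFrame(table.counts.T, index=pd.Index(table.otu_ids, name="#OTU_ID"),
                      columns=table.sample_ids)
    if table.taxonomy is not None:
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.to_csv(path, sep="\t")


def read_env_table(path) -> EnvTable:
    """Read a samples x variables TSV with a header row."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    values = df.to_numpy(dtype=float)
    return EnvTable([str(s) for s in df.index], [str(v) for v in df.columns], values)


def write_env_table(env: EnvTable, path) -> None:
    df = env.to_dataframe()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


def read_groups(path) -> dict[str, str]:
    """Read a two-column ``sample_id TAB group`` file (no header)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OtuTableError(f"groups file line {ln}: expected 2 columns")
            if parts[0] in groups:
                raise OtuTableError(f"groups file line {ln}: duplicate sample {parts[0]!r}")
            groups[parts[0]] = parts[1]
    return groups


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total count is below ``depth`` are dropped with a warning
    (padding would break the exact-depth postcondition).  The draw per sample
    is multivariate hypergeometric, so expected per-OTU counts are
    ``depth * c_j / total``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not np.all(keep):
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped[:5]}",
            UserWarning,
            stacklevel=2,
        )
    if not np.any(keep):
        raise OtuTableError(f"no sample has total count >= {depth}")
    out = np.empty((int(keep.sum()), table.n_otus), dtype=np.int64)
    r = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth, method="marginals")
        r += 1
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(sample_ids, list(table.otu_ids), out, table.taxonomy)


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample proportions (rows sum to 1). Errors on a zero-total sample."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise OtuTableError(f"sample {bad!r} has zero total count")
    return table.counts / totals[:, None]


def parse_lineage(lineage: str) -> list[str]:
    """Split a ``;``-separated lineage, stripping rank prefixes (``p__`` etc.)."""
    parts = []
    for tok in lineage.split(";"):
        tok = tok.strip()
        for pref in _RANK_PREFIXES:
            if tok.lower().startswith(pref):
                tok = tok[len(pref):]
                break
        parts.append(tok)
    return parts


def aggregate_by_taxonomy(table: OtuTable, rank: str = "phylum") -> OtuTable:
    """Pool OTU counts by taxon at ``rank``; missing ranks go to 'unclassified'.

    Sample totals are conserved exactly.
    """
    if rank not in TAXONOMIC_RANKS:
        raise OtuTableError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
    if table.taxonomy is None:
        raise OtuTableError("table has no taxonomy")
    level = TAXONOMIC_RANKS.index(rank)
    taxa: list[str] = []
    index: dict[str, int] = {}
    assign = np.empty(table.n_otus, dtype=np.int64)
    for j, otu in enumerate(table.otu_ids):
        lineage = table.taxonomy.get(otu, "")
        parts = parse_lineage(lineage) if lineage else []
        name = parts[level] if level < len(parts) and parts[level] else "unclassified"
        if name not in index:
            index[name] = len(taxa)
            taxa.append(name)
        assign[j] = index[name]
    pooled = np.zeros((table.n_samples, len(taxa)), dtype=np.int64)
    np.add.at(pooled.T, assign, table.counts.T)
    return OtuTable(list(table.sample_ids), taxa, pooled)
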