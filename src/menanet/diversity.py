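"""Alpha diversity (richness, Shannon-Wiener, Simpson) and two-group tests.

Shannon-Wiener is ``H = -sum p_i ln p_i`` in nats, with ``p_i`` the relative
abundance (or relative cover, for plants) of taxon ``i``.  Simpson is
reported in the Gini-Simpson form ``1 - sum p_i^2`` by default, so that
larger values mean higher diversity; the inverse form ``1 / sum p_i^2`` is
available via ``kind="inverse"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from menanet.otu_io import OtuTable
from menanet.result import TestResult

__all__ = ["shannon", "simpson", "richness", "diversity_table", "compare_groups"]


def _proportions(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("abundances must be a 1-D vector")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundance vector has no positive entries")
    return a / total


def shannon(abundances) -> float:
    """Shannon-Wiener index H = -sum p ln p (nats); zeros contribute 0."""
    p = _proportions(abundances)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(abundances, kind: str = "gini") -> float:
    """Simpson diversity: Gini-Simpson ``1 - sum p^2`` (default) or inverse."""
    p = _proportions(abundances)
    d = float((p * p).sum())
    if kind == "gini":
        return 1.0 - d
    if kind == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson kind {kind!r}")


def richness(abundances) -> int:
    """Number of taxa with strictly positive abundance."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    return int(np.count_nonzero(a > 0))


def diversity_table(table: OtuTable, simpson_kind: str = "gini") -> pd.DataFrame:
    """Per-sample richness/shannon/simpson as a DataFrame indexed by sample."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        rows.append(
            {
                "sample_id": sid,
                "richness": richness(row),
                "shannon": shannon(row),
                "simpson": simpson(row, kind=simpson_kind),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_groups(values, labels, method: str = "welch_t") -> TestResult:
    """Two-sided two-group comparison of per-sample values.

    ``method``: ``welch_t`` (default; unequal variances), ``student_t``, or
    ``mann_whitney``.  Each group needs at least 2 samples.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if method == "welch_t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        name = "t"
    elif method == "student_t":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        name = "t"
    elif method == "mann_whitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "U"
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(p):  # both groups constant and equal: no evidence of difference
        stat, p = 0.0, 1.0
    return TestResult(statistic_name=name, statistic=float(stat), p_value=float(p))
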