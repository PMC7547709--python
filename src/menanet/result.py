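"""Shared result container for statistical tests."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TestResult:
    """Outcome of a (possibly permutation-based) statistical test.

    Permutation p-values use the add-one estimator
    ``p = (1 + #{permuted at-least-as-extreme}) / (1 + n_permutations)``,
    one-sided in the direction that indicates structure for the given
    statistic (large R / pseudo-F / r; small delta for MRPP).  For
    deterministic tests (Welch t, Mann-Whitney) ``n_permutations`` is 0 and
    ``seed`` is None.
    """

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
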