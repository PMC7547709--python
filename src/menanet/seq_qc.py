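"""Sequencing-evaluation metrics from FASTQ input.

GC (%) is the percentage of G and C bases among all bases (ambiguity codes
such as N count toward the total but not toward GC); Q20 (%) / Q30 (%) are
the percentages of bases with Phred quality >= 20 / >= 30; Effective (%) is
100 x effective tags / PE reads, computed from supplied tag counts (the
merging/filtering that produces those counts is upstream of this package).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["QcStats", "FastqParseError", "fastq_stats", "effective_rate"]


class FastqParseError(ValueError):
    """Malformed FASTQ input; the message names the failing record index."""


@dataclass
class QcStats:
    n_reads: int
    avg_len: float
    gc_pct: float
    q20_pct: float
    q30_pct: float
    effective_pct: float | None = None

    def __post_init__(self) -> None:
        for name in ("gc_pct", "q20_pct", "q30_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.q30_pct > self.q20_pct + 1e-9:
            raise ValueError("q30_pct cannot exceed q20_pct")


def fastq_stats(path) -> QcStats:
    """Read counts, mean length, GC%, Q20% and Q30% of a Phred+33 FASTQ file."""
    n_reads = 0
    n_bases = 0
    n_gc = 0
    n_q20 = 0
    n_q30 = 0
    handle = open(path) if isinstance(path, (str, bytes, os.PathLike)) else path
    close = handle is not path
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                _, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(f"record {n_reads + 1}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {n_reads + 1}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            n_reads += 1
            n_bases += len(seq)
            n_gc += sum(1 for b in seq if b in "GCgc")
            for ch in qual:
                q = ord(ch) - 33
                if q >= 20:
                    n_q20 += 1
                    if q >= 30:
                        n_q30 += 1
    finally:
        if close:
            handle.close()
    if n_reads == 0 or n_bases == 0:
        raise FastqParseError("FASTQ input contains no bases")
    return QcStats(
        n_reads=n_reads,
        avg_len=n_bases / n_reads,
        gc_pct=100.0 * n_gc / n_bases,
        q20_pct=100.0 * n_q20 / n_bases,
        q30_pct=100.0 * n_q30 / n_bases,
    )


def effective_rate(effective_tags: int, pe_reads: int) -> float:
    """Effective (%) = 100 x effective_tags / pe_reads."""
    if pe_reads <= 0:
        raise ValueError("pe_reads must be positive")
    if not 0 <= effective_tags <= pe_reads:
        raise ValueError("need 0 <= effective_tags <= pe_reads")
    return 100.0 * effective_tags / pe_reads
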