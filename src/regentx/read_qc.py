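"""Windowed quality filtering of raw reads.

A read is kept when at least ``m`` positions have a smoothed quality strictly
above ``q``, where the smoothed quality at position i is the mean Phred score
over the moving window [i-w, i+w] (length 2w+1, truncated at the read ends).
Defaults q=10, m=20, w=2 reproduce a window of length 5. Comparisons against
the threshold are carried out on integer window sums, so the vectorized path
is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .io import read_fastq, write_fastq
from .models import QualityRead

PAIR_POLICIES = ("orphan", "drop-pair", "keep-pair-if-either")


@dataclass
class FilterParams:
    q: int = 10  # Phred threshold; positions must exceed it strictly
    m: int = 20  # minimum number of passing positions
    w: int = 2   # window half-width (window length 2w+1)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.q < 0:
            raise ValueError("q must be >= 0")


@dataclass
class FilterStats:
    reads_in: int = 0
    reads_kept: int = 0
    pairs_in: int = 0
    pairs_intact: int = 0
    orphans: int = 0

    @property
    def fraction_kept(self) -> float:
        return self.reads_kept / self.reads_in if self.reads_in else 0.0


def smoothed_quality(quals: np.ndarray, w: int = 2) -> np.ndarray:
    """Mean quality over the truncated moving window [i-w, i+w] at each
    position; same length as the input."""
    quals = np.asarray(quals, dtype=np.float64)
    if quals.size == 0:
        raise ValueError("empty quality vector")
    if w == 0:
        return quals.copy()
    sums, widths = _window_sums(quals.astype(np.int64), w)
    return sums / widths


def _window_sums(quals: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer window sums and window widths with truncated edges."""
    n = quals.size
    cs = np.concatenate(([0], np.cumsum(quals)))
    idx = np.arange(n)
    lo = np.maximum(idx - w, 0)
    hi = np.minimum(idx + w + 1, n)
    return cs[hi] - cs[lo], hi - lo


def passes_filter(read: QualityRead, p: FilterParams) -> bool:
    """Keep a read iff >= m positions have smoothed quality strictly > q.

    mean > q  <=>  window_sum > q * window_width, evaluated in integers.
    """
    quals = np.asarray(read.quals, dtype=np.int64)
    if quals.size == 0:
        return False
    sums, widths = _window_sums(quals, p.w)
    n_pass = int(np.count_nonzero(sums > p.q * widths))
    return n_pass >= p.m


def filter_reads(reads: Iterable[QualityRead], p: FilterParams) -> Iterator[QualityRead]:
    for r in reads:
        if passes_filter(r, p):
            yield r


def filter_fastq(
    in1,
    in2,
    outdir,
    p: FilterParams | None = None,
    pair_policy: str = "orphan",
    phred_offset: int = 33,
) -> FilterStats:
    """Filter a FASTQ pair, writing kept mates and (under the default
    ``orphan`` policy) surviving singletons to ``outdir``.

    Policies: ``orphan`` drops only the failing mate and writes the survivor
    to an orphans file; ``drop-pair`` requires both mates to pass;
    ``keep-pair-if-either`` keeps both mates when either passes. Input order
    is preserved and reads are never rewritten.
    """
    if p is None:
        p = FilterParams()
    if pair_policy not in PAIR_POLICIES:
        raise ValueError(f"pair_policy must be one of {PAIR_POLICIES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stats = FilterStats()
    kept1: list[QualityRead] = []
    kept2: list[QualityRead] = []
    orphans: list[QualityRead] = []
    for r1, r2 in zip(
        read_fastq(in1, mate=1, phred_offset=phred_offset),
        read_fastq(in2, mate=2, phred_offset=phred_offset),
        strict=True,
    ):
        if r1.id != r2.id:
            raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
        stats.pairs_in += 1
        stats.reads_in += 2
        p1, p2 = passes_filter(r1, p), passes_filter(r2, p)
        if pair_policy == "drop-pair":
            p1 = p2 = p1 and p2
        elif pair_policy == "keep-pair-if-either":
            p1 = p2 = p1 or p2
        if p1 and p2:
            kept1.append(r1)
            kept2.append(r2)
            stats.pairs_intact += 1
            stats.reads_kept += 2
        elif p1:
            orphans.append(r1)
            stats.orphans += 1
            stats.reads_kept += 1
        elif p2:
            orphans.append(r2)
            stats.orphans += 1
            stats.reads_kept += 1
    write_fastq(kept1, outdir / "kept_1.fq")
    write_fastq(kept2, outdir / "kept_2.fq")
    if pair_policy == "orphan":
        write_fastq(orphans, outdir / "orphans.fq")
    return stats
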