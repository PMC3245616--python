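"""Assembly quality metrics for de novo transcriptomes.

Covers the classic desk checks run on a fresh assembly: length statistics
and N50, ortholog hit ratios against a reference proteome, reciprocal-best-
hit coverage of known cDNAs, and the fraction of transcripts that align to a
single genomic scaffold over most of their length (low values flag a
fragmented genome rather than a poor assembly).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .models import AlignmentRecord, TranscriptSet


def longest_isoform_set(ts: TranscriptSet) -> TranscriptSet:
    """One transcript per gene: the longest isoform, ties broken
    lexicographically by transcript id."""
    return ts.longest_isoforms()


def n50(lengths: Sequence[int]) -> int:
    """The largest length L in the multiset such that sequences of length
    >= L together contain at least half of all bases. Always an element of
    the input."""
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length set")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    srt = np.sort(lengths)[::-1]
    half = srt.sum() / 2.0
    cum = np.cumsum(srt)
    return int(srt[np.searchsorted(cum, half)])


def length_summary(lengths: Sequence[int]) -> dict[str, float]:
    """Mean/median/max/min/count; the median of an even-sized set is the
    lower-median element (a set member, like N50)."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length set")
    srt = np.sort(arr)
    lower_median = int(srt[(arr.size - 1) // 2])
    return {
        "mean": float(arr.mean()),
        "median": lower_median,
        "max": int(arr.max()),
        "min": int(arr.min()),
        "count": int(arr.size),
    }


def ortholog_hit_ratio(
    best_hit: Optional[AlignmentRecord], ortholog_protein_length: int
) -> float:
    """Aligned query coding length over the best-hit ortholog's length:
    (aligned query nucleotides / 3) / ortholog aa length. A ratio near 1
    marks a near full-length transcript; the ratio is not capped at 1."""
    if ortholog_protein_length <= 0:
        raise ValueError("ortholog protein length must be positive")
    if best_hit is None:
        return 0.0
    aligned_nt = best_hit.query_end - best_hit.query_start
    return (aligned_nt / 3.0) / ortholog_protein_length


def ortholog_hit_ratios(
    hits: Iterable[AlignmentRecord],
    protein_lengths: Mapping[str, int],
    evalue_cutoff: float = 1e-3,
) -> dict[str, float]:
    """Per-query ratios from the best hit (highest score) passing the e-value
    cutoff. Queries without a passing hit are absent, not zero-filled."""
    best: dict[str, AlignmentRecord] = {}
    for h in hits:
        if h.evalue is not None and h.evalue > evalue_cutoff:
            continue
        cur = best.get(h.query_id)
        if cur is None or h.score > cur.score:
            best[h.query_id] = h
    return {
        q: ortholog_hit_ratio(h, protein_lengths[h.target_id])
        for q, h in best.items()
        if h.target_id in protein_lengths
    }


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _union_length(blocks: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_blocks(blocks))


def reciprocal_best_hits(
    hits_ab: Iterable[AlignmentRecord],
    hits_ba: Iterable[AlignmentRecord],
    score_cutoff: float = 50.0,
    reference_lengths: Optional[Mapping[str, int]] = None,
) -> list[dict]:
    """Reciprocal best hits between set A (e.g. an assembly) and set B (e.g.
    reference cDNAs), both directions scored; a pair (a, b) is reported iff b
    is a's unique top hit with score >= cutoff and vice versa.

    When ``reference_lengths`` gives the B-side (cDNA) lengths, each pair
    carries the fraction of the cDNA covered by the union of that pair's
    aligned blocks on the cDNA (overlaps merged).
    """
    hits_ab = list(hits_ab)
    hits_ba = list(hits_ba)
    best_ab = _best_targets(hits_ab, score_cutoff)
    best_ba = _best_targets(hits_ba, score_cutoff)
    pairs = []
    for a, b in sorted(best_ab.items()):
        if b is not None and best_ba.get(b) == a:
            rec = {"a": a, "b": b}
            if reference_lengths is not None and b in reference_lengths:
                blocks = [
                    (h.target_start, h.target_end)
                    for h in hits_ab
                    if h.query_id == a and h.target_id == b
                ] + [
                    (h.query_start, h.query_end)
                    for h in hits_ba
                    if h.query_id == b and h.target_id == a
                ]
                rec["coverage"] = _union_length(blocks) / reference_lengths[b]
            pairs.append(rec)
    return pairs


def _best_targets(hits: list[AlignmentRecord], cutoff: float) -> dict[str, Optional[str]]:
    """Top-scoring target per query among hits >= cutoff; a score tie between
    distinct targets makes the best hit ambiguous (None)."""
    best: dict[str, tuple[float, Optional[str]]] = {}
    for h in hits:
        if h.score < cutoff:
            continue
        cur = best.get(h.query_id)
        if cur is None or h.score > cur[0]:
            best[h.query_id] = (h.score, h.target_id)
        elif h.score == cur[0] and h.target_id != cur[1]:
            best[h.query_id] = (h.score, None)
    return {q: t for q, (_, t) in best.items()}


def single_scaffold_coverage(
    alignments: Iterable[AlignmentRecord],
    transcript_lengths: Mapping[str, int],
    fraction_thresholds: Sequence[float] = (0.9, 0.6),
) -> dict[float, float]:
    """Fraction of transcripts for which some single scaffold's alignments
    cover more than each threshold fraction of the transcript length.

    Blocks from the same scaffold are merged before summing; the denominator
    is all transcripts in ``transcript_lengths`` (unaligned ones count
    against every threshold).
    """
    per_tx_scaf: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for h in alignments:
        if h.query_id not in transcript_lengths:
            continue
        per_tx_scaf.setdefault(h.query_id, {}).setdefault(h.target_id, []).append(
            (h.query_start, h.query_end)
        )
    n_total = len(transcript_lengths)
    if n_total == 0:
        raise ValueError("no transcripts")
    best_cov = {}
    for tx, by_scaf in per_tx_scaf.items():
        best_cov[tx] = max(
            _union_length(blocks) / transcript_lengths[tx] for blocks in by_scaf.values()
        )
    return {
        float(f): sum(1 for c in best_cov.values() if c > f) / n_total
        for f in fraction_thresholds
    }
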