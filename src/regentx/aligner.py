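"""Minimal seeded exact-match aligner.

K-mer seeds, ungapped extension, perfect-match counting — just enough to
place transcript chunks and reads on synthetic scaffolds without shelling
out to an external aligner. Real datasets supply precomputed PSL or BLAST
tabular placements instead; this aligner exists to drive synthetic tests
end-to-end.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from .models import AlignmentRecord


def _as_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


class SeedAligner:
    """Ungapped aligner over a fixed target set.

    Seeds of length ``k`` are indexed for every target position; a query is
    scanned on both strands, seed hits define diagonals, and each candidate
    diagonal is scored by counting exact base matches over the overlap of
    the full query with the target.
    """

    def __init__(self, targets: dict[str, str], k: int = 16):
        if k < 8:
            raise ValueError("seed length must be >= 8")
        self.k = k
        self.targets = dict(targets)
        self._arrays = {tid: _as_bytes(seq) for tid, seq in self.targets.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            for pos in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((tid, pos))

    def align(self, query: str, query_id: str = "query") -> list[AlignmentRecord]:
        """All distinct ungapped placements of the query, both strands."""
        records: list[AlignmentRecord] = []
        for strand, qseq in (("+", query), ("-", str(Seq(query).reverse_complement()))):
            records.extend(self._align_one_strand(qseq, query_id, strand, len(query)))
        return records

    def _align_one_strand(self, qseq, query_id, strand, orig_len):
        k = self.k
        qarr = _as_bytes(qseq)
        n = len(qseq)
        seen: set[tuple[str, int]] = set()
        records = []
        for qpos in range(0, max(n - k, 0) + 1, k):
            for tid, tpos in self._index.get(qseq[qpos : qpos + k], ()):
                diag = tpos - qpos
                if (tid, diag) in seen:
                    continue
                seen.add((tid, diag))
                tarr = self._arrays[tid]
                # overlap of the full query projected at this diagonal
                q_lo = max(0, -diag)
                q_hi = min(n, len(tarr) - diag)
                if q_hi - q_lo < k:
                    continue
                matched = int(
                    np.count_nonzero(qarr[q_lo:q_hi] == tarr[q_lo + diag : q_hi + diag])
                )
                if strand == "+":
                    q_start, q_end = q_lo, q_hi
                else:  # report on original query coordinates
                    q_start, q_end = orig_len - q_hi, orig_len - q_lo
                records.append(
                    AlignmentRecord(
                        query_id=query_id,
                        target_id=tid,
                        query_start=q_start,
                        query_end=q_end,
                        target_start=q_lo + diag,
                        target_end=q_hi + diag,
                        strand=strand,
                        matched_bases=matched,
                        alignment_length=q_hi - q_lo,
                        score=float(matched),
                    )
                )
        return records
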