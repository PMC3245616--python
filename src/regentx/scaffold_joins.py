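"""Detection of transcripts that bridge two genomic scaffolds.

On a fragmented draft genome, a de novo transcript whose pieces align to two
different scaffolds is evidence that those scaffolds are adjacent in the real
genome. The procedure: take the longest isoform of each gene at least 1 kb
long, split it into non-overlapping 500-bp chunks, place each chunk on the
scaffolds independently keeping only near-perfect placements (>= 450/500
matched bases, ambiguous ties discarded), flag transcripts whose chunks land
on two or more scaffolds, and finally ask whether a single continuous
protein-homology block spans the putative junction — independent support
that the bridge is a real gene rather than a chimeric assembly artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .aligner import SeedAligner
from .models import AlignmentRecord, TranscriptSet

CHUNK_SIZE = 500
MIN_MATCHES = 450
MIN_TRANSCRIPT_LENGTH = 1_000
DEFAULT_MARGIN = 25


@dataclass(frozen=True)
class ChunkPlacement:
    transcript_id: str
    chunk_index: int
    chunk_start: int
    chunk_end: int
    scaffold_id: str
    matched_bases: int
    strand: str


@dataclass
class JoinCall:
    transcript_id: str
    # ordered (scaffold id, transcript span supported by its chunks)
    segments: list[tuple[str, tuple[int, int]]]
    junctions: list[int]  # transcript coordinates
    supported: bool
    supported_junctions: list[int] = field(default_factory=list)
    protein_id: Optional[str] = None
    protein_span: Optional[tuple[int, int]] = None

    @property
    def scaffolds(self) -> list[str]:
        return [s for s, _ in self.segments]


def chunk_transcript(seq: str, chunk_size: int = CHUNK_SIZE) -> list[tuple[int, int]]:
    """Non-overlapping chunk spans; the sub-chunk-size remainder is dropped."""
    n_full = len(seq) // chunk_size
    return [(i * chunk_size, (i + 1) * chunk_size) for i in range(n_full)]


def best_chunk_placement(
    placements: Sequence[ChunkPlacement], min_matches: int = MIN_MATCHES
) -> Optional[ChunkPlacement]:
    """The highest-matching placement if it clears ``min_matches``; a tie in
    matched bases across different scaffolds is ambiguous and yields none."""
    if not placements:
        return None
    best = max(placements, key=lambda p: p.matched_bases)
    if best.matched_bases < min_matches:
        return None
    tied_scaffolds = {
        p.scaffold_id for p in placements if p.matched_bases == best.matched_bases
    }
    if len(tied_scaffolds) > 1:
        return None
    return best


def candidate_joins(
    placements_by_transcript: Mapping[str, Mapping[int, Optional[ChunkPlacement]]],
) -> list[JoinCall]:
    """Transcripts whose retained chunks sit on >= 2 distinct scaffolds.

    Consecutive placed chunks on the same scaffold form a run; a junction is
    placed midway between the end of one run's chunk span and the start of
    the next run's. Unplaced chunks between runs do not block a candidate.
    """
    calls = []
    for tid in sorted(placements_by_transcript):
        by_index = placements_by_transcript[tid]
        placed = [by_index[i] for i in sorted(by_index) if by_index[i] is not None]
        if not placed:
            continue
        runs: list[list[ChunkPlacement]] = []
        for p in placed:
            if runs and runs[-1][-1].scaffold_id == p.scaffold_id:
                runs[-1].append(p)
            else:
                runs.append([p])
        if len({r[0].scaffold_id for r in runs}) < 2:
            continue
        segments = [
            (r[0].scaffold_id, (r[0].chunk_start, r[-1].chunk_end)) for r in runs
        ]
        junctions = [
            (runs[i][-1].chunk_end + runs[i + 1][0].chunk_start) // 2
            for i in range(len(runs) - 1)
        ]
        calls.append(
            JoinCall(transcript_id=tid, segments=segments, junctions=junctions, supported=False)
        )
    return calls


def junction_support(
    candidate: JoinCall,
    protein_hits: Iterable[AlignmentRecord],
    margin: int = DEFAULT_MARGIN,
    evalue_cutoff: float = 1e-3,
) -> JoinCall:
    """Mark the candidate supported when a single continuous protein
    alignment block spans [junction - margin, junction + margin] on the
    transcript for at least one junction. Candidates without protein support
    are retained as low-confidence (supported=False)."""
    hits = [
        h
        for h in protein_hits
        if h.query_id == candidate.transcript_id
        and (h.evalue is None or h.evalue <= evalue_cutoff)
    ]
    supported_junctions: list[int] = []
    best: Optional[AlignmentRecord] = None
    for j in candidate.junctions:
        for h in hits:
            if h.query_start <= j - margin and h.query_end >= j + margin:
                supported_junctions.append(j)
                if best is None or h.score > best.score:
                    best = h
                break
    candidate.supported = bool(supported_junctions)
    candidate.supported_junctions = supported_junctions
    if best is not None:
        candidate.protein_id = best.target_id
        candidate.protein_span = (best.query_start, best.query_end)
    return candidate


def placements_from_alignments(
    records: Iterable[AlignmentRecord], chunk_spans: Mapping[str, list[tuple[int, int]]]
) -> dict[str, dict[int, list[ChunkPlacement]]]:
    """Group precomputed chunk-vs-scaffold alignments by transcript and
    chunk. Record query ids must be ``<transcript_id>|chunk<i>``."""
    out: dict[str, dict[int, list[ChunkPlacement]]] = {}
    for r in records:
        tid, _, chunk_tag = r.query_id.rpartition("|chunk")
        idx = int(chunk_tag)
        start, end = chunk_spans[tid][idx]
        out.setdefault(tid, {}).setdefault(idx, []).append(
            ChunkPlacement(
                transcript_id=tid,
                chunk_index=idx,
                chunk_start=start,
                chunk_end=end,
                scaffold_id=r.target_id,
                matched_bases=r.matched_bases,
                strand=r.strand,
            )
        )
    return out


def find_joins(
    transcripts: TranscriptSet,
    scaffolds: Optional[dict[str, str]] = None,
    chunk_alignments: Optional[Iterable[AlignmentRecord]] = None,
    protein_hits: Optional[Iterable[AlignmentRecord]] = None,
    chunk_size: int = CHUNK_SIZE,
    min_matches: int = MIN_MATCHES,
    min_length: int = MIN_TRANSCRIPT_LENGTH,
    margin: int = DEFAULT_MARGIN,
) -> list[JoinCall]:
    """End-to-end join detection on the longest isoform of each gene.

    Chunk placements come either from ``chunk_alignments`` (precomputed
    PSL/BLAST-tabular records with ``<tid>|chunk<i>`` query ids) or from the
    internal seeded aligner run against ``scaffolds``.
    """
    reference = transcripts.longest_isoforms()
    eligible = [t for t in reference if len(t) >= min_length]
    chunk_spans = {t.id: chunk_transcript(t.seq, chunk_size) for t in eligible}

    if chunk_alignments is not None:
        raw = placements_from_alignments(chunk_alignments, chunk_spans)
    elif scaffolds is not None:
        aligner = SeedAligner(scaffolds)
        raw = {}
        for t in eligible:
            per_chunk: dict[int, list[ChunkPlacement]] = {}
            for idx, (s, e) in enumerate(chunk_spans[t.id]):
                recs = aligner.align(t.seq[s:e], query_id=f"{t.id}|chunk{idx}")
                per_chunk[idx] = [
                    ChunkPlacement(t.id, idx, s, e, r.target_id, r.matched_bases, r.strand)
                    for r in recs
                ]
            raw[t.id] = per_chunk
    else:
        raise ValueError("provide either scaffolds or chunk_alignments")

    best: dict[str, dict[int, Optional[ChunkPlacement]]] = {
        tid: {
            idx: best_chunk_placement(cands, min_matches)
            for idx, cands in per_chunk.items()
        }
        for tid, per_chunk in raw.items()
    }
    calls = candidate_joins(best)
    hits = list(protein_hits) if protein_hits is not None else []
    return [junction_support(c, hits, margin) for c in calls]


def joins_to_frame(calls: list[JoinCall]):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "scaffolds": ",".join(c.scaffolds),
                "junctions": ",".join(str(j) for j in c.junctions),
                "supported": c.supported,
                "protein_id": c.protein_id or "",
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["transcript_id", "scaffolds", "junctions", "supported", "protein_id"]
    )
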