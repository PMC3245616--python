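"""Hierarchical unique read assignment and strand-bias calling.

Reads are counted against the longest isoform of each locus in three steps:
(1) pairs aligned concordantly (mates on opposite strands facing inward on
one transcript, implied fragment below a maximum) are accepted when exactly
one such placement exists; (2) otherwise the forward mate alone is accepted
if it places uniquely; (3) otherwise the reverse mate, likewise. Every
accepted unit — pair or singleton — contributes a single fragment count, so
a pair is never counted twice. Stranded libraries additionally accumulate
per-gene forward/reverse fragment counts, from which a ten-fold imbalance
calls the transcribed strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .aligner import SeedAligner
from .models import CountMatrix, LibraryInfo, QualityRead, TranscriptSet

DEFAULT_MAX_FRAGMENT = 600
DEFAULT_MIN_MAPQ = 20
STRAND_BIAS_RATIO = 10.0


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    mate: int  # 1 or 2
    transcript_id: str
    start: int
    end: int
    strand: str
    mapping_quality: Optional[int] = None


@dataclass(frozen=True)
class AcceptedUnit:
    read_id: str
    transcript_id: str
    step: int  # 1 = pair, 2 = forward singleton, 3 = reverse singleton
    strand: str  # fragment strand relative to the transcript


CandidateMap = Mapping[str, Mapping[int, list[ReadPlacement]]]


def _concordant_pairs(
    p1s: list[ReadPlacement], p2s: list[ReadPlacement], max_fragment: int
) -> list[tuple[ReadPlacement, ReadPlacement]]:
    pairs = []
    for p1 in p1s:
        for p2 in p2s:
            if p1.transcript_id != p2.transcript_id or p1.strand == p2.strand:
                continue
            fwd, rev = (p1, p2) if p1.strand == "+" else (p2, p1)
            if fwd.start <= rev.start and (rev.end - fwd.start) <= max_fragment:
                pairs.append((p1, p2))
    return pairs


def _mapq_ok(p: ReadPlacement, min_mapq: int) -> bool:
    return p.mapping_quality is None or p.mapping_quality > min_mapq


def assign_hierarchical(
    candidates: CandidateMap,
    max_fragment: int = DEFAULT_MAX_FRAGMENT,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[list[AcceptedUnit], int]:
    """Resolve each read pair's candidate placements to at most one unit.

    ``candidates`` maps read id -> mate (1/2) -> candidate placements. The
    mapping-quality filter applies only to placements that carry the field.
    Returns (accepted units, number of unassigned pairs); each pair
    contributes exactly one unit or one unassigned tally.
    """
    units: list[AcceptedUnit] = []
    unassigned = 0
    for read_id in sorted(candidates):
        per_mate = candidates[read_id]
        p1s = [p for p in per_mate.get(1, []) if _mapq_ok(p, min_mapq)]
        p2s = [p for p in per_mate.get(2, []) if _mapq_ok(p, min_mapq)]
        conc = _concordant_pairs(p1s, p2s, max_fragment)
        if len(conc) == 1:
            p1, _ = conc[0]
            units.append(AcceptedUnit(read_id, p1.transcript_id, step=1, strand=p1.strand))
        elif len(p1s) == 1:
            p1 = p1s[0]
            units.append(AcceptedUnit(read_id, p1.transcript_id, step=2, strand=p1.strand))
        elif len(p2s) == 1:
            p2 = p2s[0]
            # a reverse-mate placement on '-' implies a forward-sense fragment
            strand = "+" if p2.strand == "-" else "-"
            units.append(AcceptedUnit(read_id, p2.transcript_id, step=3, strand=strand))
        else:
            unassigned += 1
    return units, unassigned


def count_per_locus(
    units_by_library: Mapping[str, list[AcceptedUnit]],
    reference: TranscriptSet,
    libraries: Mapping[str, LibraryInfo],
) -> CountMatrix:
    """Per-gene, per-library unique fragment counts on the counting
    reference (one transcript per gene). Stranded libraries also accumulate
    per-gene forward/reverse fragment counts."""
    gene_ids = sorted(reference.genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    lib_names = list(units_by_library)
    counts = np.zeros((len(gene_ids), len(lib_names)), dtype=np.int64)
    strand_rows = []
    for j, lib in enumerate(lib_names):
        fwd = np.zeros(len(gene_ids), dtype=np.int64)
        rev = np.zeros(len(gene_ids), dtype=np.int64)
        for unit in units_by_library[lib]:
            if unit.transcript_id not in reference:
                raise ValueError(
                    f"placement to unknown transcript {unit.transcript_id!r} in {lib}"
                )
            g = gene_pos[reference.gene_of(unit.transcript_id)]
            counts[g, j] += 1
            if unit.strand == "+":
                fwd[g] += 1
            else:
                rev[g] += 1
        if libraries[lib].stranded:
            strand_rows.append(
                pd.DataFrame(
                    {"library": lib, "gene_id": gene_ids, "forward": fwd, "reverse": rev}
                )
            )
    strand_counts = pd.concat(strand_rows, ignore_index=True) if strand_rows else None
    return CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=lib_names), libraries, strand_counts
    )


def strand_bias(forward: int, reverse: int, ratio: float = STRAND_BIAS_RATIO) -> str:
    """Call a gene's strand from stranded counts: forward-biased iff
    forward > ratio x reverse (strictly), symmetric for reverse; anything
    else — including (0, 0) — is unbiased."""
    if forward < 0 or reverse < 0:
        raise ValueError("counts must be non-negative")
    if forward > ratio * reverse:
        return "forward-biased"
    if reverse > ratio * forward:
        return "reverse-biased"
    return "unbiased"


# ---------------------------------------------------------------------------
# Placement sources


def placements_from_sam(path, min_len: int = 1) -> dict[str, dict[int, list[ReadPlacement]]]:
    """Candidate placements from a SAM file (one or more records per mate).

    MAPQ 255 ("unavailable") is treated as missing so the quality filter
    does not apply to aligners that do not compute it.
    """
    import pysam

    out: dict[str, dict[int, list[ReadPlacement]]] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            mate = 2 if rec.is_read2 else 1
            mapq = None if rec.mapping_quality == 255 else rec.mapping_quality
            out.setdefault(rec.query_name, {}).setdefault(mate, []).append(
                ReadPlacement(
                    read_id=rec.query_name,
                    mate=mate,
                    transcript_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end or rec.reference_start + min_len,
                    strand="-" if rec.is_reverse else "+",
                    mapping_quality=mapq,
                )
            )
    return out


def align_read_pairs(
    reads1: Iterable[QualityRead],
    reads2: Iterable[QualityRead],
    reference: TranscriptSet,
    k: int = 18,
) -> dict[str, dict[int, list[ReadPlacement]]]:
    """Enumerate perfect-match candidate placements for read pairs with the
    internal seeded aligner (synthetic-data driver)."""
    aligner = SeedAligner({t.id: t.seq for t in reference}, k=k)
    out: dict[str, dict[int, list[ReadPlacement]]] = {}
    for mate, reads in ((1, reads1), (2, reads2)):
        for r in reads:
            hits = [
                h
                for h in aligner.align(r.bases, query_id=r.id)
                if h.matched_bases == len(r.bases)
            ]
            out.setdefault(r.id, {})[mate] = [
                ReadPlacement(r.id, mate, h.target_id, h.target_start, h.target_end, h.strand)
                for h in hits
            ]
    return out
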