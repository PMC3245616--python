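"""Shared domain types for the regeneration-transcriptome toolkit.

Coordinate convention, used everywhere in this package: 0-based, half-open
spans. Strand ``"+"`` means the transcript sense strand equals the scaffold
forward strand. Tabular inputs with 1-based inclusive coordinates (BLAST
tabular) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

PHRED_MIN = 0
PHRED_MAX = 41


@dataclass
class QualityRead:
    """A sequencing read with per-base Phred qualities and mate linkage."""

    id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, one per base
    mate: Optional[int] = None  # 1, 2 or None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Transcript:
    id: str
    gene_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A locus with one or more isoforms; the longest isoform is the
    counting/QC reference (ties broken lexicographically by isoform id)."""

    gene_id: str
    isoforms: list[Transcript]

    @property
    def longest_isoform(self) -> Transcript:
        return min(self.isoforms, key=lambda t: (-len(t.seq), t.id))


class TranscriptSet:
    """An ordered collection of transcripts grouped into gene models."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: list[Transcript] = list(transcripts)
        self._by_id = {t.id: t for t in self.transcripts}
        genes: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            genes.setdefault(t.gene_id, []).append(t)
        self.genes: dict[str, GeneModel] = {
            g: GeneModel(g, iso) for g, iso in genes.items()
        }

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._by_id[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def gene_of(self, transcript_id: str) -> str:
        return self._by_id[transcript_id].gene_id

    def longest_isoforms(self) -> "TranscriptSet":
        return TranscriptSet(
            gm.longest_isoform for gm in self.genes.values()
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """Generic query-to-target local alignment (BLAST/blat-style hit)."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"
    matched_bases: int = 0
    alignment_length: int = 0
    score: float = 0.0
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError(f"invalid query span [{self.query_start},{self.query_end})")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(f"invalid target span [{self.target_start},{self.target_end})")
        if self.matched_bases > max(self.alignment_length, self.query_end - self.query_start):
            raise ValueError("matched_bases exceeds alignment length")

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)


@dataclass
class LibraryInfo:
    """Per-library metadata for a count matrix column."""

    name: str
    time_window: str
    batch: int
    is_control: bool
    stranded: bool = False


class CountMatrix:
    """Genes x libraries matrix of unique-read counts plus library metadata.

    ``counts`` is a pandas DataFrame (rows = genes, columns = library names,
    non-negative integers). ``libraries`` maps column name -> LibraryInfo.
    Optional per-gene forward/reverse strand counts for stranded libraries.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        libraries: Mapping[str, LibraryInfo],
        strand_counts: Optional[pd.DataFrame] = None,
    ):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.columns) - set(libraries)
        if missing:
            raise ValueError(f"libraries missing metadata: {sorted(missing)}")
        self.counts = counts
        self.libraries = dict(libraries)
        self.strand_counts = strand_counts

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def library_names(self) -> list[str]:
        return list(self.counts.columns)

    def control_libraries(self) -> list[str]:
        return [n for n in self.library_names if self.libraries[n].is_control]

    def timepoint_libraries(self) -> list[str]:
        return [n for n in self.library_names if not self.libraries[n].is_control]

    def control_for(self, library: str) -> str:
        """The control library in the same batch as ``library``."""
        batch = self.libraries[library].batch
        for name in self.control_libraries():
            if self.libraries[name].batch == batch:
                return name
        raise ValueError(f"library {library} (batch {batch}) has no batch control")


@dataclass
class TruthRow:
    """Ground-truth record for one synthetic gene."""

    gene_id: str
    temporal_class: Optional[int]  # 1..5 or None (null gene)
    strand: str
    # split status: both None for single-scaffold genes
    scaffold_5p: Optional[str] = None
    scaffold_3p: Optional[str] = None
    junction_offset: Optional[int] = None  # transcript coordinate of the join
    mean_expression: dict = field(default_factory=dict)  # library -> true mean

    @property
    def is_split(self) -> bool:
        return self.junction_offset is not None


class TruthTable:
    """Per-gene ground truth emitted by the synthetic generators."""

    def __init__(self, rows: Iterable[TruthRow]):
        self.rows: dict[str, TruthRow] = {}
        for r in rows:
            if r.gene_id in self.rows:
                raise ValueError(f"duplicate truth row for {r.gene_id}")
            self.rows[r.gene_id] = r

    def __getitem__(self, gene_id: str) -> TruthRow:
        return self.rows[gene_id]

    def __iter__(self):
        return iter(self.rows.values())

    def __len__(self) -> int:
        return len(self.rows)

    def split_genes(self) -> list[TruthRow]:
        return [r for r in self.rows.values() if r.is_split]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows.values():
            recs.append(
                {
                    "gene_id": r.gene_id,
                    "temporal_class": "" if r.temporal_class is None else r.temporal_class,
                    "strand": r.strand,
                    "scaffold_5p": r.scaffold_5p or "",
                    "scaffold_3p": r.scaffold_3p or "",
                    "junction_offset": "" if r.junction_offset is None else r.junction_offset,
                }
            )
        return pd.DataFrame.from_records(recs)
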