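"""Readers and writers for the standard formats the pipeline consumes.

FASTA/FASTQ go through Biopython; SAM through pysam; tabular alignment
formats (BLAST outfmt-6 and PSL) through pandas. BLAST tabular coordinates
(1-based, inclusive, possibly reversed) are converted to 0-based half-open
spans with an explicit strand on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentRecord, CountMatrix, LibraryInfo, QualityRead, Transcript, TranscriptSet

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

PSL_COLUMNS = [
    "matches", "misMatches", "repMatches", "nCount", "qNumInsert", "qBaseInsert",
    "tNumInsert", "tBaseInsert", "strand", "qName", "qSize", "qStart", "qEnd",
    "tName", "tSize", "tStart", "tEnd", "blockCount", "blockSizes", "qStarts", "tStarts",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_transcript_fasta(path, gene_of=None) -> TranscriptSet:
    """Read transcripts from FASTA. ``gene_of`` maps a transcript id to its
    gene id; by default ids of the form ``<gene>.<isoform>`` are split on the
    last dot, otherwise the transcript is its own gene."""
    if gene_of is None:
        gene_of = lambda tid: tid.rsplit(".", 1)[0] if "." in tid else tid
    seqs = read_fasta(path)
    return TranscriptSet(Transcript(tid, gene_of(tid), s) for tid, s in seqs.items())


def read_fastq(path, mate: Optional[int] = None, phred_offset: int = 33) -> Iterator[QualityRead]:
    """Stream a FASTQ file as QualityRead records."""
    extra = 0 if phred_offset == 33 else phred_offset - 33
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64) - extra
            yield QualityRead(rec.id, str(rec.seq), quals, mate=mate)


def write_fastq(reads: Iterable[QualityRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            q = "".join(chr(int(x) + 33) for x in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# Alignment tables


def read_blast6(path) -> list[AlignmentRecord]:
    """Read BLAST tabular (outfmt 6). Coordinates converted from 1-based
    inclusive to 0-based half-open; reversed subject spans encode strand."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    records = []
    for row in df.itertuples(index=False):
        qs, qe = int(row.qstart) - 1, int(row.qend)
        ss, se = int(row.sstart), int(row.send)
        if ss <= se:
            strand, ts, te = "+", ss - 1, se
        else:
            strand, ts, te = "-", se - 1, ss
        aln_len = int(row.length)
        matched = int(round(aln_len * float(row.pident) / 100.0))
        records.append(
            AlignmentRecord(
                query_id=str(row.qseqid),
                target_id=str(row.sseqid),
                query_start=qs,
                query_end=qe,
                target_start=ts,
                target_end=te,
                strand=strand,
                matched_bases=matched,
                alignment_length=aln_len,
                score=float(row.bitscore),
                evalue=float(row.evalue),
            )
        )
    return records


def write_blast6(records: Iterable[AlignmentRecord], path) -> None:
    rows = []
    for r in records:
        pident = 100.0 * r.matched_bases / max(r.alignment_length, 1)
        if r.strand == "+":
            ss, se = r.target_start + 1, r.target_end
        else:
            ss, se = r.target_end, r.target_start + 1
        rows.append(
            (r.query_id, r.target_id, f"{pident:.2f}", r.alignment_length,
             r.alignment_length - r.matched_bases, 0, r.query_start + 1,
             r.query_end, ss, se,
             "1e-180" if r.evalue is None else repr(r.evalue), f"{r.score:.1f}")
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_psl(path) -> list[AlignmentRecord]:
    """Read blat PSL (headerless or with the 5-line header). PSL is already
    0-based half-open. The blat score is computed as
    matches + repMatches - misMatches - qNumInsert - tNumInsert (the classic
    web-BLAT score)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 21 or not parts[0].lstrip("-").isdigit():
                continue  # header lines
            rows.append(parts)
    records = []
    for p in rows:
        d = dict(zip(PSL_COLUMNS, p))
        matches = int(d["matches"]) + int(d["repMatches"])
        mismatches = int(d["misMatches"])
        score = matches - mismatches - int(d["qNumInsert"]) - int(d["tNumInsert"])
        records.append(
            AlignmentRecord(
                query_id=d["qName"],
                target_id=d["tName"],
                query_start=int(d["qStart"]),
                query_end=int(d["qEnd"]),
                target_start=int(d["tStart"]),
                target_end=int(d["tEnd"]),
                strand=d["strand"][0],
                matched_bases=matches,
                alignment_length=matches + mismatches,
                score=float(score),
                evalue=None,
            )
        )
    return records


def read_alignments(path, fmt: str) -> list[AlignmentRecord]:
    if fmt == "blast6":
        return read_blast6(path)
    if fmt == "psl":
        return read_psl(path)
    raise ValueError(f"unknown alignment format: {fmt}")


# ---------------------------------------------------------------------------
# Count matrices


def write_count_matrix(cm: CountMatrix, counts_path, libs_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    meta = {
        name: {
            "time_window": info.time_window,
            "batch": int(info.batch),
            "is_control": bool(info.is_control),
            "stranded": bool(info.stranded),
        }
        for name, info in cm.libraries.items()
    }
    with open(libs_path, "w") as fh:
        yaml.safe_dump({"libraries": meta}, fh, sort_keys=False)


def read_count_matrix(counts_path, libs_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    with open(libs_path) as fh:
        meta = yaml.safe_load(fh)["libraries"]
    libs = {
        name: LibraryInfo(
            name=name,
            time_window=str(m["time_window"]),
            batch=int(m["batch"]),
            is_control=bool(m["is_control"]),
            stranded=bool(m.get("stranded", False)),
        )
        for name, m in meta.items()
    }
    return CountMatrix(counts, libs)
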