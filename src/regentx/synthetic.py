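"""Synthetic data with planted ground truth.

Emulates the data shapes of a short-read regeneration time-course study on a
fragmented, A/T-rich genome: supercontig-like scaffolds, multi-isoform
transcripts (a configurable fraction spanning two scaffolds), 2 x 36-bp
paired-end reads with decaying qualities, a stand-in ortholog protein set,
and negative-binomial count matrices for five regeneration time windows plus
two control libraries split across two processing batches. Every generator
records its ground truth so downstream stages can be scored exactly.

All randomness flows from ``SimConfig.seed``; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from Bio.Seq import Seq

from .models import (
    AlignmentRecord,
    CountMatrix,
    LibraryInfo,
    QualityRead,
    Transcript,
    TranscriptSet,
    TruthRow,
    TruthTable,
)

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Five temporal prototypes (log2 fold change vs control per time window),
# shaped after the canonical regeneration classes: early sustained induction,
# transient early induction, late induction, repression peaking mid-course
# with partial recovery, and monotone late repression. Because downstream
# classification z-scores each profile, the prototypes are chosen to be
# distinct as SHAPES (minimum pairwise z-space distance ~1.7), not merely in
# amplitude.
DEFAULT_CLASS_PROFILES: tuple[tuple[float, ...], ...] = (
    (0.4, 1.6, 2.0, 2.0, 2.0),
    (1.6, 2.2, -0.2, -0.4, -0.3),
    (-0.2, -0.1, 0.0, 0.8, 2.4),
    (-0.2, -1.5, -2.4, -1.4, -0.6),
    (0.1, 0.0, -0.2, -0.9, -2.4),
)

TIME_WINDOW_LABELS = ("0.5-1h", "2-3h", "4-8h", "10-18h", "24-72h")


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Lengths are bp; ``scaffold_length_dist`` and ``transcript_length_dist``
    are (mean, sd) of log-normal draws; ``quality_model`` is
    (start Phred, per-cycle decay, noise sd); ``library_size_dist`` is
    (mean, cv) of relative library size factors.
    """

    seed: int = 0
    n_scaffolds: int = 40
    scaffold_length_dist: tuple[float, float] = (11_300.0, 6_000.0)
    at_fraction: float = 0.65
    n_genes: int = 200
    isoforms_per_gene_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    split_gene_fraction: float = 0.1
    transcript_length_dist: tuple[float, float] = (1_500.0, 900.0)
    min_transcript_length: int = 300
    read_length: int = 36
    n_read_pairs: int = 10_000
    fragment_length: tuple[float, float] = (200.0, 20.0)
    quality_model: tuple[float, float, float] = (38.0, 0.35, 2.0)
    n_timepoint_libs: int = 5
    class_profiles: tuple[tuple[float, ...], ...] = DEFAULT_CLASS_PROFILES
    de_gene_fraction: float = 0.065
    # (median, log-sd) of per-gene baseline counts; median 500 with log-sd 1
    # gives a mean of ~820 counts/gene, matching libraries of ~12-16 million
    # unique counts over ~17,500 loci
    baseline_expression: tuple[float, float] = (500.0, 1.0)
    nb_dispersion: float = 0.0
    library_size_dist: tuple[float, float] = (1.0, 0.2)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("at_fraction", "split_gene_fraction", "de_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("n_scaffolds", "n_genes", "read_length", "n_read_pairs",
                     "n_timepoint_libs", "min_transcript_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if any(m <= 0 for m in self.scaffold_length_dist + self.transcript_length_dist):
            raise ConfigError("length distributions must have positive parameters")
        if abs(sum(self.isoforms_per_gene_dist.values()) - 1.0) > 1e-9:
            raise ConfigError("isoforms_per_gene_dist probabilities must sum to 1")
        if len(self.class_profiles) < 1:
            raise ConfigError("need at least one class profile")
        for prof in self.class_profiles:
            if len(prof) != self.n_timepoint_libs:
                raise ConfigError("class profile length must equal n_timepoint_libs")

    def rng(self, *stream: int) -> np.random.Generator:
        """A named, independent random stream derived from the master seed."""
        return np.random.default_rng([self.seed, *stream])

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "isoforms_per_gene_dist" in raw:
            raw["isoforms_per_gene_dist"] = {
                int(k): float(v) for k, v in raw["isoforms_per_gene_dist"].items()
            }
        for key in ("scaffold_length_dist", "transcript_length_dist", "quality_model",
                    "library_size_dist", "fragment_length", "baseline_expression"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        if "class_profiles" in raw:
            raw["class_profiles"] = tuple(tuple(float(x) for x in p) for p in raw["class_profiles"])
        return cls(**raw)


def _lognormal_lengths(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.asarray(np.round(rng.lognormal(mu, np.sqrt(sigma2), size=n)), dtype=np.int64)


# ---------------------------------------------------------------------------
# Genome


def generate_genome(cfg: SimConfig) -> dict[str, str]:
    """Random scaffolds with the configured A/T composition."""
    rng = cfg.rng(1)
    lengths = np.maximum(
        _lognormal_lengths(rng, *cfg.scaffold_length_dist, cfg.n_scaffolds), 1_000
    )
    at = cfg.at_fraction
    probs = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    alphabet = np.frombuffer(b"ATGC", dtype=np.uint8)
    scaffolds: dict[str, str] = {}
    for i, L in enumerate(lengths):
        idx = rng.choice(4, size=int(L), p=probs)
        scaffolds[f"scaf{i:05d}"] = alphabet[idx].tobytes().decode("ascii")
    return scaffolds


# ---------------------------------------------------------------------------
# Transcriptome


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def generate_transcriptome(
    genome: dict[str, str], cfg: SimConfig
) -> tuple[TranscriptSet, TruthTable]:
    """Plant genes on the scaffolds.

    Single-scaffold genes are exact substrings of one scaffold (on either
    strand); split genes concatenate a 3'-end region of one scaffold with a
    5'-end region of another, emulating a transcript that bridges two pieces
    of a fragmented assembly. Split genes carry a single isoform and the
    forward strand so that truth coordinates stay unambiguous; other genes
    may carry shorter isoforms nested in the longest one.
    """
    if not genome:
        raise ConfigError("genome is empty")
    rng = cfg.rng(2)
    scaffold_ids = sorted(genome)
    iso_counts = sorted(cfg.isoforms_per_gene_dist)
    iso_probs = [cfg.isoforms_per_gene_dist[k] for k in iso_counts]

    transcripts: list[Transcript] = []
    truth_rows: list[TruthRow] = []
    for g in range(cfg.n_genes):
        gene_id = f"g{g:05d}"
        L = int(
            max(
                cfg.min_transcript_length,
                _lognormal_lengths(rng, *cfg.transcript_length_dist, 1)[0],
            )
        )
        is_split = rng.random() < cfg.split_gene_fraction
        if is_split:
            tx, row = _make_split_gene(gene_id, L, genome, scaffold_ids, rng)
            transcripts.extend(tx)
        else:
            tx, row = _make_single_gene(
                gene_id, L, genome, scaffold_ids, rng, iso_counts, iso_probs, cfg
            )
            transcripts.extend(tx)
        truth_rows.append(row)
    return TranscriptSet(transcripts), TruthTable(truth_rows)


def _pick_scaffold(scaffold_ids, genome, rng, min_len, max_retries=100):
    for _ in range(max_retries):
        sid = scaffold_ids[rng.integers(len(scaffold_ids))]
        if len(genome[sid]) >= min_len:
            return sid
    raise ConfigError(f"no scaffold of length >= {min_len} after {max_retries} retries")


def _make_single_gene(gene_id, L, genome, scaffold_ids, rng, iso_counts, iso_probs, cfg):
    sid = _pick_scaffold(scaffold_ids, genome, rng, L)
    scaf = genome[sid]
    start = int(rng.integers(0, len(scaf) - L + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    seq = scaf[start : start + L]
    if strand == "-":
        seq = _revcomp(seq)
    n_iso = int(rng.choice(iso_counts, p=iso_probs))
    isoforms = [Transcript(f"{gene_id}.i1", gene_id, seq)]
    for k in range(2, n_iso + 1):
        sub_len = max(cfg.min_transcript_length // 2, int(L * rng.uniform(0.4, 0.9)))
        sub_len = min(sub_len, L - 1)
        off = int(rng.integers(0, L - sub_len + 1))
        isoforms.append(Transcript(f"{gene_id}.i{k}", gene_id, seq[off : off + sub_len]))
    row = TruthRow(gene_id=gene_id, temporal_class=None, strand=strand)
    return isoforms, row


def _make_split_gene(gene_id, L, genome, scaffold_ids, rng):
    # Scaffold-bridging transcripts are long loci by nature (they span a
    # scaffold end on each side); enforce a 2-kb floor and keep the junction
    # at least 500 bp from either end so both sides carry real alignment
    # signal.
    L = max(L, 2_000)
    min_side = 500
    L1 = int(rng.integers(min_side, L - min_side + 1))
    L2 = L - L1
    sid_a = _pick_scaffold(scaffold_ids, genome, rng, L1)
    for _ in range(100):
        sid_b = _pick_scaffold(scaffold_ids, genome, rng, L2)
        if sid_b != sid_a:
            break
    else:
        raise ConfigError("could not pick two distinct scaffolds for a split gene")
    seq = genome[sid_a][-L1:] + genome[sid_b][:L2]
    tx = Transcript(f"{gene_id}.i1", gene_id, seq)
    row = TruthRow(
        gene_id=gene_id,
        temporal_class=None,
        strand="+",
        scaffold_5p=sid_a,
        scaffold_3p=sid_b,
        junction_offset=L1,
    )
    return [tx], row


# ---------------------------------------------------------------------------
# Reads


def generate_reads(
    transcripts: TranscriptSet,
    cfg: SimConfig,
    expression: Optional[dict[str, float]] = None,
) -> tuple[list[QualityRead], list[QualityRead]]:
    """Paired 36-bp reads from inward-facing fragment ends.

    Read 1 is the transcript-sense prefix of the fragment, read 2 the
    reverse complement of its suffix, so mates sit on opposite strands
    pointing inward. Pairs are allocated to transcripts in proportion to
    ``expression`` (uniform by default). Base calls are exact; qualities
    follow the linear-decay model with Gaussian noise, clamped to [2, 41].
    Read ids carry a ``tx=`` truth suffix used only by oracle checks.
    """
    rng = cfg.rng(3)
    rl = cfg.read_length
    min_frag = 2 * rl
    usable = [t for t in transcripts if len(t) >= min_frag]
    skipped = [t.id for t in transcripts if len(t) < min_frag]
    for tid in skipped:
        logger.warning("transcript %s shorter than minimum fragment %d; skipped", tid, min_frag)
    if not usable:
        raise ConfigError("no transcript long enough to fragment")
    if expression is None:
        weights = np.ones(len(usable))
    else:
        weights = np.array([expression.get(t.id, 0.0) for t in usable], dtype=float)
        if weights.sum() <= 0:
            raise ConfigError("expression weights sum to zero")
    weights = weights / weights.sum()
    alloc = rng.multinomial(cfg.n_read_pairs, weights)

    fmean, fsd = cfg.fragment_length
    start_q, decay, noise_sd = cfg.quality_model
    reads1: list[QualityRead] = []
    reads2: list[QualityRead] = []
    pair_idx = 0
    for t, n_pairs in zip(usable, alloc):
        L = len(t)
        for _ in range(int(n_pairs)):
            frag = int(np.clip(np.round(rng.normal(fmean, fsd)), min_frag, min(600, L)))
            pos = int(rng.integers(0, L - frag + 1))
            fragment = t.seq[pos : pos + frag]
            rid = f"simr{pair_idx:08d} tx={t.id} fs={pos} fl={frag}"
            q1 = _simulate_quals(rng, rl, start_q, decay, noise_sd)
            q2 = _simulate_quals(rng, rl, start_q, decay, noise_sd)
            reads1.append(QualityRead(rid, fragment[:rl], q1, mate=1))
            reads2.append(QualityRead(rid, _revcomp(fragment[-rl:]), q2, mate=2))
            pair_idx += 1
    return reads1, reads2


def _simulate_quals(rng, n, start, decay, noise_sd):
    cycles = np.arange(n)
    q = start - decay * cycles
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, size=n)
    return np.clip(np.round(q), 2, 41).astype(np.int64)


def truth_transcript_of(read_id: str) -> str:
    """Parse the truth suffix of a simulated read id (oracle use only)."""
    for tok in read_id.split():
        if tok.startswith("tx="):
            return tok[3:]
    raise ValueError(f"read id carries no truth suffix: {read_id}")


# ---------------------------------------------------------------------------
# Count time course


def generate_count_timecourse(cfg: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Unique-count matrix for 5 time windows + 2 controls in 2 batches.

    Batch 1 holds time windows 1-3 and control 1; batch 2 holds windows 4-5
    and control 2, mirroring the two-batch processing design. A fraction of
    genes is assigned one of the temporal classes; the rest are null
    (profile 0). Counts are negative binomial with mean
    baseline x size factor x 2^profile and the configured dispersion;
    dispersion 0 degenerates to Poisson.
    """
    rng = cfg.rng(4)
    n_t = cfg.n_timepoint_libs
    n_classes = len(cfg.class_profiles)
    gene_ids = [f"g{g:05d}" for g in range(cfg.n_genes)]

    # class assignment
    classes = np.zeros(cfg.n_genes, dtype=int)  # 0 = null
    n_de = int(round(cfg.de_gene_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    classes[de_idx] = rng.integers(1, n_classes + 1, size=n_de)

    med, log_sd = cfg.baseline_expression
    baseline = np.exp(rng.normal(np.log(med), log_sd, size=cfg.n_genes))

    mean_sf, cv = cfg.library_size_dist
    n_libs = n_t + 2
    size_factors = _lognormal_factors(rng, mean_sf, cv, n_libs)

    lib_names = [f"t{i+1}" for i in range(n_t)] + ["ctl1", "ctl2"]
    labels = list(TIME_WINDOW_LABELS[:n_t])
    if len(labels) < n_t:
        labels += [f"w{i+1}" for i in range(len(labels), n_t)]
    batch_of = {}
    meta = {}
    split_at = (n_t + 1) // 2  # windows 1..ceil(n/2) with control 1
    for i, name in enumerate(lib_names[:n_t]):
        batch_of[name] = 1 if i < split_at else 2
        meta[name] = LibraryInfo(name, labels[i], batch_of[name], is_control=False)
    meta["ctl1"] = LibraryInfo("ctl1", "0h", 1, is_control=True)
    meta["ctl2"] = LibraryInfo("ctl2", "0h", 2, is_control=True)

    profiles = np.zeros((cfg.n_genes, n_libs))
    prof_arr = np.asarray(cfg.class_profiles)
    for k in range(1, n_classes + 1):
        profiles[classes == k, :n_t] = prof_arr[k - 1]

    means = baseline[:, None] * size_factors[None, :] * np.exp2(profiles)
    counts = _nb_draw(rng, means, cfg.nb_dispersion)

    import pandas as pd

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=lib_names), meta)
    rows = []
    for g, gid in enumerate(gene_ids):
        rows.append(
            TruthRow(
                gene_id=gid,
                temporal_class=int(classes[g]) if classes[g] else None,
                strand="+",
                mean_expression={lib: float(means[g, j]) for j, lib in enumerate(lib_names)},
            )
        )
    return cm, TruthTable(rows)


def _lognormal_factors(rng, mean, cv, n):
    if cv <= 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Stand-in ortholog proteins


def generate_protein_db(
    transcripts: TranscriptSet,
    divergence: float,
    seed: int = 0,
    truth: Optional[TruthTable] = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """One stand-in ortholog protein per gene, translated from frame 0 of the
    longest isoform with point substitutions at the given per-residue rate.
    For split genes the protein continuously spans the junction by
    construction. Returns (protein fasta dict, gene -> ortholog aa length).
    """
    if not 0.0 <= divergence <= 0.5:
        raise ConfigError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng([seed, 5])
    proteins: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for gene_id in sorted(transcripts.genes):
        tx = transcripts.genes[gene_id].longest_isoform
        aa = _naive_translate(tx.seq)
        if divergence > 0:
            aa_list = list(aa)
            hits = rng.random(len(aa_list)) < divergence
            for i in np.flatnonzero(hits):
                choices = AA_ALPHABET.replace(aa_list[i], "") if aa_list[i] in AA_ALPHABET else AA_ALPHABET
                aa_list[i] = choices[rng.integers(len(choices))]
            aa = "".join(aa_list)
        pid = f"prot_{gene_id}"
        proteins[pid] = aa
        lengths[gene_id] = len(aa)
    return proteins, lengths


def _naive_translate(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def naive_protein_hits(
    transcripts: TranscriptSet, proteins: dict[str, str]
) -> list[AlignmentRecord]:
    """Full-length transcript-vs-protein alignments computed by direct
    frame-0 comparison (a blastx stand-in for synthetic data). One record per
    gene whose stand-in ortholog exists; coordinates are nucleotides on the
    transcript, residues on the protein."""
    records = []
    for gene_id in sorted(transcripts.genes):
        pid = f"prot_{gene_id}"
        if pid not in proteins:
            continue
        tx = transcripts.genes[gene_id].longest_isoform
        query_aa = _naive_translate(tx.seq)
        prot = proteins[pid]
        n = min(len(query_aa), len(prot))
        if n == 0:
            continue
        matched = sum(1 for a, b in zip(query_aa[:n], prot[:n]) if a == b)
        records.append(
            AlignmentRecord(
                query_id=tx.id,
                target_id=pid,
                query_start=0,
                query_end=3 * n,
                target_start=0,
                target_end=n,
                strand="+",
                matched_bases=3 * matched,
                alignment_length=3 * n,
                score=float(2 * matched),
                evalue=1e-180,
            )
        )
    return records


def eligible_split_genes(
    truth: TruthTable,
    transcripts: TranscriptSet,
    chunk_size: int = 500,
    min_length: int = 1_000,
) -> list[str]:
    """Planted split genes detectable by the chunked join procedure: the
    longest isoform is at least ``min_length`` and at least one full chunk
    lies entirely on each side of the junction."""
    import math

    out = []
    for row in truth.split_genes():
        t = transcripts.genes[row.gene_id].longest_isoform
        L, L1 = len(t), row.junction_offset
        if L < min_length:
            continue
        n_chunks = L // chunk_size
        side1 = L1 // chunk_size
        side2 = n_chunks - math.ceil(L1 / chunk_size)
        if side1 >= 1 and side2 >= 1:
            out.append(row.gene_id)
    return out
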