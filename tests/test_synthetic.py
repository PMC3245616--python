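"""The synthetic generators: determinism, composition, planted truth."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import chisquare

from regentx.synthetic import (
    ConfigError,
    SimConfig,
    eligible_split_genes,
    generate_count_timecourse,
    generate_genome,
    generate_protein_db,
    generate_reads,
    generate_transcriptome,
    naive_protein_hits,
    truth_transcript_of,
    _naive_translate,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"at_fraction": 1.2},
            {"split_gene_fraction": -0.1},
            {"n_genes": 0},
            {"nb_dispersion": -0.5},
            {"isoforms_per_gene_dist": {1: 0.5, 2: 0.2}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("seed: 5\nn_genes: 10\nat_fraction: 0.6\n")
        cfg = SimConfig.from_yaml(path)
        assert (cfg.seed, cfg.n_genes, cfg.at_fraction) == (5, 10, 0.6)


class TestGenome:
    def test_fixed_seed_is_byte_identical(self):
        cfg = SimConfig(seed=9, n_scaffolds=5)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_balanced_composition_at_half(self):
        cfg = SimConfig(seed=10, n_scaffolds=10, at_fraction=0.5,
                        scaffold_length_dist=(10_000.0, 1.0))
        seqs = "".join(generate_genome(cfg).values())
        obs = [seqs.count(b) for b in "ATGC"]
        assert chisquare(obs).pvalue > 0.01

    def test_at_rich_composition_within_two_points(self):
        cfg = SimConfig(seed=11, n_scaffolds=20, at_fraction=0.65,
                        scaffold_length_dist=(50_000.0, 10_000.0))
        seqs = "".join(generate_genome(cfg).values())
        assert len(seqs) >= 100_000
        at = (seqs.count("A") + seqs.count("T")) / len(seqs)
        assert 0.63 <= at <= 0.67


class TestTranscriptome:
    def test_no_splits_means_every_transcript_within_one_scaffold(self, small_genome):
        cfg = SimConfig(seed=12, n_genes=30, split_gene_fraction=0.0)
        ts, truth = generate_transcriptome(small_genome, cfg)
        assert not truth.split_genes()
        for t in ts:
            found = any(
                t.seq in s or str(Seq(t.seq).reverse_complement()) in s
                for s in small_genome.values()
            )
            assert found, t.id

    def test_split_count_within_binomial_bounds(self, small_genome):
        cfg = SimConfig(seed=13, n_genes=200, split_gene_fraction=0.1)
        _, truth = generate_transcriptome(small_genome, cfg)
        n_split = len(truth.split_genes())
        # 99.9% binomial(200, 0.1) interval
        assert 7 <= n_split <= 35

    def test_split_parts_match_source_scaffolds_at_truth_coordinates(
        self, small_genome, small_transcriptome
    ):
        ts, truth = small_transcriptome
        for row in truth.split_genes():
            t = ts.genes[row.gene_id].longest_isoform
            j = row.junction_offset
            assert 0 < j < len(t)
            assert small_genome[row.scaffold_5p].endswith(t.seq[:j])
            assert small_genome[row.scaffold_3p].startswith(t.seq[j:])

    def test_every_gene_has_exactly_one_truth_row(self, small_cfg, small_transcriptome):
        ts, truth = small_transcriptome
        assert len(truth) == small_cfg.n_genes == len(ts.genes)


class TestReads:
    def test_pair_count_conserved_and_deterministic(self, small_transcriptome):
        ts, _ = small_transcriptome
        cfg = SimConfig(seed=14, n_read_pairs=1_000)
        r1, r2 = generate_reads(ts, cfg)
        assert len(r1) == len(r2) == 1_000
        r1b, _ = generate_reads(ts, cfg)
        assert [(a.id, a.bases, tuple(a.quals)) for a in r1] == [
            (b.id, b.bases, tuple(b.quals)) for b in r1b
        ]

    def test_noiseless_quality_model_is_flat(self, small_transcriptome):
        ts, _ = small_transcriptome
        cfg = SimConfig(seed=15, n_read_pairs=50, quality_model=(40.0, 0.0, 0.0))
        r1, r2 = generate_reads(ts, cfg)
        assert all((r.quals == 40).all() for r in r1 + r2)

    def test_mates_are_inward_facing_fragment_ends(self, small_transcriptome):
        ts, _ = small_transcriptome
        cfg = SimConfig(seed=16, n_read_pairs=100)
        r1, r2 = generate_reads(ts, cfg)
        for a, b in zip(r1[:30], r2[:30]):
            tid = truth_transcript_of(a.id)
            tx = next(t for t in ts if t.id == tid)
            fs = int(dict(tok.split("=") for tok in a.id.split()[1:])["fs"])
            fl = int(dict(tok.split("=") for tok in a.id.split()[1:])["fl"])
            frag = tx.seq[fs : fs + fl]
            assert a.bases == frag[:36]
            assert b.bases == str(Seq(frag[-36:]).reverse_complement())

    def test_read_allocation_tracks_expression(self, small_transcriptome):
        ts, _ = small_transcriptome
        reference = ts.longest_isoforms()
        ids = sorted(t.id for t in reference)[:5]
        expr = {tid: w for tid, w in zip(ids, (1, 1, 2, 4, 8))}
        cfg = SimConfig(seed=17, n_read_pairs=4_000)
        r1, _ = generate_reads(reference, cfg, expression=expr)
        counts = {tid: 0 for tid in ids}
        for r in r1:
            counts[truth_transcript_of(r.id)] += 1
        total_w = sum(expr.values())
        expected = [4_000 * expr[t] / total_w for t in ids]
        assert chisquare([counts[t] for t in ids], expected).pvalue > 0.001


class TestCountTimecourse:
    def test_deterministic_and_correct_shape(self):
        cfg = SimConfig(seed=18, n_genes=100)
        cm1, truth = generate_count_timecourse(cfg)
        cm2, _ = generate_count_timecourse(cfg)
        assert cm1.counts.equals(cm2.counts)
        assert cm1.counts.shape == (100, 7)
        assert cm1.control_libraries() == ["ctl1", "ctl2"]
        assert cm1.control_for("t2") == "ctl1" and cm1.control_for("t4") == "ctl2"
        assert len(truth) == 100

    def test_null_poisson_counts_match_baseline(self):
        cfg = SimConfig(seed=19, n_genes=3_000, de_gene_fraction=0.0,
                        nb_dispersion=0.0, library_size_dist=(1.0, 0.0))
        cm, truth = generate_count_timecourse(cfg)
        means = np.array([truth[g].mean_expression["t1"] for g in cm.counts.index])
        # standardized residuals of Poisson draws: mean ~ 0, sd ~ 1
        zres = (cm.counts["t1"].to_numpy() - means) / np.sqrt(means)
        assert abs(zres.mean()) < 0.1
        assert 0.9 < zres.std() < 1.1

    def test_planted_log2fc_recovered_in_mean_ratio(self):
        cfg = SimConfig(
            seed=20, n_genes=5_000, de_gene_fraction=1.0, n_timepoint_libs=5,
            class_profiles=((2.0, 0.0, 0.0, 0.0, 0.0),),
            library_size_dist=(1.0, 0.0), nb_dispersion=0.0,
        )
        cm, _ = generate_count_timecourse(cfg)
        ratio = cm.counts["t1"].mean() / cm.counts["ctl1"].mean()
        assert ratio == pytest.approx(4.0, rel=0.03)

    def test_dispersion_zero_vs_positive_variance(self):
        base = dict(n_genes=4_000, de_gene_fraction=0.0, library_size_dist=(1.0, 0.0),
                    baseline_expression=(500.0, 1e-9))
        cm0, _ = generate_count_timecourse(SimConfig(seed=21, nb_dispersion=0.0, **base))
        cm1, _ = generate_count_timecourse(SimConfig(seed=21, nb_dispersion=0.3, **base))
        v0 = cm0.counts["t1"].var() / cm0.counts["t1"].mean()
        v1 = cm1.counts["t1"].var() / cm1.counts["t1"].mean()
        assert v0 == pytest.approx(1.0, rel=0.15)  # Poisson: var == mean
        assert v1 > 50  # NB: var = mu + phi mu^2 >> mu at mu ~ 500


class TestProteinDb:
    def test_zero_divergence_equals_naive_translation(self, small_transcriptome):
        ts, _ = small_transcriptome
        proteins, lengths = generate_protein_db(ts, divergence=0.0, seed=1)
        for gid, gm in ts.genes.items():
            assert proteins[f"prot_{gid}"] == _naive_translate(gm.longest_isoform.seq)
            assert lengths[gid] == len(proteins[f"prot_{gid}"])

    def test_divergence_substitutes_within_binomial_bounds(self, small_transcriptome):
        ts, _ = small_transcriptome
        clean, _ = generate_protein_db(ts, divergence=0.0, seed=2)
        div, _ = generate_protein_db(ts, divergence=0.1, seed=2)
        n_sub = n_tot = 0
        for pid in clean:
            n_sub += sum(1 for a, b in zip(clean[pid], div[pid]) if a != b)
            n_tot += len(clean[pid])
        rate = n_sub / n_tot
        assert 0.07 <= rate <= 0.13

    def test_split_gene_protein_spans_junction(self, small_transcriptome):
        ts, truth = small_transcriptome
        proteins, _ = generate_protein_db(ts, divergence=0.0, seed=3)
        hits = {h.query_id: h for h in naive_protein_hits(ts, proteins)}
        for row in truth.split_genes():
            t = ts.genes[row.gene_id].longest_isoform
            h = hits[t.id]
            assert h.query_start < row.junction_offset < h.query_end

    def test_divergence_out_of_range_rejected(self, small_transcriptome):
        ts, _ = small_transcriptome
        with pytest.raises(ConfigError):
            generate_protein_db(ts, divergence=0.6)


class TestEligibility:
    def test_eligible_genes_have_full_chunk_each_side(self, small_transcriptome):
        ts, truth = small_transcriptome
        for gid in eligible_split_genes(truth, ts):
            row = truth[gid]
            t = ts.genes[gid].longest_isoform
            assert len(t) >= 1_000
            assert row.junction_offset // 500 >= 1
            assert len(t) // 500 > -(-row.junction_offset // 500)  # ceil
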