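"""RLE normalization, exact Poisson/NB tests, qCML dispersion, and the joint
significance call."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from regentx.diffexp import (
    adjust_and_call,
    estimate_common_dispersion_qcml,
    exact_nb_test,
    exact_poisson_test,
    lfc_matrix,
    log2_fc,
    rle_size_factors,
    significant_genes,
)
from regentx.models import CountMatrix, LibraryInfo
from regentx.synthetic import SimConfig, generate_count_timecourse


class TestRleSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        assert np.allclose(rle_size_factors(df), 1.0)

    def test_doubled_library_gives_sqrt2_factors(self):
        a = np.array([10, 50, 100, 7, 33])
        df = pd.DataFrame({"a": a, "b": 2 * a})
        sf = rle_size_factors(df)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_row_permutation_invariance_and_geomean_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.poisson(100, size=(200, 4)), columns=list("abcd"))
        sf = rle_size_factors(df)
        perm = df.sample(frac=1, random_state=0)
        assert np.allclose(sf, rle_size_factors(perm))
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_genes_with_zeros_are_excluded(self):
        df = pd.DataFrame({"a": [0, 10, 10], "b": [1000, 10, 10]})
        assert np.allclose(rle_size_factors(df), 1.0)

    def test_all_genes_zero_somewhere_raises(self):
        df = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            rle_size_factors(df)

    def test_agrees_with_deseq2_median_of_ratios(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(4, 1, size=(300, 1)) * np.array([0.6, 1.0, 1.7, 1.1]),),
            columns=["s1", "s2", "s3", "s4"],
        )
        sf = rle_size_factors(counts)
        meta = pd.DataFrame({"condition": ["A", "A", "B", "B"]}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ref = pd.Series(dds.obs["size_factors"].to_numpy(), index=counts.columns)
        ref = ref / np.exp(np.log(ref).mean())
        assert np.allclose(sf, ref, rtol=1e-3)


class TestExactPoisson:
    def test_balanced_counts_give_p_one(self):
        assert exact_poisson_test(5, 5) == 1.0

    def test_ten_zero_split(self):
        assert exact_poisson_test(10, 0) == pytest.approx(2 * 0.5**10)

    def test_size_scale_invariance(self):
        assert exact_poisson_test(7, 3, 1.0, 2.0) == exact_poisson_test(7, 3, 10.0, 20.0)

    def test_empty_pair_gives_p_one(self):
        assert exact_poisson_test(0, 0) == 1.0

    def test_power_increases_with_depth_at_fixed_ratio(self):
        ps = [exact_poisson_test(2 * n, n) for n in (2, 10, 50, 250)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_poisson_test(-1, 2)
        with pytest.raises(ValueError):
            exact_poisson_test(1, 2, s1=0.0)


class TestExactNB:
    def test_zero_dispersion_reduces_to_poisson_bitwise(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            c1, c2 = int(rng.integers(0, 300)), int(rng.integers(0, 300))
            s1, s2 = float(rng.lognormal(0, 0.4)), float(rng.lognormal(0, 0.4))
            assert exact_nb_test(c1, c2, s1, s2, phi=0.0) == exact_poisson_test(c1, c2, s1, s2)

    def test_balanced_counts_give_p_one(self):
        assert exact_nb_test(8, 8, phi=0.3) == pytest.approx(1.0)

    def test_overdispersion_softens_evidence(self):
        assert exact_nb_test(60, 20, phi=0.3) > exact_nb_test(60, 20, phi=0.0)

    def test_null_pvalues_near_uniform(self):
        rng = np.random.default_rng(6)
        r = 1 / 0.2
        mu = np.exp(rng.normal(np.log(500), 1.0, 2_000))
        c = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2_000, 2))
        p = np.array([exact_nb_test(a, b, phi=0.2) for a, b in c])
        assert kstest(p, "uniform").statistic < 0.05

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test(1, 2, phi=-0.1)


class TestQcmlDispersion:
    def test_identical_columns_drive_phi_to_zero(self):
        counts = np.tile(np.array([[10], [40], [200], [7]]), (1, 2))
        assert estimate_common_dispersion_qcml(counts).phi < 1e-4

    def test_recovers_planted_dispersion(self):
        cfg = SimConfig(seed=31, n_genes=5_000, nb_dispersion=0.2, de_gene_fraction=0.0)
        cm, _ = generate_count_timecourse(cfg)
        est = estimate_common_dispersion_qcml(cm.counts[["ctl1", "ctl2"]].to_numpy())
        assert 0.15 <= est.phi <= 0.25

    def test_poisson_data_estimates_near_zero(self):
        cfg = SimConfig(seed=32, n_genes=5_000, nb_dispersion=0.0, de_gene_fraction=0.0)
        cm, _ = generate_count_timecourse(cfg)
        est = estimate_common_dispersion_qcml(cm.counts[["ctl1", "ctl2"]].to_numpy())
        assert est.phi < 0.02

    def test_requires_exactly_two_controls(self):
        with pytest.raises(ValueError):
            estimate_common_dispersion_qcml(np.ones((10, 3)))


class TestLog2FC:
    def test_examples(self):
        assert log2_fc(10, 10) == 0.0
        assert log2_fc(4, 1, pseudocount=1e-12) == pytest.approx(2.0)
        assert log2_fc(10, 0, pseudocount=0.5) == pytest.approx(np.log2(10.5 / 0.5))


def toy_count_matrix(counts: np.ndarray) -> CountMatrix:
    libs = {
        "t1": LibraryInfo("t1", "0.5-1h", 1, False),
        "t2": LibraryInfo("t2", "2-3h", 2, False),
        "ctl1": LibraryInfo("ctl1", "0h", 1, True),
        "ctl2": LibraryInfo("ctl2", "0h", 2, True),
    }
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=list(libs)), libs)


class TestAdjustAndCall:
    def test_null_matrix_yields_no_calls(self):
        rng = np.random.default_rng(9)
        cm = toy_count_matrix(rng.poisson(200, size=(300, 4)))
        res = adjust_and_call(cm)
        assert not res["significant"].any()

    def test_strong_single_gene_called_in_its_batch(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(200, size=(400, 4))
        counts[0, 0] = 3_000  # gene 0 up in t1 (batch 1)
        cm = toy_count_matrix(counts)
        res = adjust_and_call(cm)
        row = res[(res.gene_id == "g0") & (res.library == "t1")].iloc[0]
        assert row.significant and row.control == "ctl1" and row.lfc > 0.7
        assert significant_genes(res) == ["g0"]

    def test_bh_adjustment_matches_hand_computation(self):
        pvals = np.array([1e-6] + [0.8] * 999)
        counts = np.full((1_000, 4), 100)
        cm = toy_count_matrix(counts)
        res = adjust_and_call(cm)
        # independent BH on a hand-built vector
        m = len(pvals)
        order = np.argsort(pvals)
        ranked = pvals[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        assert adj[0] == pytest.approx(1e-3)  # boundary: strict < keeps it out
        assert not res["significant"].any()

    def test_large_effect_with_small_p_but_small_lfc_not_called(self):
        # high counts: tiny p but fold change below 0.7 -> excluded
        counts = np.full((200, 4), 4_000)
        counts[:, 0] = 5_200  # lfc = log2(1.3) ~ 0.38
        cm = toy_count_matrix(counts)
        sf = pd.Series(1.0, index=cm.counts.columns)
        res = adjust_and_call(cm, size_factors=sf)
        sub = res[res.library == "t1"]
        assert (sub.padj < 1e-3).all() and not sub.significant.any()

    def test_missing_batch_control_raises(self):
        libs = {
            "t1": LibraryInfo("t1", "0.5-1h", 1, False),
            "ctl2": LibraryInfo("ctl2", "0h", 2, True),
        }
        cm = CountMatrix(
            pd.DataFrame([[10, 10]], index=["g0"], columns=["t1", "ctl2"]), libs
        )
        with pytest.raises(ValueError, match="batch"):
            adjust_and_call(cm, size_factors=pd.Series(1.0, index=["t1", "ctl2"]))

    def test_lfc_matrix_shape(self):
        rng = np.random.default_rng(12)
        cm = toy_count_matrix(rng.poisson(100, size=(50, 4)))
        res = adjust_and_call(cm)
        wide = lfc_matrix(res)
        assert wide.shape == (50, 2) and list(wide.columns) == ["t1", "t2"]
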